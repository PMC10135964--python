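"""One-site isothermal titration calorimetry: simulation and fitting.

Implements the standard single-site binding isotherm for an injection
series, with displacement-corrected cell concentrations.  After the i-th
injection (cumulative injected volume dV), the effective cell and
titrant concentrations are

    M_t = M0 * (1 - dV/2V0) / (1 + dV/2V0)
    X_t = X0 * (dV/V0)     / (1 + dV/2V0)

and the cumulative heat content of the cell is

    Q = (n*M_t*dH*V0/2) * (b - sqrt(b^2 - 4*Xt/(n*Mt))),
    b = 1 + Xt/(n*Mt) + Kd/(n*Mt).

The observed per-injection heat (kcal per mole of injectant) is the
difference of consecutive Q values corrected for the displaced volume,
plus a constant dilution offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .conformer_thermo import R_KCAL

__all__ = [
    "ITCProtocol",
    "BindingParams",
    "Isotherm",
    "ITCFitResult",
    "simulate_isotherm",
    "fit_one_site",
    "average_binding_params",
]


@dataclass(frozen=True)
class ITCProtocol:
    """Injection schedule and cell/syringe concentrations.

    ``cell_volume_ul`` is the *active* cell volume V0 seen by the
    detector (instrument-defined; 200 uL default).  Temperature defaults
    to 25 C.
    """

    cell_conc: float  # mol/L macromolecule in cell
    syringe_conc: float  # mol/L ligand in syringe
    injection_volumes_ul: tuple[float, ...]
    cell_volume_ul: float = 200.0
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes_ul", tuple(float(v) for v in self.injection_volumes_ul)
        )
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume_ul <= 0 or any(v <= 0 for v in self.injection_volumes_ul):
            raise ValueError("volumes must be positive")
        if not self.injection_volumes_ul:
            raise ValueError("at least one injection required")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    @property
    def cumulative_volumes_ul(self) -> np.ndarray:
        return np.cumsum(self.injection_volumes_ul)

    def cell_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Displacement-corrected (M_t, X_t) after each injection."""
        dv = self.cumulative_volumes_ul / self.cell_volume_ul
        mt = self.cell_conc * (1 - dv / 2) / (1 + dv / 2)
        xt = self.syringe_conc * dv / (1 + dv / 2)
        return mt, xt

    @classmethod
    def uniform(
        cls,
        cell_conc: float,
        syringe_conc: float,
        n_injections: int = 19,
        injection_volume_ul: float = 2.0,
        cell_volume_ul: float = 200.0,
        temperature_k: float = 298.15,
    ) -> "ITCProtocol":
        return cls(
            cell_conc=cell_conc,
            syringe_conc=syringe_conc,
            injection_volumes_ul=(injection_volume_ul,) * n_injections,
            cell_volume_ul=cell_volume_ul,
            temperature_k=temperature_k,
        )


@dataclass(frozen=True)
class BindingParams:
    """Single-site binding parameters; ΔG and -TΔS are derived on demand."""

    n: float  # stoichiometry (sites per macromolecule)
    k_d: float  # mol/L
    delta_h: float  # kcal/mol
    dilution_offset: float = 0.0  # kcal/mol of injectant

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValueError("k_d must be positive")

    def delta_g(self, temperature_k: float) -> float:
        """ΔG = RT ln K_d (kcal/mol, 1 M standard state)."""
        return R_KCAL * temperature_k * math.log(self.k_d)

    def minus_t_delta_s(self, temperature_k: float) -> float:
        """-TΔS = ΔG - ΔH, so that ΔG = ΔH + (-TΔS) holds identically."""
        return self.delta_g(temperature_k) - self.delta_h


@dataclass(frozen=True)
class Isotherm:
    """Integrated per-injection heats, normalized per mole of injectant."""

    molar_ratio: np.ndarray  # X_t / M_t after each injection
    heat_kcal_per_mol: np.ndarray
    injection_volumes_ul: tuple[float, ...]

    def __post_init__(self) -> None:
        mr = np.asarray(self.molar_ratio, dtype=float)
        q = np.asarray(self.heat_kcal_per_mol, dtype=float)
        if mr.shape != q.shape or mr.ndim != 1:
            raise ValueError("molar_ratio and heats must be 1-D arrays of equal length")
        if len(self.injection_volumes_ul) != mr.size:
            raise ValueError("one heat per injection required")
        object.__setattr__(self, "molar_ratio", mr)
        object.__setattr__(self, "heat_kcal_per_mol", q)
        object.__setattr__(
            self, "injection_volumes_ul", tuple(float(v) for v in self.injection_volumes_ul)
        )

    def __len__(self) -> int:
        return self.molar_ratio.size


def _cumulative_heats(protocol: ITCProtocol, n: float, k_d: float, delta_h: float) -> np.ndarray:
    """Cumulative cell heat content Q_i (kcal) after each injection."""
    mt, xt = protocol.cell_concentrations()
    v0_l = protocol.cell_volume_ul * 1e-6
    s = n * mt  # binding-site concentration
    b = 1.0 + xt / s + k_d / s
    disc = np.sqrt(np.maximum(b * b - 4.0 * xt / s, 0.0))
    return s * delta_h * v0_l / 2.0 * (b - disc)


def _model_heats(protocol: ITCProtocol, params: BindingParams) -> np.ndarray:
    """Per-injection heats (kcal/mol of injectant) including displacement."""
    q = _cumulative_heats(protocol, params.n, params.k_d, params.delta_h)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = np.asarray(protocol.injection_volumes_ul) / protocol.cell_volume_ul
    raw = q + dv * (q + q_prev) / 2.0 - q_prev  # kcal
    moles = np.asarray(protocol.injection_volumes_ul) * 1e-6 * protocol.syringe_conc
    return raw / moles + params.dilution_offset


def simulate_isotherm(
    protocol: ITCProtocol,
    params: BindingParams,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Isotherm:
    """Forward-simulate a one-site isotherm; optional Gaussian heat noise.

    ``noise_sd`` is in kcal per mole of injectant; ``seed`` feeds a
    ``numpy.random.default_rng`` PCG64 generator for reproducibility.
    """
    heats = _model_heats(protocol, params)
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.size)
    mt, xt = protocol.cell_concentrations()
    return Isotherm(
        molar_ratio=xt / mt,
        heat_kcal_per_mol=heats,
        injection_volumes_ul=protocol.injection_volumes_ul,
    )


@dataclass(frozen=True)
class ITCFitResult:
    """Fit output: best-fit parameters plus diagnostics."""

    params: BindingParams
    param_sd: dict[str, float]
    converged: bool
    c_value: float
    low_information: bool
    k_d_undetermined: bool
    rms_residual: float
    n_obs: int

    def delta_g(self, temperature_k: float) -> float:
        return self.params.delta_g(temperature_k)

    def minus_t_delta_s(self, temperature_k: float) -> float:
        return self.params.minus_t_delta_s(temperature_k)


def fit_one_site(
    isotherm: Isotherm,
    protocol: ITCProtocol,
    float_n: bool = True,
    discard_first: bool = False,
    weights: Sequence[float] | None = None,
) -> ITCFitResult:
    """Weighted least-squares fit of (n, K_d, ΔH, dilution offset).

    K_d is optimized on a log10 scale to enforce positivity.  With
    ``float_n=False`` the stoichiometry is fixed at 1.  ``discard_first``
    drops the first injection (common practice for diffusion artefacts).
    A c-value (n·M_t/K_d) outside [1, 1000] is flagged as low-information
    but the fit is still returned.
    """
    y = isotherm.heat_kcal_per_mol
    if len(isotherm) < 5:
        raise ValueError("need at least 5 injections to fit")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    if w.size != y.size or (w < 0).any():
        raise ValueError("weights must be nonnegative, one per injection")
    mask = np.ones(y.size, dtype=bool)
    if discard_first:
        mask[0] = False
    sw = np.sqrt(w[mask])

    # initial guesses from the raw curve shape (masked points excluded)
    ym = y[mask]
    mr = isotherm.molar_ratio[mask]
    offset0 = float(np.mean(ym[-2:]))
    dh0 = float(ym[0] - offset0)
    if abs(dh0) < 1e-12:
        dh0 = -1e-3
    half = offset0 + dh0 / 2.0
    below = np.flatnonzero(np.abs(ym - offset0) < np.abs(half - offset0))
    n0 = float(mr[below[0]]) if below.size else 1.0
    n0 = min(max(n0, 0.1), 10.0)
    kd0 = max(protocol.cell_conc * n0 / 100.0, 1e-12)

    def theta_to_params(theta: np.ndarray) -> BindingParams:
        if float_n:
            n, log_kd, dh, off = theta
        else:
            log_kd, dh, off = theta
            n = 1.0
        return BindingParams(n=abs(n), k_d=10.0**log_kd, delta_h=dh, dilution_offset=off)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = theta_to_params(theta)
        return sw * (_model_heats(protocol, p)[mask] - y[mask])

    if float_n:
        theta0 = np.array([n0, math.log10(kd0), dh0, offset0])
        lo = [1e-3, -15.0, -np.inf, -np.inf]
        hi = [100.0, 0.0, np.inf, np.inf]
    else:
        theta0 = np.array([math.log10(kd0), dh0, offset0])
        lo = [-15.0, -np.inf, -np.inf]
        hi = [0.0, np.inf, np.inf]
    res = least_squares(residuals, theta0, method="trf", bounds=(lo, hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    params = theta_to_params(res.x)

    dof = max(int(mask.sum()) - res.x.size, 1)
    rms = float(np.sqrt(2.0 * res.cost / dof))
    # parameter sd from local curvature (Gauss-Newton covariance)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.pinv(jtj) * rms**2
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sd = np.full(res.x.size, np.nan)
    names = ["n", "log10_k_d", "delta_h", "dilution_offset"] if float_n else [
        "log10_k_d", "delta_h", "dilution_offset"]
    param_sd = dict(zip(names, sd))

    c_value = params.n * protocol.cell_conc / params.k_d
    k_d_undetermined = abs(params.delta_h) < 1e-6 or not math.isfinite(c_value)
    return ITCFitResult(
        params=params,
        param_sd=param_sd,
        converged=bool(res.success),
        c_value=float(c_value),
        low_information=not (1.0 <= c_value <= 1000.0),
        k_d_undetermined=bool(k_d_undetermined),
        rms_residual=rms,
        n_obs=int(mask.sum()),
    )


def average_binding_params(
    fits: Sequence[BindingParams], temperature_k: float = 298.15
) -> dict[str, float]:
    """Replicate-mean report: arithmetic means of n, K_d, ΔH; ΔG from mean K_d."""
    if not fits:
        raise ValueError("need at least one replicate")
    n = float(np.mean([p.n for p in fits]))
    k_d = float(np.mean([p.k_d for p in fits]))
    dh = float(np.mean([p.delta_h for p in fits]))
    dg = R_KCAL * temperature_k * math.log(k_d)
    return {
        "n": n,
        "k_d": k_d,
        "delta_h": dh,
        "delta_g": dg,
        "minus_t_delta_s": dg - dh,
        "n_replicates": float(len(fits)),
    }
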