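"""Fast-exchange NMR titration forward model and constant refinement.

In the fast-exchange regime every nucleus shows a single resonance whose
chemical shift is the ligand-fraction-weighted average of the limiting
shifts of the coexisting species:

    delta_obs(nucleus) = sum_j fraction_j * delta_j(nucleus)

Fitting uses variable projection (separable nonlinear least squares):
for any trial vector of formation constants the speciation is solved at
every titration point and the limiting shifts -- which enter linearly --
are obtained by weighted linear least squares.  The nonlinear search
therefore runs only over the selected log beta values.

Model selection follows the sigma statistic (weighted RMS misfit per
residual degree of freedom), with ties broken toward the model with
fewer species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .chem_model import ChemicalModel, SpeciesDef
from .equilibrium import SolutionConditions, fraction_matrix, solve_point

__all__ = [
    "NUCLEI",
    "TitrationPoint",
    "TitrationDataset",
    "ShiftBasis",
    "FitOptions",
    "FitResult",
    "ProtonationStepShiftChange",
    "predict_shifts",
    "fit_titration",
    "model_selection",
    "protonation_step_shifts",
]

#: default 31P nucleus labels (alpha/beta pyrophosphate positions as a/b)
NUCLEI = ("P1a", "P1b", "P2", "P3", "P4", "P5a", "P5b", "P6")

#: species populated below this maximum fraction anywhere are treated as
#: unobservable and their shifts are flagged undetermined, not fitted
POPULATION_FLOOR = 1e-4


@dataclass(frozen=True)
class TitrationPoint:
    ph: float
    observed: dict[str, float]  # nucleus -> delta (ppm); absent = missing
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")
        if not self.observed:
            raise ValueError(f"titration point at pH {self.ph} has no observations")
        bad = [n for n, v in self.observed.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite shift for {bad} at pH {self.ph}")


@dataclass(frozen=True)
class TitrationDataset:
    """Observed delta-vs-pH curves plus the solution conditions they share."""

    points: tuple[TitrationPoint, ...]
    nuclei: tuple[str, ...]
    conditions_template: SolutionConditions

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        phs = [p.ph for p in self.points]
        if len(set(phs)) != len(phs):
            raise ValueError("pH values must be distinct")
        for p in self.points:
            unknown = set(p.observed) - set(self.nuclei)
            if unknown:
                raise ValueError(f"unknown nuclei {sorted(unknown)} at pH {p.ph}")

    @property
    def ph_values(self) -> np.ndarray:
        return np.array([p.ph for p in self.points])

    @property
    def n_observations(self) -> int:
        return sum(len(p.observed) for p in self.points)

    def observation_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(Y, W): (P, N) shift matrix with NaN for missing, per-point weights."""
        P, N = len(self.points), len(self.nuclei)
        y = np.full((P, N), np.nan)
        w = np.empty(P)
        for i, p in enumerate(self.points):
            w[i] = p.weight
            for j, nuc in enumerate(self.nuclei):
                if nuc in p.observed:
                    y[i, j] = p.observed[nuc]
        return y, w


@dataclass(frozen=True)
class ShiftBasis:
    """Limiting chemical shifts: (species id, nucleus) -> ppm."""

    delta: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", dict(self.delta))
        bad = [k for k, v in self.delta.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite limiting shifts for {bad}")

    def get(self, species_id: str, nucleus: str) -> float:
        return self.delta[(species_id, nucleus)]

    def nuclei(self) -> tuple[str, ...]:
        return tuple(sorted({nuc for _, nuc in self.delta}))

    def species_ids(self) -> tuple[str, ...]:
        return tuple(sorted({sid for sid, _ in self.delta}))

    def matrix(self, species_ids: Sequence[str], nuclei: Sequence[str]) -> np.ndarray:
        """(S, N) matrix of limiting shifts; KeyError on gaps."""
        return np.array([[self.delta[(s, n)] for n in nuclei] for s in species_ids])

    @classmethod
    def from_matrix(
        cls, species_ids: Sequence[str], nuclei: Sequence[str], m: np.ndarray
    ) -> "ShiftBasis":
        m = np.asarray(m, dtype=float)
        return cls({(s, n): float(m[i, j]) for i, s in enumerate(species_ids) for j, n in enumerate(nuclei)})


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_titration`.

    ``refine``: species ids whose cumulative log beta is optimized; the
    default refines every complex species (everything but the free
    ligand).  ``start``: optional initial values overriding the model.
    """

    refine: tuple[str, ...] | None = None
    start: Mapping[str, float] | None = None
    population_floor: float = POPULATION_FLOOR
    max_nfev: int | None = None
    xtol: float = 1e-12
    ftol: float = 1e-12
    #: when set, limiting shifts are held at these values instead of being
    #: projected out; only the formation constants are optimized
    fixed_basis: "ShiftBasis | None" = None


@dataclass(frozen=True)
class FitResult:
    refined_log_betas: dict[str, tuple[float, float]]  # id -> (value, sd)
    refined_basis: ShiftBasis
    sigma: float
    chi_square: float
    n_obs: int
    n_params: int
    converged: bool
    undetermined_species: tuple[str, ...] = ()
    model: ChemicalModel | None = None

    def refined_model(self) -> ChemicalModel:
        if self.model is None:
            raise ValueError("fit carries no model")
        return self.model


@dataclass(frozen=True)
class ProtonationStepShiftChange:
    """Shift changes delta(H_{n+1}L) - delta(H_nL) for one protonation step."""

    from_id: str
    to_id: str
    step: int  # proton count after the step
    delta_delta: dict[str, float]
    inferred_sites: tuple[str, ...]
    degenerate: bool = False


def predict_shifts(
    model: ChemicalModel,
    basis: ShiftBasis,
    cond: SolutionConditions,
) -> dict[str, float]:
    """Population-weighted shift per nucleus at one solution condition."""
    res = solve_point(model, cond)
    if not res.converged:
        raise RuntimeError(f"speciation did not converge at pH {cond.ph}")
    nuclei = basis.nuclei()
    out = {nuc: 0.0 for nuc in nuclei}
    for sid, frac in res.ligand_fractions.items():
        if frac <= 1e-6:
            continue
        for nuc in nuclei:
            try:
                out[nuc] += frac * basis.get(sid, nuc)
            except KeyError as exc:
                raise KeyError(
                    f"basis has no limiting shift for populated species {sid!r}, nucleus {nuc!r}"
                ) from exc
    return out


def _projected_residuals(F, y, w, floor):
    """Weighted residuals after projecting out the limiting shifts.

    F: (P, S) fractions; y: (P, N) observations with NaN; w: (P,) weights.
    Returns (residual vector, shift matrix D (S, N) with NaN for
    undetermined species, active-species mask).
    """
    P, S = F.shape
    N = y.shape[1]
    active = F.max(axis=0) > floor
    A = F[:, active]
    sw = np.sqrt(w)
    D = np.full((S, N), np.nan)
    res_parts = []
    for j in range(N):
        rows = ~np.isnan(y[:, j])
        if not rows.any():
            continue
        Aw = A[rows] * sw[rows, None]
        yw = y[rows, j] * sw[rows]
        d, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
        D[active, j] = d
        res_parts.append(Aw @ d - yw)
    return np.concatenate(res_parts), D, active


def fit_titration(
    data: TitrationDataset,
    model: ChemicalModel,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Refine formation constants (and limiting shifts) against a titration.

    Returns sigma = sqrt(weighted SSQ / (n_obs - n_params)), the weighted
    SSQ itself as the chi-square statistic, and standard deviations of
    the refined constants from the local Gauss-Newton curvature.
    """
    refine = options.refine
    if refine is None:
        refine = tuple(s.id for s in model.species if not s.is_free_ligand)
    refine = tuple(refine)
    for sid in refine:
        model.get(sid)  # KeyError on unknown ids
    theta0 = np.array(
        [
            (options.start or {}).get(sid, model.get(sid).log_beta)
            for sid in refine
        ],
        dtype=float,
    )

    ph = data.ph_values
    y, w = data.observation_matrix()
    # observations must line up with dataset nuclei order
    cond = data.conditions_template
    warm: dict[str, np.ndarray] = {}

    def frac_of(theta: np.ndarray) -> np.ndarray:
        override = dict(zip(refine, theta))
        F, ids, u, ok = fraction_matrix(model, cond, ph, override, u0=warm.get("u"))
        if not ok:
            # retry cold in case the warm start trapped the solver
            F, ids, u, ok = fraction_matrix(model, cond, ph, override)
            if not ok:
                raise RuntimeError("speciation failed to converge during fitting")
        warm["u"] = u
        return F

    fixed_d = None
    ids = list(model.ids)
    if options.fixed_basis is not None:
        fixed_d = options.fixed_basis.matrix(ids, data.nuclei)  # (S, N)

    def residuals(theta: np.ndarray) -> np.ndarray:
        F = frac_of(theta)
        if fixed_d is not None:
            sw = np.sqrt(w)[:, None]
            r = (sw * (F @ fixed_d - y)).ravel()
            return r[~np.isnan(r)]
        r, _, _ = _projected_residuals(F, y, w, options.population_floor)
        return r

    res = least_squares(
        residuals,
        theta0,
        method="trf",
        xtol=options.xtol,
        ftol=options.ftol,
        gtol=1e-12,
        max_nfev=options.max_nfev,
    )

    F = frac_of(res.x)
    if fixed_d is not None:
        r = residuals(res.x)
        D = fixed_d.copy()
        active = F.max(axis=0) > options.population_floor
        n_shift_params = 0
    else:
        r, D, active = _projected_residuals(F, y, w, options.population_floor)
        n_shift_params = int(np.sum(~np.isnan(D)))
    undetermined = tuple(sid for sid, a in zip(ids, active) if not a)

    n_obs = data.n_observations
    n_params = len(refine) + n_shift_params
    dof = n_obs - n_params
    if dof <= 0:
        raise ValueError(
            f"underdetermined fit: {n_obs} observations for {n_params} parameters"
        )
    ssq = float(r @ r)
    sigma = math.sqrt(ssq / dof)

    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.pinv(jtj) * sigma**2
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sds = np.full(res.x.size, np.nan)

    basis_entries = {
        (sid, nuc): float(D[i, j])
        for i, sid in enumerate(ids)
        for j, nuc in enumerate(data.nuclei)
        if not np.isnan(D[i, j])
    }
    refined = dict(zip(refine, zip(map(float, res.x), map(float, sds))))
    return FitResult(
        refined_log_betas={k: (v, s) for k, (v, s) in refined.items()},
        refined_basis=ShiftBasis(basis_entries),
        sigma=sigma,
        chi_square=ssq,
        n_obs=n_obs,
        n_params=n_params,
        converged=bool(res.success),
        undetermined_species=undetermined,
        model=model.with_log_betas({k: v for k, (v, _) in refined.items()}),
    )


@dataclass(frozen=True)
class ModelSelectionEntry:
    model: ChemicalModel
    fit: FitResult | None
    error: str | None = None

    @property
    def n_species(self) -> int:
        return len(self.model.species)


def model_selection(
    data: TitrationDataset,
    candidates: Sequence[ChemicalModel],
    options: FitOptions = FitOptions(),
    sigma_tolerance: float = 0.05,
) -> list[ModelSelectionEntry]:
    """Fit every candidate model and rank by sigma; parsimony breaks ties.

    Two candidates tie when their sigmas agree within ``sigma_tolerance``
    (relative) or are both numerically zero; the model with fewer species
    then ranks first.  Raises RuntimeError if every candidate fails.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    entries: list[ModelSelectionEntry] = []
    for m in candidates:
        try:
            entries.append(ModelSelectionEntry(m, fit_titration(data, m, options)))
        except Exception as exc:  # noqa: BLE001 - report, don't mask, per-candidate failures
            entries.append(ModelSelectionEntry(m, None, error=str(exc)))
    ok = [e for e in entries if e.fit is not None]
    if not ok:
        raise RuntimeError(
            "all candidate models failed: " + "; ".join(e.error or "?" for e in entries)
        )

    def rank_key(e: ModelSelectionEntry):
        # bucket sigmas so near-equal fits compare by parsimony
        s = e.fit.sigma
        best = min(x.fit.sigma for x in ok)
        tied_with_best = s <= 1e-9 or (best > 0 and (s - best) <= sigma_tolerance * max(s, best))
        return (0 if tied_with_best else 1, s if not tied_with_best else 0.0, e.n_species)

    ranked = sorted(ok, key=rank_key)
    failed = [e for e in entries if e.fit is None]
    return ranked + failed


def protonation_step_shifts(
    model: ChemicalModel,
    basis: ShiftBasis,
    margin: float = 0.25,
) -> list[ProtonationStepShiftChange]:
    """Per-step shift changes along the metal-free protonation ladder.

    For each consecutive pair H_nL -> H_{n+1}L the change of every
    nucleus's limiting shift is reported; the inferred protonation sites
    are the nuclei whose change lies within ``margin`` ppm of the most
    negative one.  A step with no negative change at all is degenerate.
    """
    ladder = model.protonation_ladder()
    if len(ladder) < 2:
        raise ValueError("model has no protonation steps")
    for prev, cur in zip(ladder, ladder[1:]):
        if cur.n_h != prev.n_h + 1:
            raise ValueError(
                f"protonation ladder has a gap between {prev.id} (n_h={prev.n_h}) "
                f"and {cur.id} (n_h={cur.n_h})"
            )
    nuclei = basis.nuclei()
    out = []
    for prev, cur in zip(ladder, ladder[1:]):
        dd = {nuc: basis.get(cur.id, nuc) - basis.get(prev.id, nuc) for nuc in nuclei}
        lo = min(dd.values())
        degenerate = lo >= -1e-12
        sites = () if degenerate else tuple(
            sorted(n for n, v in dd.items() if v <= lo + margin)
        )
        out.append(
            ProtonationStepShiftChange(
                from_id=prev.id,
                to_id=cur.id,
                step=cur.n_h,
                delta_delta=dd,
                inferred_sites=sites,
                degenerate=degenerate,
            )
        )
    return out
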