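"""Axial/equatorial conformer equilibrium thermodynamics.

Quantifies the two-state ring-flip equilibrium K = [ax]/[eq] from NMR
peak integrals, extracts ΔH⁰/ΔS⁰ by van't Hoff regression of ln K on
1/T, and extrapolates the axial fraction to other temperatures through
the Gibbs-Helmholtz relation.  Also provides the linear conversion from
apparent pH readings in D₂O (pH*) to pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_KCAL",
    "ConformerPoint",
    "ConformerSeries",
    "ThermoParams",
    "ConformerRatio",
    "conformer_ratio",
    "vant_hoff_fit",
    "fraction_axial",
    "ph_star_to_ph",
]

#: gas constant, kcal/(mol K)
R_KCAL = 1.987204e-3

#: pH* (apparent pH-meter reading in D2O) -> pH linear conversion
_PH_STAR_SLOPE = 0.929
_PH_STAR_INTERCEPT = 0.42


class ConformerRatio(NamedTuple):
    k_ax_eq: float
    fraction_axial_percent: float


def conformer_ratio(
    ax_integral: float,
    eq_integral: float,
    impurity_correction: float = 0.0,
    correction_on: str = "eq",
) -> ConformerRatio:
    """Equilibrium constant K = [ax]/[eq] from two peak integrals.

    ``impurity_correction`` is subtracted from the nominated peak
    (``correction_on`` is ``"eq"`` or ``"ax"``) before forming the ratio,
    e.g. to remove a co-resonant impurity contribution.
    """
    if correction_on not in ("ax", "eq"):
        raise ValueError("correction_on must be 'ax' or 'eq'")
    ax = ax_integral - (impurity_correction if correction_on == "ax" else 0.0)
    eq = eq_integral - (impurity_correction if correction_on == "eq" else 0.0)
    if ax <= 0 or eq <= 0:
        raise ValueError(
            f"corrected integrals must be positive (ax={ax}, eq={eq})"
        )
    k = ax / eq
    return ConformerRatio(k, 100.0 * k / (1.0 + k))


@dataclass(frozen=True)
class ConformerPoint:
    temperature_k: float
    k_ax_eq: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if self.k_ax_eq <= 0:
            raise ValueError("k_ax_eq must be positive")


@dataclass(frozen=True)
class ConformerSeries:
    """K = [ax]/[eq] versus temperature, possibly with replicate structure."""

    points: tuple[ConformerPoint, ...]
    mg_equivalents: float | None = None
    ph_star: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p.temperature_k for p in self.points])

    @property
    def k_values(self) -> np.ndarray:
        return np.array([p.k_ax_eq for p in self.points])

    def replicate_ids(self) -> tuple[int, ...]:
        return tuple(sorted({p.replicate for p in self.points}))

    def replicate(self, rid: int) -> "ConformerSeries":
        return ConformerSeries(
            tuple(p for p in self.points if p.replicate == rid),
            self.mg_equivalents,
            self.ph_star,
        )


@dataclass(frozen=True)
class ThermoParams:
    """Standard enthalpy/entropy of the eq -> ax transition with regression errors."""

    delta_h: float  # kcal/mol
    delta_s: float  # kcal/(mol K)
    delta_h_se: float = 0.0
    delta_s_se: float = 0.0
    r_squared: float = float("nan")
    n: int = 0
    r_gas: float = R_KCAL

    def __post_init__(self) -> None:
        if self.delta_h_se < 0 or self.delta_s_se < 0:
            raise ValueError("standard errors must be nonnegative")

    def k_at(self, temperature_k: float) -> float:
        dg = self.delta_h - temperature_k * self.delta_s
        return math.exp(-dg / (self.r_gas * temperature_k))

    def fraction_axial(self, temperature_k: float) -> float:
        return fraction_axial(self.delta_h, self.delta_s, temperature_k, r_gas=self.r_gas)


def vant_hoff_fit(series: ConformerSeries) -> ThermoParams:
    """Ordinary least squares of ln K on 1/T, replicates pooled.

    ΔH⁰ = -slope·R and ΔS⁰ = intercept·R; standard errors are propagated
    from the regression standard errors of slope and intercept.
    """
    t = series.temperatures
    k = series.k_values
    if np.unique(t).size < 3:
        raise ValueError("van't Hoff regression needs at least 3 distinct temperatures")
    x = 1.0 / t
    y = np.log(k)
    res = stats.linregress(x, y)
    return ThermoParams(
        delta_h=-res.slope * R_KCAL,
        delta_s=res.intercept * R_KCAL,
        delta_h_se=res.stderr * R_KCAL,
        delta_s_se=res.intercept_stderr * R_KCAL,
        r_squared=res.rvalue**2,
        n=t.size,
    )


def fraction_axial(
    delta_h: float,
    delta_s: float,
    temperature_k: float,
    r_gas: float = R_KCAL,
) -> float:
    """Percent axial conformer at ``temperature_k`` by Gibbs-Helmholtz.

    ΔG = ΔH⁰ - TΔS⁰, K = exp(-ΔG/RT), percent = 100·K/(1+K).  The raw
    (unrounded) percentage is returned; round for display.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    dg = delta_h - temperature_k * delta_s
    # logistic form of K/(1+K): stable for strongly favourable dG
    return 100.0 / (1.0 + math.exp(dg / (r_gas * temperature_k)))


def ph_star_to_ph(ph_star: float) -> float:
    """Convert an apparent D₂O pH-meter reading to pH: 0.929·pH* + 0.42."""
    return _PH_STAR_SLOPE * ph_star + _PH_STAR_INTERCEPT
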