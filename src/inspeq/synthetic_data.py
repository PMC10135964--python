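"""Seeded synthetic data for every analysis stage.

All generators use ``numpy.random.default_rng`` (PCG64); identical seeds
and parameters give identical output on any platform.  Noise models:
Gaussian in ppm for chemical shifts, log-normal for conformer integral
ratios (ratios are positive), Gaussian in kcal/mol for injection heats.

The demo limiting-shift basis is FABRICATED: it mimics the qualitative
behaviour of highly phosphorylated inositol ligands (upfield movement on
protonation, downfield on metal complexation, distinct per-step site
patterns) but is not measured data.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .chem_model import ChemicalModel
from .conformer_thermo import R_KCAL, ConformerPoint, ConformerSeries, ThermoParams
from .equilibrium import SolutionConditions, fraction_matrix
from .itc_binding import BindingParams, ITCProtocol, Isotherm, simulate_isotherm
from .nmr_titration import NUCLEI, ShiftBasis, TitrationDataset, TitrationPoint

__all__ = [
    "demo_shift_basis",
    "gen_titration",
    "gen_conformer_series",
    "gen_itc",
    "DEFAULT_PH_GRID",
]

#: pH 3.0-12.5 in 0.5 steps (20 points)
DEFAULT_PH_GRID = tuple(np.round(np.arange(3.0, 12.51, 0.5), 2))

# free-ligand 31P shifts (ppm) and per-protonation-step changes of the
# limiting shifts; step 1 moves P3/P5b/P1b the most, step 2 mimics the
# abrupt monophosphate changes that accompany the ring flip.
_BASE_SHIFTS = {
    "P1a": -6.2, "P1b": -4.8, "P2": 2.2, "P3": 1.6,
    "P4": 1.2, "P5a": -6.6, "P5b": -5.1, "P6": 0.8,
}
_STEP_DELTAS = (
    {"P1a": -0.10, "P1b": -0.80, "P2": -0.10, "P3": -1.00, "P4": -0.10, "P5a": -0.10, "P5b": -0.90, "P6": -0.10},
    {"P1a": -0.10, "P1b": -0.10, "P2": -0.90, "P3": -0.30, "P4": -0.85, "P5a": -0.10, "P5b": -0.15, "P6": -0.80},
    {"P1a": -0.10, "P1b": -0.10, "P2": -0.10, "P3": -0.10, "P4": -0.90, "P5a": -0.10, "P5b": -0.10, "P6": -0.70},
    {"P1a": -0.10, "P1b": -0.10, "P2": -0.10, "P3": -0.10, "P4": -0.10, "P5a": -0.90, "P5b": -0.50, "P6": -0.10},
    {"P1a": -0.90, "P1b": -0.40, "P2": -0.10, "P3": -0.10, "P4": -0.10, "P5a": -0.10, "P5b": -0.10, "P6": -0.10},
    {"P1a": -0.10, "P1b": -0.10, "P2": -0.80, "P3": -0.30, "P4": -0.10, "P5a": -0.10, "P5b": -0.10, "P6": -0.10},
    {"P1a": -0.10, "P1b": -0.10, "P2": -0.10, "P3": -0.90, "P4": -0.10, "P5a": -0.10, "P5b": -0.10, "P6": -0.10},
    {"P1a": -0.10, "P1b": -0.10, "P2": -0.10, "P3": -0.10, "P4": -0.30, "P5a": -0.10, "P5b": -0.10, "P6": -0.90},
)
#: downfield (positive) offsets per bound metal ion
_K_SHIFT = 0.25
_MG_SHIFT = 0.40


def demo_shift_basis(model: ChemicalModel, nuclei: Sequence[str] = NUCLEI) -> ShiftBasis:
    """Synthetic limiting shifts for every species of ``model``.

    delta(species, nucleus) = base + sum of the first n_h per-step
    changes + 0.25*n_k + 0.40*n_mg (metal complexation is downfield).
    Illustrative only -- not measured shifts.
    """
    entries: dict[tuple[str, str], float] = {}
    for sp in model.species:
        if sp.n_l == 0:
            continue
        if sp.n_h > len(_STEP_DELTAS):
            raise ValueError(f"demo basis covers at most {len(_STEP_DELTAS)} protons, {sp.id} has {sp.n_h}")
        for nuc in nuclei:
            if nuc not in _BASE_SHIFTS:
                raise KeyError(f"demo basis has no base shift for nucleus {nuc!r}")
            val = _BASE_SHIFTS[nuc]
            for step in range(sp.n_h):
                val += _STEP_DELTAS[step][nuc]
            val += _K_SHIFT * sp.n_k + _MG_SHIFT * sp.n_mg
            entries[(sp.id, nuc)] = val
    return ShiftBasis(entries)


def gen_titration(
    model: ChemicalModel,
    basis: ShiftBasis,
    ph_grid: Sequence[float] = DEFAULT_PH_GRID,
    noise_sd_ppm: float = 0.0,
    seed: int | np.random.Generator | None = None,
    conditions_template: SolutionConditions | None = None,
    missing_rate: float = 0.0,
    nuclei: Sequence[str] = NUCLEI,
) -> TitrationDataset:
    """Forward-model a titration dataset with Gaussian ppm noise.

    ``missing_rate`` randomly blanks observations (never an entire
    point), mimicking peaks lost to exchange broadening.
    """
    cond = conditions_template or SolutionConditions(total_ligand=1e-3)
    ph = np.asarray(list(ph_grid), dtype=float)
    F, ids, _, ok = fraction_matrix(model, cond, ph)
    if not ok:
        raise RuntimeError("speciation failed to converge on the requested pH grid")
    ligand_ids = [s.id for s in model.species if s.n_l == 1]
    keep = [ids.index(sid) for sid in ligand_ids]
    D = basis.matrix(ligand_ids, nuclei)  # (S, N)
    delta = F[:, keep] @ D  # (P, N)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sd_ppm < 0 or not 0 <= missing_rate < 1:
        raise ValueError("noise_sd_ppm >= 0 and 0 <= missing_rate < 1 required")
    if noise_sd_ppm > 0:
        delta = delta + rng.normal(0.0, noise_sd_ppm, size=delta.shape)
    mask = np.zeros(delta.shape, dtype=bool)
    if missing_rate > 0:
        mask = rng.random(delta.shape) < missing_rate
        for i in range(mask.shape[0]):  # keep at least one observation per point
            if mask[i].all():
                mask[i, rng.integers(mask.shape[1])] = False

    points = []
    for i, p in enumerate(ph):
        observed = {
            nuc: float(delta[i, j]) for j, nuc in enumerate(nuclei) if not mask[i, j]
        }
        points.append(TitrationPoint(ph=float(p), observed=observed))
    return TitrationDataset(points=tuple(points), nuclei=tuple(nuclei), conditions_template=cond)


def gen_conformer_series(
    delta_h: float,
    delta_s: float,
    t_grid: Sequence[float] = tuple(range(274, 284)),
    ln_k_noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int | np.random.Generator | None = None,
    mg_equivalents: float | None = None,
    ph_star: float | None = None,
) -> ConformerSeries:
    """K(T) = exp(-(dH - T dS)/RT) with multiplicative log-normal noise."""
    t = np.asarray(list(t_grid), dtype=float)
    if (t <= 0).any():
        raise ValueError("temperatures must be positive (Kelvin)")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = ThermoParams(delta_h, delta_s)
    points = []
    for rep in range(1, replicates + 1):
        k = np.array([params.k_at(ti) for ti in t])
        if ln_k_noise_sd > 0:
            k = k * np.exp(rng.normal(0.0, ln_k_noise_sd, size=k.size))
        points.extend(
            ConformerPoint(float(ti), float(ki), replicate=rep) for ti, ki in zip(t, k)
        )
    return ConformerSeries(tuple(points), mg_equivalents=mg_equivalents, ph_star=ph_star)


def gen_itc(
    protocol: ITCProtocol,
    params: BindingParams,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Isotherm:
    """Seeded wrapper around :func:`inspeq.itc_binding.simulate_isotherm`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return simulate_isotherm(protocol, params, noise_sd=noise_sd, seed=rng)
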