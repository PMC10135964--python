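"""Mass-balance speciation solver for H+/K+/Mg2+-ligand models.

Given a :class:`~inspeq.chem_model.ChemicalModel` and total (analytical)
concentrations of ligand, K+ and Mg2+ at a fixed pH, solves the coupled
mass-balance equations

    T_X = [X]_free + sum_j n_{X,j} * c_j ,
    c_j = beta_j * [H]^h_j * [K]^k_j * [Mg]^m_j * [L]^l_j ,

for the free concentrations.  Protons are buffered: [H+] = 10**-pH is an
input, not a mass-balanced unknown (no hydroxo species are modelled).

The solver is a damped Newton iteration on log10 free concentrations,
which keeps all concentrations positive and remains stable for the very
large cumulative constants of highly charged ligands (residuals are
evaluated in log space with shifted exponentials, so no overflow occurs
even from poor starting points).  Grids of pH values are solved in a
single vectorized batch; stragglers are re-solved with warm starts from
the nearest converged neighbour (continuation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .chem_model import ChemicalModel

__all__ = [
    "SolutionConditions",
    "SpeciationResult",
    "MostAbundant",
    "solve_point",
    "solve_grid",
    "speciation_diagram",
    "most_abundant_species",
]

#: component order used internally
_COMPONENTS = ("L", "K", "Mg")

#: max relative mass-balance error accepted as converged
REL_TOL = 1e-10
MAX_ITER = 200
MAX_HALVINGS = 20


@dataclass(frozen=True)
class SolutionConditions:
    """Analytical totals (mol/L) and buffered pH of one solution."""

    total_ligand: float
    total_k: float = 0.0
    total_mg: float = 0.0
    ph: float = 7.0

    def __post_init__(self) -> None:
        for name in ("total_ligand", "total_k", "total_mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"ph must lie in [0, 14], got {self.ph}")

    def at_ph(self, ph: float) -> "SolutionConditions":
        return SolutionConditions(self.total_ligand, self.total_k, self.total_mg, ph)


@dataclass
class SpeciationResult:
    """Free and complexed concentrations at one solution condition."""

    ph: float
    free: dict[str, float]
    concentrations: dict[str, float]
    ligand_fractions: dict[str, float]
    converged: bool
    residual: float
    iterations: int = 0


class MostAbundant(NamedTuple):
    species_id: str
    fraction: float
    tied: bool


class _Stoich:
    """Stoichiometric arrays extracted once per model."""

    def __init__(self, model: ChemicalModel):
        sp = model.species
        self.ids = [s.id for s in sp]
        self.h = np.array([s.n_h for s in sp], dtype=float)
        # columns: L, K, Mg
        self.N = np.array([[s.n_l, s.n_k, s.n_mg] for s in sp], dtype=float)
        self.log_beta = np.array([s.log_beta for s in sp], dtype=float)


def _solve_batch(
    st: _Stoich,
    ph: np.ndarray,
    totals: Sequence[float],
    log_beta: np.ndarray | None = None,
    u0: np.ndarray | None = None,
    rel_tol: float = REL_TOL,
    max_iter: int = MAX_ITER,
):
    """Solve all pH points at once.

    Returns (logc, u_full, converged, residual, iterations) where ``logc``
    is (P, S) log10 species concentrations and ``u_full`` is (P, 3) log10
    free concentrations over (L, K, Mg) with -inf for absent components.
    """
    ph = np.asarray(ph, dtype=float)
    P = ph.size
    lb = st.log_beta if log_beta is None else np.asarray(log_beta, dtype=float)
    totals = np.asarray(totals, dtype=float)
    active = np.flatnonzero(totals > 0)
    if active.size == 0:
        raise ValueError("at least one total concentration must be positive")

    # species requiring a component whose total is zero can never form
    absent = np.flatnonzero(totals == 0)
    feasible = ~(st.N[:, absent] > 0).any(axis=1)
    lb_eff = np.where(feasible, lb, -np.inf)

    Na = st.N[:, active]  # (S, C)
    C = active.size
    log_tot = np.log10(totals[active])

    if u0 is None:
        u = np.tile(np.log10(0.1 * totals[active]), (P, 1))
    else:
        u = np.array(u0, dtype=float).reshape(P, C).copy()

    tol_r = rel_tol / math.log(10)

    # per-component term lists: species columns with n_{x} > 0.
    # The free ligand is itself a species (log_beta = 0), so its balance
    # needs no separate free-ion term; free K+ and Mg2+ are solver
    # unknowns only and get an explicit term.
    sel = [np.flatnonzero(Na[:, x] > 0) for x in range(C)]
    logw = [np.log10(Na[s, x]) for x, s in zip(range(C), sel)]
    free_term = [active[x] != 0 for x in range(C)]

    def logc_of(uu: np.ndarray, ph_sub: np.ndarray) -> np.ndarray:
        return lb_eff[None, :] - np.outer(ph_sub, st.h) + uu @ Na.T

    def residual(uu: np.ndarray, ph_sub: np.ndarray, with_jac: bool):
        lc = logc_of(uu, ph_sub)
        r = np.empty((uu.shape[0], C))
        J = np.empty((uu.shape[0], C, C)) if with_jac else None
        for x in range(C):
            blocks = [lc[:, sel[x]] + logw[x][None, :]]
            if free_term[x]:
                blocks.append(uu[:, [x]])
            terms = np.concatenate(blocks, axis=1)
            M = terms.max(axis=1, keepdims=True)
            E = np.exp((terms - M) * math.log(10))  # 10**(terms - M)
            S = E.sum(axis=1)
            r[:, x] = M[:, 0] + np.log10(S) - log_tot[x]
            if with_jac:
                ns = sel[x].size
                wc = E[:, :ns]  # n_x,j * c_j (shifted units)
                for y in range(C):
                    num = wc @ Na[sel[x], y]
                    if free_term[x] and y == x:
                        num = num + E[:, -1]
                    J[:, x, y] = num / S
        return r, J

    # Far from the solution the full Newton direction can be poor (the
    # balances are dominated by the same highly charged complexes, making
    # the Jacobian near-singular), so a damped Jacobi step -- each free
    # concentration against its own balance -- is used until the residual
    # is O(1), after which full Newton with backtracking takes over.
    conv = np.zeros(P, dtype=bool)
    r, _ = residual(u, ph, with_jac=False)
    iters = np.zeros(P, dtype=int)
    for it in range(max_iter):
        conv |= np.abs(r).max(axis=1) < tol_r
        todo = np.flatnonzero(~conv)
        if todo.size == 0:
            break
        ut = u[todo]
        pht = ph[todo]
        rt, Jt = residual(ut, pht, with_jac=True)
        phi0 = np.abs(rt).max(axis=1)
        far = phi0 >= 0.5
        try:
            step = np.linalg.solve(Jt, rt[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.array(
                [np.linalg.lstsq(Jt[i], rt[i], rcond=None)[0] for i in range(len(todo))]
            )
        if far.any():
            diag = np.einsum("pxx->px", Jt)
            step[far] = np.clip(0.5 * rt[far] / diag[far], -2.0, 2.0)
        np.clip(step, -5.0, 5.0, out=step)
        alpha = np.ones(todo.size)
        near = ~far
        if near.any():
            for _ in range(MAX_HALVINGS):
                u_try = ut - alpha[:, None] * step
                r_try, _ = residual(u_try, pht, with_jac=False)
                worse = near & (np.abs(r_try).max(axis=1) > phi0)
                if not worse.any():
                    break
                alpha[worse] *= 0.5
        u[todo] = ut - alpha[:, None] * step
        iters[todo] = it + 1
        r, _ = residual(u, ph, with_jac=False)
    conv |= np.abs(r).max(axis=1) < tol_r

    # continuation rescue: re-solve stragglers from the nearest converged point
    if not conv.all() and conv.any():
        good = np.flatnonzero(conv)
        for p in np.flatnonzero(~conv):
            nearest = good[np.argmin(np.abs(ph[good] - ph[p]))]
            lc2, u2, c2, r2, i2 = _solve_batch(
                st, ph[[p]], totals, lb, u0=u[[nearest]], rel_tol=rel_tol, max_iter=max_iter
            )
            if c2[0]:
                u[p] = u2[0, active]
                conv[p] = True
                iters[p] += i2[0]
        r, _ = residual(u, ph, with_jac=False)

    logc = logc_of(u, ph)
    u_full = np.full((P, 3), -np.inf)
    u_full[:, active] = u
    res_rel = np.abs(np.exp(r * math.log(10)) - 1.0).max(axis=1)
    return logc, u_full, conv, res_rel, iters


def _result_from_arrays(st, model, ph, logc, u_full, conv, res, iters, total_ligand):
    c = np.power(10.0, np.clip(logc, -320, 300))
    free = {
        name: (0.0 if not np.isfinite(u_full[k]) else float(10.0 ** u_full[k]))
        for k, name in enumerate(_COMPONENTS)
    }
    fractions = c / total_ligand
    return SpeciationResult(
        ph=float(ph),
        free=free,
        concentrations={sid: float(ci) for sid, ci in zip(st.ids, c)},
        ligand_fractions={sid: float(fi) for sid, fi in zip(st.ids, fractions)},
        converged=bool(conv),
        residual=float(res),
        iterations=int(iters),
    )


def solve_point(model: ChemicalModel, cond: SolutionConditions) -> SpeciationResult:
    """Solve one solution condition; raises on invalid input, flags non-convergence."""
    if cond.total_ligand <= 0:
        raise ValueError("total_ligand must be positive to compute ligand fractions")
    st = _Stoich(model)
    totals = (cond.total_ligand, cond.total_k, cond.total_mg)
    logc, u_full, conv, res, iters = _solve_batch(st, np.array([cond.ph]), totals)
    return _result_from_arrays(
        st, model, cond.ph, logc[0], u_full[0], conv[0], res[0], iters[0], cond.total_ligand
    )


def solve_grid(
    model: ChemicalModel,
    cond_template: SolutionConditions,
    ph_grid: Sequence[float],
) -> list[SpeciationResult]:
    """Solve a pH grid with a shared set of totals (batched with continuation)."""
    ph = np.asarray(list(ph_grid), dtype=float)
    if cond_template.total_ligand <= 0:
        raise ValueError("total_ligand must be positive")
    st = _Stoich(model)
    totals = (cond_template.total_ligand, cond_template.total_k, cond_template.total_mg)
    logc, u_full, conv, res, iters = _solve_batch(st, ph, totals)
    return [
        _result_from_arrays(
            st, model, ph[i], logc[i], u_full[i], conv[i], res[i], iters[i],
            cond_template.total_ligand,
        )
        for i in range(ph.size)
    ]


def fraction_matrix(
    model: ChemicalModel,
    cond_template: SolutionConditions,
    ph: np.ndarray,
    log_beta_override: dict[str, float] | None = None,
    u0: np.ndarray | None = None,
):
    """Low-level: (P, S) ligand-fraction matrix for a pH grid.

    Used by the titration fitter, where the constants change per optimizer
    iteration; ``u0`` warm-starts from the previous iteration's solution.
    Returns (F, ids, u, all_converged).
    """
    st = _Stoich(model)
    lb = st.log_beta.copy()
    if log_beta_override:
        index = {sid: i for i, sid in enumerate(st.ids)}
        for sid, val in log_beta_override.items():
            lb[index[sid]] = val
    totals = (cond_template.total_ligand, cond_template.total_k, cond_template.total_mg)
    active = [i for i, t in enumerate(totals) if t > 0]
    logc, u_full, conv, res, iters = _solve_batch(st, ph, totals, log_beta=lb, u0=u0)
    F = np.power(10.0, np.clip(logc, -320, 300)) / cond_template.total_ligand
    return F, st.ids, u_full[:, active], bool(conv.all())


def speciation_diagram(
    model: ChemicalModel,
    cond_template: SolutionConditions,
    ph_grid: Sequence[float],
) -> pd.DataFrame:
    """Species-distribution table over a monotone pH grid.

    Columns: ``ph``, ``free_L``, ``free_K``, ``free_Mg`` then one
    ligand-fraction column per species id.
    """
    ph = np.asarray(list(ph_grid), dtype=float)
    d = np.diff(ph)
    if ph.size > 1 and not ((d > 0).all() or (d < 0).all()):
        raise ValueError("ph_grid must be strictly monotone")
    results = solve_grid(model, cond_template, ph)
    bad = [r.ph for r in results if not r.converged]
    if bad:
        raise RuntimeError(f"speciation failed to converge at pH {bad}")
    rows = []
    for r in results:
        row = {
            "ph": r.ph,
            "free_L": r.free["L"],
            "free_K": r.free["K"],
            "free_Mg": r.free["Mg"],
        }
        row.update({sid: r.ligand_fractions[sid] for sid in model.ids})
        rows.append(row)
    return pd.DataFrame(rows)


def most_abundant_species(result: SpeciationResult) -> MostAbundant:
    """Argmax of the ligand fractions; exact ties break lexicographically."""
    if not result.converged:
        raise ValueError("cannot rank species of a non-converged speciation result")
    best = max(result.ligand_fractions.values())
    tied = sorted(sid for sid, f in result.ligand_fractions.items() if f == best)
    return MostAbundant(species_id=tied[0], fraction=best, tied=len(tied) > 1)


def mean_protonation(result: SpeciationResult, model: ChemicalModel) -> float:
    """Ligand-fraction-weighted mean number of bound protons."""
    return float(
        sum(model.get(sid).n_h * f for sid, f in result.ligand_fractions.items())
    )
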