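"""Independent brute-force oracles used to cross-check the fast solvers.

These deliberately avoid the package's Newton machinery: nested interval
bisection on the monotone mass-balance excess functions, and a direct
root solve of the binding equilibrium for ITC heats.
"""

import numpy as np
from scipy.optimize import brentq


def _total_calc(model, ph, free_l, free_k, free_mg, component):
    """Analytical total of one component implied by trial free concentrations."""
    tot = {"L": 0.0, "K": free_k, "Mg": free_mg}[component]
    for s in model.species:
        logc = (
            s.log_beta
            - s.n_h * ph
            + s.n_l * np.log10(free_l)
            + (s.n_k * np.log10(free_k) if s.n_k else 0.0)
            + (s.n_mg * np.log10(free_mg) if s.n_mg else 0.0)
        )
        c = 10.0**logc
        n = {"L": s.n_l, "K": s.n_k, "Mg": s.n_mg}[component]
        tot += n * c
    return tot


def brute_force_speciation(model, cond, lo=-60.0, hi=2.0, xtol=1e-14):
    """Solve <=2-unknown models by (nested) bisection on log10 free concs.

    Returns dict species id -> concentration.  Requires total_mg == 0 and,
    when total_k > 0, uses an outer bisection on log10[K] with an inner
    solve of the ligand balance (both excess functions are monotone).
    """
    assert cond.total_mg == 0, "oracle supports at most 2 unknowns (L, K)"

    def solve_l(free_k):
        f = lambda ul: _total_calc(model, cond.ph, 10.0**ul, free_k, 0.0, "L") - cond.total_ligand
        return 10.0 ** brentq(f, lo, np.log10(cond.total_ligand), xtol=xtol)

    if cond.total_k == 0:
        free_k = 0.0
        free_l = solve_l(1e-300)  # effectively zero K
    else:
        def g(uk):
            fk = 10.0**uk
            fl = solve_l(fk)
            return _total_calc(model, cond.ph, fl, fk, 0.0, "K") - cond.total_k

        uk = brentq(g, lo, np.log10(cond.total_k), xtol=xtol)
        free_k = 10.0**uk
        free_l = solve_l(free_k)

    out = {}
    for s in model.species:
        logc = (
            s.log_beta
            - s.n_h * cond.ph
            + s.n_l * np.log10(free_l)
            + (s.n_k * np.log10(free_k) if s.n_k else 0.0)
        )
        out[s.id] = 10.0**logc
    return out, {"L": free_l, "K": free_k}


def brute_force_itc_heats(protocol, n, k_d, delta_h, offset=0.0):
    """Per-injection heats from a direct root solve of the binding quadratic.

    Solves X_t = [X] + [X]*S/(K_d + [X]) for free ligand [X] at every
    injection (S = n*M_t total sites), forms Q = V0*dH*[bound], and
    applies the same displacement bookkeeping as the instrument model.
    """
    mt, xt = protocol.cell_concentrations()
    v0_l = protocol.cell_volume_ul * 1e-6
    q = np.empty(len(xt))
    for i, (m, x) in enumerate(zip(mt, xt)):
        s = n * m

        def excess(free_x):
            return free_x + free_x * s / (k_d + free_x) - x

        free = brentq(excess, 0.0, x, xtol=1e-24, rtol=1e-15)
        bound = x - free
        q[i] = bound * delta_h * v0_l
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = np.asarray(protocol.injection_volumes_ul) / protocol.cell_volume_ul
    raw = q + dv * (q + q_prev) / 2.0 - q_prev
    moles = np.asarray(protocol.injection_volumes_ul) * 1e-6 * protocol.syringe_conc
    return raw / moles + offset
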