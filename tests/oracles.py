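"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form code paths they check: chain
cumulated activities come from a stiff ODE integration of the atom-number
balance with quadrature accumulators, and LQ parameters from a brute-force
grid search refined by a derivative-free simplex minimiser.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp


def ode_cumulated_activity(chain, a0: float, t0: float, t1: float) -> dict[str, float]:
    """Cumulated activity of every chain member over [t0, t1] by stiff ODE.

    State: atom numbers N_i (in units of MBq*s) plus running integrals of
    activity lambda_i * N_i; LSODA at rtol 1e-10.
    """
    names = [n.name for n in chain.members]
    lam = {n.name: n.decay_constant for n in chain.members}
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)

    def rhs(t, y):
        d_atoms = np.zeros(k)
        d_cum = np.zeros(k)
        for i, n in enumerate(names):
            act = lam[n] * y[i]
            d_atoms[i] -= act
            d_cum[i] = act
            for parent, br in chain.parents_of(n):
                d_atoms[i] += br * lam[parent] * y[idx[parent]]
        return np.concatenate([d_atoms, d_cum])

    y0 = np.zeros(2 * k)
    y0[idx[chain.parent.name]] = a0 / chain.parent.decay_constant
    t_eval = [t0, t1] if t0 > 0 else [t1]
    sol = solve_ivp(
        rhs, (0.0, t1), y0, method="LSODA", rtol=1e-10, atol=1e-18, t_eval=t_eval
    )
    assert sol.success, sol.message
    if t0 > 0:
        return {n: float(sol.y[k + idx[n], 1] - sol.y[k + idx[n], 0]) for n in names}
    return {n: float(sol.y[k + idx[n], 0]) for n in names}


def brute_force_lq(doses, neg_log_sf) -> tuple[float, float]:
    """Grid search + simplex refinement of least-squares LQ parameters."""
    d = np.asarray(doses, dtype=float)
    y = np.asarray(neg_log_sf, dtype=float)

    def sse(p):
        a, b = p
        if a < 0 or b < 0:
            return np.inf
        r = y - a * d - b * d * d
        return float(r @ r)

    grid_a = np.linspace(0.0, 2.0, 201)
    grid_b = np.linspace(0.0, 0.5, 201)
    best = min(((sse((a, b)), a, b) for a in grid_a for b in grid_b))
    res = optimize.minimize(
        sse, [best[1], best[2]], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10000},
    )
    return float(res.x[0]), float(res.x[1])
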