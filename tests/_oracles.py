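"""Independent oracles for cross-checking the implementation.

These deliberately avoid the package's matrix-exponential code path:
transition probabilities come from numerically integrating the
Kolmogorov forward equations dP/dt = P Q(t) with a high-order ODE
solver, under the same piecewise-constant age-freezing scheme.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_transition_matrix(model, age0, dt, covariates=None, approx_step=1.0,
                          rtol=1e-12, atol=1e-14):
    n = model.structure.n_states
    p = np.eye(n)
    t = 0.0
    while t < dt - 1e-12:
        h = min(approx_step, dt - t)
        q = model.intensity_matrix(age0 + t, covariates)

        def rhs(_s, y):
            return (y.reshape(n, n) @ q).ravel()

        sol = solve_ivp(rhs, (0.0, h), p.ravel(), method="DOP853",
                        rtol=rtol, atol=atol)
        p = sol.y[:, -1].reshape(n, n)
        t += h
    return p


def ode_panel_loglik(model, data, approx_step=1.0):
    """Interval-censored panel log-likelihood via the ODE oracle."""
    iv = data.intervals()
    dead = data.dead_state
    live = [s - 1 for s in model.structure.live_states]
    total = 0.0
    for row in iv.itertuples():
        z = None
        if model.covariate_names:
            z = np.array([getattr(row, c) for c in model.covariate_names])
        p = ode_transition_matrix(model, row.age0, row.dt, z, approx_step)
        if row.to_state == dead:
            q = model.intensity_matrix(row.age0 + row.dt, z)[:, dead - 1]
            total += np.log(sum(p[row.from_state - 1, s] * q[s] for s in live))
        else:
            total += np.log(p[row.from_state - 1, row.to_state - 1])
    return total
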