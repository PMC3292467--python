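"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's analytic machinery: the compartment
system is integrated as an ODE, frame means are obtained by quadrature of the
integrated state, and box counting is re-done by dense brute-force
rasterization.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_impulse_response(params, t_eval):
    """h(t) by stiff ODE integration from the post-impulse state [K1, 0]."""

    def rhs(_t, x):
        return [
            -(params.k2 + params.k3) * x[0] + params.k4 * x[1],
            params.k3 * x[0] - params.k4 * x[1],
        ]

    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval.max())),
        [params.K1, 0.0],
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-11,
        atol=1e-14,
    )
    return sol.y.sum(axis=0)


def ode_frame_means(params, input_model, schedule):
    """Frame-averaged C_pet by ODE integration of the running integral."""
    amps = np.array([a for a, _ in input_model.terms])
    lams = np.array([lam for _, lam in input_model.terms])
    t0 = input_model.delay_t0

    def cp(t):
        u = t - t0
        if u < 0:
            return 0.0
        return float(np.sum(amps * np.exp(-lams * u)))

    def rhs(t, x):
        c = cp(t)
        return [
            params.K1 * c - (params.k2 + params.k3) * x[0] + params.k4 * x[1],
            params.k3 * x[0] - params.k4 * x[1],
            (1.0 - params.vb) * (x[0] + x[1]) + params.vb * c,
        ]

    bounds = np.union1d(schedule.start_min, schedule.end_min)
    sol = solve_ivp(
        rhs,
        (0.0, float(bounds[-1])),
        [0.0, 0.0, 0.0],
        t_eval=bounds,
        method="LSODA",
        rtol=1e-11,
        atol=1e-12,
        max_step=0.25,
    )
    cumulative = dict(zip(sol.t, sol.y[2]))
    return np.array(
        [
            (cumulative[e] - cumulative[s]) / (e - s)
            for s, e in zip(schedule.start_min, schedule.end_min)
        ]
    )


def brute_force_box_count(points, g, step=None):
    """Box count by pure-Python rasterization of each segment.

    ``step`` defaults to the contract's 1/(10 g); pass a smaller value for a
    denser lower-bound check.
    """
    pts = np.clip(np.asarray(points, dtype=float), 0.0, 1.0)
    if step is None:
        step = 1.0 / (10 * g)
    cells = set()

    def cell(x, y):
        return (min(int(np.floor(x * g)), g - 1), min(int(np.floor(y * g)), g - 1))

    for x, y in pts:
        cells.add(cell(x, y))
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        length = float(np.hypot(x1 - x0, y1 - y0))
        n = int(np.ceil(length / step))
        for t in np.linspace(0.0, 1.0, n + 1):
            cells.add(cell(x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
    return len(cells)
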