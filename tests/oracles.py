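"""Independent oracles: numeric ODE integration of the infusion schedule and
dense Gauss-Hermite quadrature of the random-effect marginal likelihood."""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import roots_hermite

from vancopk import DoseEvent, StructuralParams, concentration
from vancopk.estimation import _Objective


def ode_concentration(doses, params: StructuralParams, times):
    """Concentration by numerically integrating dA/dt = in(t) - k*A."""
    k = params.k

    def rate_in(t):
        return sum(
            d.rate for d in doses if d.start_time <= t < d.end_time
        )

    def rhs(t, y):
        return [rate_in(t) - k * y[0]]

    t_end = float(max(times)) if len(np.atleast_1d(times)) else 0.0
    breaks = sorted(
        {0.0, t_end}
        | {d.start_time for d in doses}
        | {d.end_time for d in doses if d.end_time <= t_end}
    )
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.0],
        t_eval=np.atleast_1d(times).astype(float),
        max_step=0.25,
        rtol=1e-10,
        atol=1e-12,
        method="LSODA",
    )
    return sol.y[0] / params.v


def gauss_hermite_ofv(obj: _Objective, cl_tv, beta, omega, s1, s2, n_nodes=10000):
    """Constant-free -2 log marginal likelihood by dense (non-adaptive)
    Gauss-Hermite quadrature, one subject at a time."""
    x, w = roots_hermite(n_nodes)
    keep = w > 0
    x, logw = x[keep], np.log(w[keep])
    log_cl_typ = np.log(cl_tv) + (
        obj.X @ np.asarray(beta) if obj.n_beta else np.zeros(obj.n_subjects)
    )
    v = obj.spec.v
    total = 0.0
    for i in range(obj.n_subjects):
        idx = np.flatnonzero(obj.design.obs_subject == i)
        y = obj.design.y[idx]
        t = obj.design.obs_time[idx]
        doses = [
            DoseEvent(row.time, row.amount, row.duration)
            for row in _subject_doses(obj, i)
        ]
        ll = np.empty(len(x))
        for j, eta in enumerate(np.sqrt(2.0) * omega * x):
            cl = np.exp(log_cl_typ[i] + eta)
            f = np.atleast_1d(
                concentration(doses, StructuralParams(cl=cl, v=v), t)
            )
            g2 = s2 * s2 + (s1 * f) ** 2
            r = y - f
            ll[j] = -0.5 * np.sum(np.log(g2) + r * r / g2)
        m = logw + ll
        mx = m.max()
        total += -2.0 * (mx + np.log(np.sum(np.exp(m - mx))) - 0.5 * np.log(np.pi))
    return total


def _subject_doses(obj, i):
    # reconstruct the subject's dose rows from the stored table reference
    table = obj._table
    sid = table.subject_ids[i]
    return table.doses[table.doses["id"] == sid].itertuples()
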