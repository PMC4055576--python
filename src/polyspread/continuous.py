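"""Continuous-time deterministic equations and their integration.

Letting the time step shrink to zero (with every probability parameter
replaced by rate * dt) removes simultaneous transmissions: at most one
event can land in an infinitesimal window, so the uniform choice between
competing transmissions disappears and the contact term becomes bilinear.
For a general stimulation tensor Theta the per-node equations read

    dp_i[k]/dt = sum_{l != k} (drate[l, k] p_i[l] - drate[k, l] p_i[k])
               + sum_l p_i[l] sum_r grate[l, r] theta[l, r, k] s_i[r]
               - p_i[k] sum_r grate[k, r] s_i[r]

with s_i[r] = sum_j a_ij p_j[r] the expected number of neighbors in state
r. For the identity Theta the contact terms collapse to the classical form
in which dp_i[k]/dt depends only on the neighbors' state-k components:

    + sum_{l != k} grate[l, k] p_i[l] s_i[k]
    - sum_{l != k} grate[k, l] p_i[k] s_i[l]

(the matrix form of which is a Hadamard product of P with rate-weighted
neighbor sums). Rows of dP/dt sum to zero exactly.

Integration is fixed-step RK4 (default dt = 0.01) so that order-of-
consistency checks against the discrete-time solver are clean; adaptive
stepping is a documented extension point, not provided.
"""

from __future__ import annotations

import numpy as np

from .modelspec import ModelSpec, to_probabilities
from .netio import Network


def _check_rate(spec) -> None:
    if not spec.is_rate_form:
        raise ValueError("continuous-time equations need a rate-form spec; "
                         "convert with modelspec.to_rates")


def ode_rhs(P, spec: ModelSpec, network: Network) -> np.ndarray:
    """dP/dt for the full per-node system (N x m in, N x m out)."""
    _check_rate(spec)
    P = np.asarray(P, dtype=float)
    s = network.adjacency @ P                  # expected neighbors per state
    drate = spec.delta.copy()
    np.fill_diagonal(drate, 0.0)
    spont = P @ drate - P * drate.sum(axis=1)[None, :]
    exposure = s @ spec.gamma.T                # exposure[i, k] = sum_r grate[k,r] s_i[r]
    gain = np.zeros_like(P)
    for l in range(spec.m):
        gain += P[:, l:l + 1] * ((s * spec.gamma[l]) @ spec.theta[l])
    loss = P * exposure
    return spont + gain - loss


def ode_rhs_multiplex(P, mspec, mnetwork) -> np.ndarray:
    """Multiplex dP/dt: one spontaneous term plus a contact term per layer,
    each with its own rate matrix and adjacency. With a single layer this is
    exactly :func:`ode_rhs`."""
    _check_rate(mspec)
    P = np.asarray(P, dtype=float)
    drate = mspec.delta.copy()
    np.fill_diagonal(drate, 0.0)
    out = P @ drate - P * drate.sum(axis=1)[None, :]
    for alpha, lay in enumerate(mnetwork.layers):
        s = lay.adjacency @ P
        gam = mspec.gammas[alpha]
        for l in range(mspec.m):
            out += P[:, l:l + 1] * ((s * gam[l]) @ mspec.theta[l])
        out -= P * (s @ gam.T)
    return out


def integrate(P0, spec: ModelSpec, network: Network, t_end: float,
              dt: float = 0.01):
    """Fixed-step RK4 integration; returns (times, trajectory (T+1, N, m))."""
    _check_rate(spec)
    P = np.asarray(P0, dtype=float)
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1,) + P.shape)
    out[0] = P
    for t in range(n_steps):
        k1 = ode_rhs(P, spec, network)
        k2 = ode_rhs(P + 0.5 * dt * k1, spec, network)
        k3 = ode_rhs(P + 0.5 * dt * k2, spec, network)
        k4 = ode_rhs(P + dt * k3, spec, network)
        P = P + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[t + 1] = P
    return times, out


def discrete_continuous_consistency(spec_rates: ModelSpec, network: Network,
                                    P0, t_end: float,
                                    dts=(0.1, 0.05, 0.025, 0.0125),
                                    ref_dt: float = 1e-3):
    """First-order consistency of the discrete solver with the ODE limit.

    For each dt the discrete deterministic solver is run with the
    probability-form parameters gamma = grate * dt, delta = drate * dt and
    its endpoint at ``t_end`` compared with an RK4 reference. Returns
    ``(dts, deviations, slope)`` where slope is the fitted log-log order
    (about 1 for this reactive-process limit).
    """
    from . import deterministic

    _check_rate(spec_rates)
    _, ref = integrate(P0, spec_rates, network, t_end, dt=ref_dt)
    endpoint = ref[-1]
    devs = []
    for dt in dts:
        pspec = to_probabilities(spec_rates, dt)
        n_steps = int(round(t_end / dt))
        traj = deterministic.run_field(P0, pspec, network, n_steps,
                                       backend="approx")
        devs.append(float(np.max(np.abs(traj[-1] - endpoint))))
    devs = np.array(devs)
    slope = float(np.polyfit(np.log(np.asarray(dts)), np.log(devs), 1)[0])
    return np.asarray(dts), devs, slope


def maki_thompson_homogeneous(k_degree: float, lambda_: float, alpha: float,
                              sigma: float, y0, t_end: float,
                              dt: float = 0.01):
    """Homogeneous mean-field Maki-Thompson rumor model.

    On a k-regular graph with identical initial conditions every node obeys
    the same scalar system for (i, s, r) = (ignorant, spreader, stifler):

        di/dt = -lambda k i s
        ds/dt =  lambda k i s - alpha k s (s + r) - sigma s
        dr/dt =  alpha k s (s + r) + sigma s

    Integrated with the same fixed-step RK4 as the full system so the two
    agree node-for-node on k-regular graphs. Returns (times, (T+1) x 3).
    """
    y = np.asarray(y0, dtype=float)
    if y.shape != (3,):
        raise ValueError("y0 must be (i0, s0, r0)")

    def rhs(y):
        i, s, r = y
        inf = lambda_ * k_degree * i * s
        stifle = alpha * k_degree * s * (s + r) + sigma * s
        return np.array([-inf, inf - stifle, stifle])

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 3))
    out[0] = y
    for t in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[t + 1] = y
    return times, out
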