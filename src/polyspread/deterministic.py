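"""Deterministic discrete-time counterpart (NLDS) of the stochastic model.

Taking expectations of the synchronous update under the assumption that
nodes' marginal state distributions are independent turns the state vector
of each node into a probability mass vector p_i. One step maps the N x m
field P to

    p'_i[k] = sum_{l != k} delta[l, k] p_i[l]                (spontaneous in)
            + sum_l p_i[l] delta[l, l] qhat_i^{l -> k}       (contact in)
            + p_i[k] delta[k, k] h_i^k                       (stay)

where qhat_i^{l -> k} and h_i^k are the Theta-composed adoption and
no-adoption probabilities of node i computed for receiver state l (resp. k)
from its neighbors' current probability vectors. The ``approx`` backend uses
the tractable closed form (any degree); the ``exact`` backend evaluates the
configuration sum (guarded by the adoption-module budget). Note the l = k
term of the contact sum is the probability of "adopting" one's own state,
which together with the stay term keeps every row summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import adoption
from .modelspec import ModelSpec, MultiplexModelSpec, require_valid
from .netio import MultiplexNetwork, Network

ROW_SUM_TOL = 1e-9


@dataclass
class FixedPointReport:
    field: np.ndarray          # final N x m probability field
    fractions: np.ndarray      # macroscopic per-state fractions (column means)
    iterations: int
    converged: bool
    residual: float            # final L-inf step change
    residual_history: np.ndarray = None


def uniform_field(n: int, m: int) -> np.ndarray:
    return np.full((n, m), 1.0 / m)


def field_from_assignment(assignment, m: int) -> np.ndarray:
    """Degenerate 0/1 field matching a concrete state assignment."""
    assignment = np.asarray(assignment)
    return np.eye(m)[assignment]


def check_field(P: np.ndarray, tol: float = ROW_SUM_TOL) -> None:
    if np.any(P < -tol):
        raise ValueError("probability field has negative entries")
    if np.max(np.abs(P.sum(axis=1) - 1.0)) > tol:
        raise ValueError("probability field rows must sum to 1")


def _log_product_over_neighbors(adj, t: np.ndarray) -> np.ndarray:
    """h_i = prod_{j in N(i)} t_j for a per-node vector t in [0, 1]."""
    t = np.clip(t, 0.0, 1.0)
    zero = t <= 0.0
    safe = np.where(zero, 1.0, t)
    logh = adj @ np.log(safe)
    h = np.exp(logh)
    kills = adj @ zero.astype(float)
    h[kills > 0] = 0.0
    return h


def _adoption_all_states_approx(P, spec: ModelSpec, network: Network):
    """Vectorized approximate (q_hat, h) for every receiver state.

    Returns ``qhat`` with shape m x N x m (receiver state, node, adopted
    state) and ``h`` with shape N x m (node, receiver state).
    """
    n, m = P.shape
    adj = network.adjacency
    qhat = np.empty((m, n, m))
    h = np.empty((n, m))
    for k in range(m):
        g = spec.gamma[k]
        W = P * g                      # W[j, r] = gamma[k, r] p_j^r
        agg = adj @ W                  # agg[i, r] = sum_j a_ij gamma_kr p_j^r
        denom = agg.sum(axis=1)
        hk = _log_product_over_neighbors(adj, 1.0 - W.sum(axis=1))
        h[:, k] = hk
        share = np.divide(agg, denom[:, None],
                          out=np.zeros_like(agg), where=denom[:, None] > 0)
        q = share * (1.0 - hk)[:, None]
        qhat[k] = q @ spec.theta[k]
    return qhat, h


def _adoption_all_states_exact(P, spec: ModelSpec, network: Network):
    """Per-node exact (q_hat, h) for every receiver state via the
    count-distribution route (mathematically the full configuration sum)."""
    n, m = P.shape
    qhat = np.empty((m, n, m))
    h = np.empty((n, m))
    for i in range(n):
        qh_i, h_i = adoption.exact_adoption_all_states(
            P[network.neighbors(i)], spec.gamma, spec.theta)
        qhat[:, i, :] = qh_i
        h[i] = h_i
    return qhat, h


def _compose(P, spec, qhat, h):
    """Assemble the three-term update from per-receiver-state (qhat, h)."""
    m = spec.m
    stay = np.diag(spec.delta)                   # delta[k, k]
    off = spec.delta.copy()
    np.fill_diagonal(off, 0.0)
    P_next = P @ off                             # spontaneous arrivals
    for l in range(m):
        P_next += (P[:, l] * stay[l])[:, None] * qhat[l]
    P_next += P * stay[None, :] * h              # no dice move, no adoption
    return P_next


def step_field(P, spec: ModelSpec, network: Network,
               backend: str = "approx") -> np.ndarray:
    """One deterministic step of the probability field."""
    if spec.is_rate_form:
        raise ValueError("deterministic step needs a probability-form spec")
    P = np.asarray(P, dtype=float)
    if backend == "approx":
        qhat, h = _adoption_all_states_approx(P, spec, network)
    elif backend == "exact":
        qhat, h = _adoption_all_states_exact(P, spec, network)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return _compose(P, spec, qhat, h)


def run_field(P0, spec, network, n_steps: int, backend: str = "approx",
              check: bool = True):
    """Iterate ``n_steps`` steps; returns the (T+1, N, m) trajectory."""
    require_valid(spec)
    P = np.asarray(P0, dtype=float)
    if check:
        check_field(P)
    out = np.empty((n_steps + 1,) + P.shape)
    out[0] = P
    stepper = step_field_multiplex if isinstance(spec, MultiplexModelSpec) \
        else step_field
    for t in range(1, n_steps + 1):
        P = stepper(P, spec, network, backend=backend)
        if check:
            check_field(P)
        out[t] = P
    return out


def iterate_to_fixed_point(P0, spec, network, backend: str = "approx",
                           tol: float = 1e-10, max_iter: int = 100_000
                           ) -> FixedPointReport:
    """Iterate until the L-inf step change drops below ``tol``.

    Oscillatory systems (e.g. the three-innovation model) will not converge;
    that is reported through ``converged=False`` with the bounded residual
    history, never raised.
    """
    require_valid(spec)
    P = np.asarray(P0, dtype=float)
    check_field(P)
    stepper = step_field_multiplex if isinstance(spec, MultiplexModelSpec) \
        else step_field
    history = []
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        P_next = stepper(P, spec, network, backend=backend)
        residual = float(np.max(np.abs(P_next - P)))
        history.append(residual)
        P = P_next
        if residual < tol:
            break
    return FixedPointReport(
        field=P, fractions=P.mean(axis=0), iterations=it,
        converged=residual < tol, residual=residual,
        residual_history=np.array(history))


# ---------------------------------------------------------------------------
# multiplex
# ---------------------------------------------------------------------------

def step_field_multiplex(P, mspec: MultiplexModelSpec,
                         mnetwork: MultiplexNetwork,
                         backend: str = "approx") -> np.ndarray:
    """Multiplex deterministic step.

    Links from all layers compete in one pooled uniform choice; each
    (neighbor, layer) link transmits with its own layer's Gamma. The
    no-adoption probability factorizes over layers:

        h_i^k = prod_alpha prod_{j in N_alpha(i)} (1 - sum_l
                gamma^(alpha)[k, l] p_j^l).

    With one layer this reduces exactly to :func:`step_field`.
    """
    if mspec.is_rate_form:
        raise ValueError("deterministic step needs a probability-form spec")
    if backend != "approx":
        raise NotImplementedError("multiplex exact backend is not provided; "
                                  "use the single-layer exact route per layer")
    P = np.asarray(P, dtype=float)
    n, m = P.shape
    qhat = np.empty((m, n, m))
    h = np.empty((n, m))
    for k in range(m):
        agg = np.zeros((n, m))
        hk = np.ones(n)
        for alpha, lay in enumerate(mnetwork.layers):
            g = mspec.gammas[alpha][k]
            W = P * g
            agg += lay.adjacency @ W
            hk = hk * _log_product_over_neighbors(lay.adjacency,
                                                  1.0 - W.sum(axis=1))
        denom = agg.sum(axis=1)
        share = np.divide(agg, denom[:, None],
                          out=np.zeros_like(agg), where=denom[:, None] > 0)
        q = share * (1.0 - hk)[:, None]
        qhat[k] = q @ mspec.theta[k]
        h[:, k] = hk
    return _compose(P, mspec, qhat, h)
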