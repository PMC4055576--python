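"""Single-step adoption probabilities for the reactive process.

In one time step, every neighbor of a receiving node attempts to transmit
its current state over the shared link; a link carrying state ``l`` becomes
infectious independently with probability ``gamma_row[l]`` (``gamma_row`` is
the row of the transmission matrix for the receiver's current state). If at
least one link is infectious, the node picks one uniformly at random and is
exposed to the state carried by that link; exposure is then composed with
the stimulation tensor Theta to give the adopted state.

This module computes, for one receiver:

* ``q[l]`` — probability that state ``l`` is the uniformly chosen
  transmission (before Theta),
* ``h``    — probability that no link is infectious,
* ``q_hat`` — Theta-composed redistribution of the ``q`` mass,

exactly (several interchangeable backends) and approximately (the tractable
closed form used by the deterministic solver on large graphs).

Writing ``s_l`` for the number of infectious links carrying state ``l`` and
``S = sum_l s_l``, the exact chosen-transmission probability is
``q_l = E[s_l / S ; S > 0]`` with ``s_l ~ Binomial(n_l, g_l)`` independent
per state, and ``h = prod_l (1 - g_l)^{n_l}``. The approximation replaces
the random share ``s_l/S`` by the ratio of expectations:

    q*_l = (n_l g_l / sum_r n_r g_r) * (1 - prod_r (1 - g_r)^{n_r})

which is exact when only one state is transmissible (product form), when
all gammas are equal (the share is then deterministic given S), and for
n <= 1; ``h`` is always computed by its exact product form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

#: largest neighbor count handled by the 2^n bit-enumeration backend
ENUM_GUARD = 20
#: elementary-term budget for the literal configuration x event double sum
DETERMINISTIC_BUDGET = 10_000_000


class ComplexityError(RuntimeError):
    """Exact computation would exceed its guard; use the approximation."""


@dataclass(frozen=True)
class AdoptionResult:
    """q, Theta-composed q_hat and the no-adoption probability h."""

    q: np.ndarray
    h: float
    q_hat: np.ndarray = None

    def __post_init__(self):
        if self.q_hat is None:
            object.__setattr__(self, "q_hat", self.q)


def apply_theta(q: np.ndarray, theta_slice: np.ndarray) -> np.ndarray:
    """Stimulated adoption: q_hat[l] = sum_r theta[r, l] q[r].

    ``theta_slice`` is the m x m slice of Theta for the receiver's state.
    Mass-preserving because every row of the slice sums to one.
    """
    return np.asarray(q) @ np.asarray(theta_slice)


def _finish(q: np.ndarray, h: float, theta_slice) -> AdoptionResult:
    q_hat = apply_theta(q, theta_slice) if theta_slice is not None else None
    return AdoptionResult(q=q, h=float(h), q_hat=q_hat)


def no_adoption_prob_counts(counts, gamma_row) -> float:
    """h = prod_l (1 - g_l)^{n_l}: no neighbor transmits successfully."""
    counts = np.asarray(counts)
    g = np.asarray(gamma_row, dtype=float)
    return float(np.prod((1.0 - g) ** counts))


def no_adoption_prob_field(neighbor_probs, gamma_row) -> float:
    """Deterministic form: h = prod_j (1 - sum_l g_l p_j^l)."""
    P = np.atleast_2d(np.asarray(neighbor_probs, dtype=float))
    g = np.asarray(gamma_row, dtype=float)
    if P.shape[0] == 0:
        return 1.0
    return float(np.prod(1.0 - P @ g))


# ---------------------------------------------------------------------------
# exact backends, stochastic (integer counts) input
# ---------------------------------------------------------------------------

def _expand_states(counts) -> np.ndarray:
    """Per-neighbor state array for a neighbor-count vector."""
    return np.repeat(np.arange(len(counts)), counts)


def _enumeration_q(counts, g) -> tuple[np.ndarray, float]:
    """Literal sum over the 2^n infectious-link event vectors.

    Event vectors are indexed by the binary number whose least significant
    digit is the last component; the indexing is only a bookkeeping choice,
    the sum is over all of them.
    """
    states = _expand_states(counts)
    n, m = states.size, len(counts)
    q = np.zeros(m)
    h = 1.0
    if n == 0:
        return q, h
    gs = g[states]  # per-link success probability
    h = float(np.prod(1.0 - gs))
    onehot = np.eye(m)[states]  # n x m
    # chunk the 2^n event axis to bound memory at high n
    chunk = 1 << min(n, 16)
    powers = 1 << np.arange(n - 1, -1, -1)  # first component most significant
    for start in range(0, 1 << n, chunk):
        idx = np.arange(start, min(start + chunk, 1 << n))
        events = (idx[:, None] & powers[None, :]) > 0  # chunk x n
        probs = np.prod(np.where(events, gs, 1.0 - gs), axis=1)
        s = events.astype(float) @ onehot  # chunk x m, successes per state
        S = s.sum(axis=1)
        live = S > 0
        q += (s[live] * (probs[live] / S[live])[:, None]).sum(axis=0)
    return q, h


def _gauss_nodes(n: int):
    x, w = leggauss(max(n // 2 + 1, 1))
    # map from [-1, 1] to [0, 1]
    return 0.5 * (x + 1.0), 0.5 * w


def _polynomial_q(counts, g) -> tuple[np.ndarray, float]:
    """Exact q via the polynomial identity

        E[s_l / S ; S>0] = ∫_0^1 n_l g_l (1-g_l+g_l x)^{n_l-1}
                            prod_{j != l} (1-g_j+g_j x)^{n_j} dx,

    integrated exactly by Gauss-Legendre (the integrand has degree n-1).
    Scales to degrees in the thousands.
    """
    counts = np.asarray(counts)
    m = len(counts)
    n = int(counts.sum())
    q = np.zeros(m)
    h = no_adoption_prob_counts(counts, g)
    if n == 0:
        return q, h
    x, w = _gauss_nodes(n)
    base = 1.0 - g[:, None] + g[:, None] * x[None, :]  # m x nodes
    for l in range(m):
        if counts[l] == 0 or g[l] == 0:
            continue
        integrand = counts[l] * g[l] * base[l] ** (counts[l] - 1)
        for j in range(m):
            if j != l and counts[j] > 0:
                integrand = integrand * base[j] ** counts[j]
        q[l] = float(integrand @ w)
    return q, h


def exact_adoption_stochastic(counts, gamma_row, theta_slice=None,
                              enum_guard: int = ENUM_GUARD) -> AdoptionResult:
    """Exact adoption probabilities for a fixed neighbor-state count vector.

    Uses the 2^n event-vector enumeration for n <= ``enum_guard`` and the
    (equally exact) polynomial backend beyond it.
    """
    counts = np.asarray(counts, dtype=int)
    g = np.asarray(gamma_row, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative neighbor counts")
    n = int(counts.sum())
    if n <= enum_guard:
        q, h = _enumeration_q(counts, g)
    else:
        q, h = _polynomial_q(counts, g)
    return _finish(q, h, theta_slice)


def exact_adoption_polynomial_oracle(counts, gamma_row,
                                     theta_slice=None) -> AdoptionResult:
    """The polynomial-integral backend exposed directly (independent exact
    route used to cross-check the enumeration)."""
    counts = np.asarray(counts, dtype=int)
    g = np.asarray(gamma_row, dtype=float)
    q, h = _polynomial_q(counts, g)
    return _finish(q, h, theta_slice)


# ---------------------------------------------------------------------------
# exact backends, deterministic (probability vector) input
# ---------------------------------------------------------------------------

def exact_adoption_deterministic(neighbor_probs, gamma_row, theta_slice=None,
                                 budget: int = DETERMINISTIC_BUDGET
                                 ) -> AdoptionResult:
    """The literal double sum over neighbor-state configurations and
    infectious-link event vectors.

    Every configuration (variation with repetition, m^k of them) is weighted
    by the product of the neighbors' marginal probabilities — the
    independence assumption — and contributes its exact event-enumerated
    adoption probabilities. O(m^k 2^k); guarded, intended for small graphs
    and as the reference for the fast route below.
    """
    P = np.atleast_2d(np.asarray(neighbor_probs, dtype=float))
    k, m = P.shape
    if k and (m ** k) * (2 ** k) > budget:
        raise ComplexityError(
            f"m^k 2^k = {(m ** k) * (2 ** k):.3g} exceeds budget {budget:.3g}; "
            "use approx_adoption or the fast exact route")
    g = np.asarray(gamma_row, dtype=float)
    q = np.zeros(m)
    h = 0.0
    cache: dict[tuple, tuple[np.ndarray, float]] = {}
    for config in itertools.product(range(m), repeat=k):
        weight = 1.0
        for j, c in enumerate(config):
            weight *= P[j, c]
        if weight == 0.0:
            continue
        counts = tuple(np.bincount(config, minlength=m))
        if counts not in cache:
            cache[counts] = _enumeration_q(np.array(counts), g)
        qc, hc = cache[counts]
        q += weight * qc
        h += weight * hc
    return _finish(q, h, theta_slice)


def _counts_distribution(P: np.ndarray) -> dict[tuple, float]:
    """Joint distribution of the neighbor-state count vector under neighbor
    independence, by dynamic programming over neighbors."""
    k, m = P.shape
    dist = {tuple([0] * m): 1.0}
    for j in range(k):
        nxt: dict[tuple, float] = {}
        # renormalize: a row-sum rounding error of eps would otherwise be
        # amplified by a factor of k per solver step
        pj = np.clip(P[j], 0.0, None)
        pj = pj / pj.sum()
        for counts, w in dist.items():
            for l in range(m):
                if pj[l] == 0.0:
                    continue
                key = list(counts)
                key[l] += 1
                key = tuple(key)
                nxt[key] = nxt.get(key, 0.0) + w * pj[l]
        dist = nxt
    return dist


def _counts_tensor(P: np.ndarray, kmax: int) -> np.ndarray:
    """Dense joint count distribution: entry (n_1, ..., n_m) is the
    probability that the neighbor states realize that count vector.
    Convolution over neighbors, one shift-add per state."""
    k, m = P.shape
    dist = np.zeros((kmax + 1,) * m)
    dist[(0,) * m] = 1.0
    grow = [slice(1, kmax + 1)]
    keep = [slice(0, kmax)]
    full = [slice(None)]
    for j in range(k):
        # renormalize: a row-sum rounding error of eps would otherwise be
        # amplified by a factor of k per solver step
        pj = np.clip(P[j], 0.0, None)
        pj = pj / pj.sum()
        nxt = np.zeros_like(dist)
        for l in range(m):
            dst = tuple(full * l + grow + full * (m - l - 1))
            src = tuple(full * l + keep + full * (m - l - 1))
            nxt[dst] += pj[l] * dist[src]
        dist = nxt
    return dist


# per (gamma row, kmax) tables of exact count-vector adoption results;
# these repeat across nodes and fixed-point iterations on small graphs
_TABLE_CACHE: dict = {}


def _counts_q_table(g: np.ndarray, kmax: int):
    """(q, h) for every count vector with sum <= kmax, laid out on the same
    dense grid as :func:`_counts_tensor`."""
    key = (g.tobytes(), len(g), kmax)
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    m = len(g)
    backend = _polynomial_q if kmax > ENUM_GUARD else _enumeration_q
    qtab = np.zeros((kmax + 1,) * m + (m,))
    htab = np.zeros((kmax + 1,) * m)
    for counts in itertools.product(range(kmax + 1), repeat=m):
        if sum(counts) > kmax:
            continue
        qc, hc = backend(np.array(counts), g)
        qtab[counts] = qc
        htab[counts] = hc
    if len(_TABLE_CACHE) > 512:
        _TABLE_CACHE.clear()
    _TABLE_CACHE[key] = (qtab, htab)
    return qtab, htab


def exact_adoption_all_states(neighbor_probs, gamma, theta):
    """Exact deterministic (q_hat, h) for every receiver state at once.

    The neighbor count distribution does not depend on the receiver's
    state, so it is built once and contracted against the per-row q tables.
    Returns ``(qhat, h)`` with shapes (m, m) and (m,): row k holds the
    Theta-composed adoption vector and no-adoption probability of a
    receiver in state k.
    """
    P = np.atleast_2d(np.asarray(neighbor_probs, dtype=float))
    k, m = P.shape
    qhat = np.zeros((m, m))
    h = np.ones(m)
    if k == 0:
        return qhat, h
    dist = _counts_tensor(P, k)
    for state in range(m):
        g = np.ascontiguousarray(gamma[state], dtype=float)
        qtab, htab = _counts_q_table(g, k)
        q = np.tensordot(dist, qtab, axes=m)
        qhat[state] = q @ theta[state]
        h[state] = float((dist * htab).sum())
    return qhat, h


def exact_adoption_deterministic_fast(neighbor_probs, gamma_row,
                                      theta_slice=None) -> AdoptionResult:
    """Exact deterministic adoption via the count-distribution collapse.

    Mathematically identical to :func:`exact_adoption_deterministic` (the
    configuration sum only enters through the induced distribution of the
    neighbor-state count vector), but costs O(k * (k+1)^m) instead of
    O(m^k 2^k). Powers the exact backend of the deterministic solver on the
    scan graphs.
    """
    P = np.atleast_2d(np.asarray(neighbor_probs, dtype=float))
    k, m = P.shape
    g = np.asarray(gamma_row, dtype=float)
    if k == 0:
        return _finish(np.zeros(m), 1.0, theta_slice)
    if (k + 1) ** m <= 1_000_000:
        dist = _counts_tensor(P, k)
        qtab, htab = _counts_q_table(g, k)
        q = np.tensordot(dist, qtab, axes=m)
        h = float((dist * htab).sum())
    else:  # very-high-degree fallback: sparse dict DP over reachable counts
        backend = _polynomial_q if k > ENUM_GUARD else _enumeration_q
        q = np.zeros(m)
        h = 0.0
        for counts, w in _counts_distribution(P).items():
            qc, hc = backend(np.array(counts), g)
            q += w * qc
            h += w * hc
    return _finish(q, h, theta_slice)


# ---------------------------------------------------------------------------
# the tractable approximation
# ---------------------------------------------------------------------------

def approx_adoption_counts(counts, gamma_row, theta_slice=None
                           ) -> AdoptionResult:
    """Compact count form of the approximation (stochastic inputs):

        q*_l = n_l g_l / (sum_r n_r g_r) * (1 - prod_r (1 - g_r)^{n_r})

    with the no-adoption probability kept exact.
    """
    counts = np.asarray(counts, dtype=float)
    g = np.asarray(gamma_row, dtype=float)
    h = no_adoption_prob_counts(counts, g)
    expected = counts * g
    denom = expected.sum()
    if denom == 0.0:
        q = np.zeros(len(g))
    else:
        q = expected / denom * (1.0 - h)
    return _finish(q, h, theta_slice)


def approx_adoption_field(neighbor_probs, gamma_row, theta_slice=None
                          ) -> AdoptionResult:
    """Probability-vector form of the approximation (deterministic inputs):

        q*_l = (sum_j g_l p_j^l) / (sum_r sum_j g_r p_j^r)
               * (1 - prod_j (1 - sum_r g_r p_j^r)).
    """
    P = np.atleast_2d(np.asarray(neighbor_probs, dtype=float))
    g = np.asarray(gamma_row, dtype=float)
    h = no_adoption_prob_field(P, g)
    expected = P.sum(axis=0) * g if P.shape[0] else np.zeros(len(g))
    denom = expected.sum()
    if denom == 0.0:
        q = np.zeros(len(g))
    else:
        q = expected / denom * (1.0 - h)
    return _finish(q, h, theta_slice)


def approx_adoption(arg, gamma_row, theta_slice=None) -> AdoptionResult:
    """Dispatch on input kind: 1-D integer counts or a stack of neighbor
    probability vectors."""
    a = np.asarray(arg)
    if a.ndim == 1:
        return approx_adoption_counts(a, gamma_row, theta_slice)
    return approx_adoption_field(a, gamma_row, theta_slice)
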