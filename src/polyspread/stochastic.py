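"""Synchronous discrete-time stochastic simulator of the reactive process.

Each step, every node — reading only the step-start state of the network —
first rolls its loaded spontaneous-transition dice (row of Delta); if the
roll moves it, that is its new state. Otherwise it collects transmissions:
every ordered neighbor pair attempts one directed transmission (receiver in
state k, sender in state l succeeds with probability gamma[k, l]); if at
least one link is infectious, the node picks one uniformly at random and
adopts the Theta-stimulated target of the transmitted state; otherwise it
keeps its state. Self-state transmissions are generated like any other and
may win the uniform choice (a no-op that still dilutes competing states).

All randomness in a step is drawn as arrays indexed by node or directed
edge, so the update is independent of any node iteration order by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .modelspec import require_valid
from .netio import Network


@dataclass
class SimulationRun:
    """Trajectory of one seeded realization."""

    fractions: np.ndarray          # (T+1) x m, per-step state fractions
    state_labels: tuple
    seed: int | None = None
    snapshots: dict = field(default_factory=dict)  # step -> state vector

    @property
    def n_steps(self) -> int:
        return self.fractions.shape[0] - 1


def random_assignment(n: int, m: int, rng) -> np.ndarray:
    """Uniform random 1-of-m state assignment."""
    return rng.integers(0, m, size=n)


def fractions_of(assignment: np.ndarray, m: int) -> np.ndarray:
    return np.bincount(assignment, minlength=m) / assignment.size


def _draw_categorical_rows(probs_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw per row: probs_rows is n x m, u is n uniforms."""
    cdf = np.cumsum(probs_rows, axis=1)
    idx = (u[:, None] >= cdf).sum(axis=1)
    return np.minimum(idx, probs_rows.shape[1] - 1)  # guard float round-off


def step(assignment: np.ndarray, spec, network: Network, rng) -> np.ndarray:
    """One synchronous update of the whole network.

    ``spec`` must be in probability form; ``rng`` is a numpy Generator.
    """
    if spec.is_rate_form:
        raise ValueError("stochastic step needs a probability-form spec; "
                         "convert with modelspec.to_probabilities")
    state = np.asarray(assignment)
    n = network.n
    if state.shape != (n,):
        raise ValueError("assignment length does not match network")

    # mechanism 1: the loaded dice (diagonal of Delta = stay put)
    u_spont = rng.random(n)
    spont = _draw_categorical_rows(spec.delta[state], u_spont)

    # mechanism 2: directed transmissions, read from the step-start state
    recv, send = network.directed_pairs()
    p_link = spec.gamma[state[recv], state[send]]
    success = rng.random(recv.size) < p_link
    keys = rng.random(recv.size)

    contact = state.copy()
    if success.any():
        r_idx = recv[success]
        k_idx = keys[success]
        s_idx = send[success]
        # uniform choice among a receiver's infectious links == the link
        # with the smallest i.i.d. key
        order = np.lexsort((k_idx, r_idx))
        r_sorted = r_idx[order]
        first = np.ones(r_sorted.size, dtype=bool)
        first[1:] = r_sorted[1:] != r_sorted[:-1]
        winners = order[first]
        receivers = r_idx[winners]
        transmitted = state[s_idx[winners]]
        targets = spec.theta_targets()
        contact[receivers] = targets[state[receivers], transmitted]

    moved = spont != state
    new_state = np.where(moved, spont, contact)
    return new_state


def run(assignment0, spec, network: Network, n_steps: int, rng=None,
        seed: int | None = None, snapshot_steps=()) -> SimulationRun:
    """Apply :func:`step` ``n_steps`` times, recording state fractions each
    step and full snapshots at the requested steps. Deterministic given the
    seed and inputs."""
    require_valid(spec)
    if rng is None:
        rng = np.random.default_rng(seed)
    state = np.asarray(assignment0).copy()
    m = spec.m
    fractions = np.empty((n_steps + 1, m))
    fractions[0] = fractions_of(state, m)
    snapshot_steps = set(snapshot_steps)
    snapshots = {0: state.copy()} if 0 in snapshot_steps else {}
    for t in range(1, n_steps + 1):
        state = step(state, spec, network, rng)
        fractions[t] = fractions_of(state, m)
        if t in snapshot_steps:
            snapshots[t] = state.copy()
    return SimulationRun(fractions=fractions, state_labels=spec.state_labels,
                         seed=seed, snapshots=snapshots)


def run_ensemble(assignment0, spec, network: Network, n_steps: int,
                 n_runs: int, base_seed: int = 0):
    """Independent seeded runs; per-step mean and standard error of the
    state fractions across runs.

    Returns ``(mean, stderr)``, both (T+1) x m. With ``n_runs=1`` the mean
    is the single run and the stderr is zero.
    """
    m = spec.m
    acc = np.zeros((n_steps + 1, m))
    acc2 = np.zeros((n_steps + 1, m))
    ss = np.random.SeedSequence(base_seed)
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        out = run(assignment0, spec, network, n_steps, rng=rng)
        acc += out.fractions
        acc2 += out.fractions ** 2
    mean = acc / n_runs
    if n_runs > 1:
        var = np.maximum(acc2 / n_runs - mean ** 2, 0.0) * n_runs / (n_runs - 1)
        stderr = np.sqrt(var / n_runs)
    else:
        stderr = np.zeros_like(mean)
    return mean, stderr
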