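"""Model parameter containers, validation, probability<->rate conversion and
the preset model zoo.

A model over ``m`` node states is the triple (Gamma, Delta, Theta):

* ``gamma[k, l]`` — transmission probability: a node in state ``k`` is
  successfully "infected" on a contact with a neighbor in state ``l``.
  Diagonal entries are legal and meaningful (a contact may transmit the
  receiver's own state; it then competes in the uniform choice).
* ``delta[k, l]`` — spontaneous (loaded-dice) transition probability
  ``k -> l`` for ``k != l``; the diagonal ``delta[k, k] = 1 - sum_{l!=k}``
  is the probability of making no spontaneous move.
* ``theta[k, r, l]`` — 0/1 indicator: exposure of a node in state ``k`` to a
  transmitted state ``r`` makes it adopt state ``l``. Exactly one ``l`` per
  ``(k, r)``; the default is the identity ``l = r`` (adopt what was sent).

``form`` distinguishes probability-form parameters (discrete time) from
rate-form parameters (continuous time). Mixing the two in one computation is
an error, never a silent reinterpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

PROBABILITY = "probability"
RATE = "rate"


def identity_theta(m: int) -> np.ndarray:
    """theta[k, r, l] = [r == l]: every exposure adopts the transmitted state."""
    theta = np.zeros((m, m, m))
    for r in range(m):
        theta[:, r, r] = 1.0
    return theta


def _full_delta(m: int, off: dict[tuple[int, int], float]) -> np.ndarray:
    delta = np.zeros((m, m))
    for (k, l), v in off.items():
        delta[k, l] = v
    np.fill_diagonal(delta, 0.0)
    np.fill_diagonal(delta, 1.0 - delta.sum(axis=1))
    return delta


@dataclass(frozen=True)
class ModelSpec:
    state_labels: tuple
    gamma: np.ndarray
    delta: np.ndarray
    theta: np.ndarray = None
    form: str = PROBABILITY

    def __post_init__(self):
        m = len(self.state_labels)
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        object.__setattr__(self, "gamma", np.array(self.gamma, dtype=float))
        object.__setattr__(self, "delta", np.array(self.delta, dtype=float))
        theta = self.theta if self.theta is not None else identity_theta(m)
        object.__setattr__(self, "theta", np.array(theta, dtype=float))

    @property
    def m(self) -> int:
        return len(self.state_labels)

    @property
    def is_rate_form(self) -> bool:
        return self.form == RATE

    def theta_targets(self) -> np.ndarray:
        """targets[k, r] = the state adopted when a node in ``k`` is exposed
        to transmitted state ``r`` (argmax of the indicator slice)."""
        return np.argmax(self.theta, axis=2)

    def delta_stay(self) -> np.ndarray:
        """Per-state probability of making no spontaneous move (the dice's
        m-th side); the diagonal of Delta in probability form."""
        return np.diag(self.delta)


@dataclass(frozen=True)
class MultiplexModelSpec:
    """As :class:`ModelSpec` but with one transmission matrix per layer."""

    state_labels: tuple
    gammas: tuple  # L matrices, gammas[alpha][k, l]
    delta: np.ndarray
    theta: np.ndarray = None
    form: str = PROBABILITY

    def __post_init__(self):
        m = len(self.state_labels)
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        object.__setattr__(self, "gammas",
                           tuple(np.array(g, dtype=float) for g in self.gammas))
        object.__setattr__(self, "delta", np.array(self.delta, dtype=float))
        theta = self.theta if self.theta is not None else identity_theta(m)
        object.__setattr__(self, "theta", np.array(theta, dtype=float))

    @property
    def m(self) -> int:
        return len(self.state_labels)

    @property
    def n_layers(self) -> int:
        return len(self.gammas)

    @property
    def is_rate_form(self) -> bool:
        return self.form == RATE

    def theta_targets(self) -> np.ndarray:
        return np.argmax(self.theta, axis=2)

    def layer_spec(self, alpha: int) -> ModelSpec:
        return ModelSpec(self.state_labels, self.gammas[alpha], self.delta,
                         self.theta, self.form)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _validate_gamma(gamma, m, form, out, name="Gamma"):
    if gamma.shape != (m, m):
        out.append(f"{name} must be {m}x{m}, got {gamma.shape}")
        return
    if np.any(gamma < 0):
        out.append(f"{name} has negative entries")
    if form == PROBABILITY and np.any(gamma > 1):
        out.append(f"{name} has entries > 1 in probability form")


def validate(spec) -> list[str]:
    """Return a list of invariant violations; empty iff the spec is valid."""
    out: list[str] = []
    m = spec.m
    if m < 1:
        out.append("need at least one state")
        return out
    gammas = spec.gammas if isinstance(spec, MultiplexModelSpec) else (spec.gamma,)
    for alpha, g in enumerate(gammas):
        name = f"Gamma^({alpha})" if len(gammas) > 1 else "Gamma"
        _validate_gamma(g, m, spec.form, out, name)
    if spec.delta.shape != (m, m):
        out.append(f"Delta must be {m}x{m}, got {spec.delta.shape}")
        return out
    off = spec.delta.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        out.append("Delta has negative off-diagonal entries")
    if spec.form == PROBABILITY:
        if np.any(off.sum(axis=1) > 1 + 1e-12):
            out.append("Delta off-diagonal row sums exceed 1")
        rowsum = spec.delta.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            out.append(f"Delta row {bad} sums to {rowsum[bad]:.6g}, expected 1 "
                       "(diagonal must absorb the remainder)")
    else:
        if np.any(np.diag(spec.delta) != 0):
            out.append("rate-form Delta must have a zero diagonal")
    if spec.theta.shape != (m, m, m):
        out.append(f"Theta must be {m}x{m}x{m}, got {spec.theta.shape}")
        return out
    if not np.isin(spec.theta, (0.0, 1.0)).all():
        out.append("Theta entries must be 0/1 indicators")
    sums = spec.theta.sum(axis=2)
    if not np.all(sums == 1.0):
        k, r = np.argwhere(sums != 1.0)[0]
        out.append(f"Theta slice (k={k}, r={r}) must have exactly one target "
                   f"state, has {sums[k, r]:g}")
    if spec.form not in (PROBABILITY, RATE):
        out.append(f"unknown form {spec.form!r}")
    return out


def require_valid(spec) -> None:
    problems = validate(spec)
    if problems:
        raise ValueError("invalid model spec: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# probability <-> rate conversion
# ---------------------------------------------------------------------------

def to_probabilities(spec, dt: float):
    """Rate form -> probability form: every rate is multiplied by the time
    step, gamma = gamma_rate * dt (and likewise for Delta)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not spec.is_rate_form:
        raise ValueError("spec already in probability form")

    def conv_gamma(g):
        p = g * dt
        if np.any(p > 1 + 1e-12):
            k, l = np.argwhere(p > 1 + 1e-12)[0]
            raise ValueError(f"gamma[{k},{l}]*dt = {p[k, l]:.6g} > 1; "
                             "reduce dt")
        return np.clip(p, 0.0, 1.0)

    doff = spec.delta * dt
    if np.any(doff.sum(axis=1) > 1 + 1e-12):
        k = int(np.argmax(doff.sum(axis=1)))
        raise ValueError(f"Delta row {k} rates*dt sum to "
                         f"{doff.sum(axis=1)[k]:.6g} > 1; reduce dt")
    delta = doff.copy()
    np.fill_diagonal(delta, 1.0 - doff.sum(axis=1))
    if isinstance(spec, MultiplexModelSpec):
        return replace(spec, gammas=tuple(conv_gamma(g) for g in spec.gammas),
                       delta=delta, form=PROBABILITY)
    return replace(spec, gamma=conv_gamma(spec.gamma), delta=delta,
                   form=PROBABILITY)


def to_rates(spec, dt: float):
    """Probability form -> rate form (inverse of :func:`to_probabilities`)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if spec.is_rate_form:
        raise ValueError("spec already in rate form")
    doff = spec.delta.copy()
    np.fill_diagonal(doff, 0.0)
    delta = doff / dt
    if isinstance(spec, MultiplexModelSpec):
        return replace(spec, gammas=tuple(g / dt for g in spec.gammas),
                       delta=delta, form=RATE)
    return replace(spec, gamma=spec.gamma / dt, delta=delta, form=RATE)


# ---------------------------------------------------------------------------
# the model zoo
# ---------------------------------------------------------------------------

def preset_SIS(beta: float, delta: float, form: str = PROBABILITY) -> ModelSpec:
    """Susceptible-infected-susceptible: infection S->I on contact with an
    infected neighbor (probability ``beta``), spontaneous cure I->S
    (probability ``delta``)."""
    gamma = np.zeros((2, 2))
    gamma[0, 1] = beta
    if form == RATE:
        d = np.zeros((2, 2))
        d[1, 0] = delta
    else:
        d = _full_delta(2, {(1, 0): delta})
    return ModelSpec(("S", "I"), gamma, d, form=form)


def preset_SIR(beta: float, delta: float, form: str = PROBABILITY) -> ModelSpec:
    """As SIS but recovery I->R grants permanent immunity."""
    gamma = np.zeros((3, 3))
    gamma[0, 1] = beta
    if form == RATE:
        d = np.zeros((3, 3))
        d[1, 2] = delta
    else:
        d = _full_delta(3, {(1, 2): delta})
    return ModelSpec(("S", "I", "R"), gamma, d, form=form)


def preset_SIRS(beta: float, delta: float, xi: float,
                form: str = PROBABILITY) -> ModelSpec:
    """SIR plus loss of immunity: a spontaneous R->S link with probability
    ``xi`` makes the immunity temporary."""
    gamma = np.zeros((3, 3))
    gamma[0, 1] = beta
    if form == RATE:
        d = np.zeros((3, 3))
        d[1, 2] = delta
        d[2, 0] = xi
    else:
        d = _full_delta(3, {(1, 2): delta, (2, 0): xi})
    return ModelSpec(("S", "I", "R"), gamma, d, form=form)


def preset_MakiThompson(lambda_: float, alpha: float, sigma: float = 0.0,
                        form: str = PROBABILITY) -> ModelSpec:
    """Maki-Thompson rumor spreading with spontaneous forgetting.

    States (I, S, R) = ignorant / spreader / stifler. An ignorant becomes a
    spreader by contacting a spreader (``lambda_``). A spreader becomes a
    stifler by contacting a spreader or a stifler (``alpha``) — the
    spreader-spreader contact *stimulates* adoption of the stifler state,
    which is Theta deviating from the identity — or spontaneously with
    ``sigma``. ``sigma=0`` recovers the original model. Contacts are
    directed: only the receiving end of each ordered pair may change.
    """
    m = 3
    I, S, R = 0, 1, 2
    gamma = np.zeros((m, m))
    gamma[I, S] = lambda_
    gamma[S, S] = alpha
    gamma[S, R] = alpha
    theta = identity_theta(m)
    # spreader exposed to a transmitted spreader state adopts stifler
    theta[S, S, :] = 0.0
    theta[S, S, R] = 1.0
    if form == RATE:
        d = np.zeros((m, m))
        d[S, R] = sigma
    else:
        d = _full_delta(m, {(S, R): sigma})
    return ModelSpec(("I", "S", "R"), gamma, d, theta, form=form)


def preset_SI1I2S(beta1: float, beta2: float, delta1: float, delta2: float,
                  form: str = PROBABILITY) -> ModelSpec:
    """Two contagions competing for susceptible nodes; infected nodes revert
    spontaneously. States (S, I1, I2)."""
    gamma = np.zeros((3, 3))
    gamma[0, 1] = beta1
    gamma[0, 2] = beta2
    if form == RATE:
        d = np.zeros((3, 3))
        d[1, 0] = delta1
        d[2, 0] = delta2
    else:
        d = _full_delta(3, {(1, 0): delta1, (2, 0): delta2})
    return ModelSpec(("S", "I1", "I2"), gamma, d, form=form)


def preset_SI1I2S_contact_only(beta1: float, beta2: float, delta1: float,
                               delta2: float,
                               form: str = PROBABILITY) -> ModelSpec:
    """The altered two-party competition: recovery is contact-induced too.

    An infected (supporter) node reverts to susceptible (abstaining) by
    contacting susceptible nodes, so the spontaneous links of
    :func:`preset_SI1I2S` are replaced by contact links gamma[I1,S]=delta1,
    gamma[I2,S]=delta2 and Delta is the identity.
    """
    gamma = np.zeros((3, 3))
    gamma[0, 1] = beta1
    gamma[0, 2] = beta2
    gamma[1, 0] = delta1
    gamma[2, 0] = delta2
    if form == RATE:
        d = np.zeros((3, 3))
    else:
        d = np.eye(3)
    return ModelSpec(("S", "I1", "I2"), gamma, d, form=form)


#: Synthetic stand-in for the three-innovation transmission matrix (the
#: published matrix is not available to this package). Constructed to the
#: documented constraints: a full 3x3 matrix with relatively large entries,
#: diagonal included, whose row-wise maxima trace the cycle 1->2->3->1,
#: producing sustained oscillatory dynamics.
THREE_INNOVATIONS_GAMMA = np.array([
    [0.1, 0.7, 0.2],
    [0.2, 0.1, 0.7],
    [0.7, 0.2, 0.1],
])


def preset_three_innovations(gamma: np.ndarray | None = None,
                             form: str = PROBABILITY) -> ModelSpec:
    """Three innovations, no susceptible state: every node holds one of the
    three, all transitions are contact-induced, and contacts may transmit
    any state including the receiver's own (full Gamma, diagonal allowed).
    Defaults to the synthetic :data:`THREE_INNOVATIONS_GAMMA`.
    """
    g = THREE_INNOVATIONS_GAMMA if gamma is None else np.asarray(gamma, float)
    if g.shape != (3, 3):
        raise ValueError("three-innovation Gamma must be 3x3")
    d = np.zeros((3, 3)) if form == RATE else np.eye(3)
    return ModelSpec(("A", "B", "C"), g, d, form=form)


def preset_multiplex_SI1I2S(beta1: float, beta2: float, delta1: float,
                            delta2: float,
                            form: str = PROBABILITY) -> MultiplexModelSpec:
    """Two contagions each spreading only on its own layer of a two-layer
    multiplex: layer 1 carries gamma^(1)[S,I1]=beta1, layer 2 carries
    gamma^(2)[S,I2]=beta2; spontaneous recoveries as in the single-layer
    competition model."""
    g1 = np.zeros((3, 3))
    g1[0, 1] = beta1
    g2 = np.zeros((3, 3))
    g2[0, 2] = beta2
    if form == RATE:
        d = np.zeros((3, 3))
        d[1, 0] = delta1
        d[2, 0] = delta2
    else:
        d = _full_delta(3, {(1, 0): delta1, (2, 0): delta2})
    return MultiplexModelSpec(("S", "I1", "I2"), (g1, g2), d, form=form)


PRESETS = {
    "SIS": preset_SIS,
    "SIR": preset_SIR,
    "SIRS": preset_SIRS,
    "MakiThompson": preset_MakiThompson,
    "SI1I2S": preset_SI1I2S,
    "SI1I2S_contact_only": preset_SI1I2S_contact_only,
    "three_innovations": preset_three_innovations,
    "multiplex_SI1I2S": preset_multiplex_SI1I2S,
}


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def from_config(path):
    """Load a ModelSpec from a YAML config.

    Keys: ``states`` (list of labels), ``gamma`` (m x m nested list, or a
    list of them under ``gammas`` for multiplex), ``delta`` (off-diagonal
    entries as ``{"k,l": p}`` or a full matrix), ``theta`` (sparse triplets
    ``{"k,r,l": 1}``, optional; identity by default), ``form``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    labels = tuple(str(s) for s in cfg["states"])
    m = len(labels)
    form = cfg.get("form", PROBABILITY)

    def parse_delta(raw):
        if isinstance(raw, dict):
            off = {}
            for key, v in raw.items():
                k, l = (int(t) for t in str(key).split(","))
                off[(k, l)] = float(v)
            if form == RATE:
                d = np.zeros((m, m))
                for (k, l), v in off.items():
                    d[k, l] = v
                return d
            return _full_delta(m, off)
        return np.array(raw, dtype=float)

    delta = parse_delta(cfg.get("delta", {}))
    theta = None
    if "theta" in cfg:
        theta = identity_theta(m)
        for key in cfg["theta"]:
            k, r, l = (int(t) for t in str(key).split(","))
            theta[k, r, :] = 0.0
            theta[k, r, l] = 1.0
    if "gammas" in cfg:
        spec = MultiplexModelSpec(labels,
                                  tuple(np.array(g, float) for g in cfg["gammas"]),
                                  delta, theta, form)
    else:
        spec = ModelSpec(labels, np.array(cfg["gamma"], float), delta, theta,
                         form)
    require_valid(spec)
    return spec


def to_config(spec, path) -> None:
    cfg = {
        "states": list(spec.state_labels),
        "delta": np.asarray(spec.delta).tolist(),
        "form": spec.form,
    }
    if isinstance(spec, MultiplexModelSpec):
        cfg["gammas"] = [g.tolist() for g in spec.gammas]
    else:
        cfg["gamma"] = spec.gamma.tolist()
    targets = spec.theta_targets() if isinstance(spec, ModelSpec) else \
        np.argmax(spec.theta, axis=2)
    nonid = {f"{k},{r},{int(targets[k, r])}": 1
             for k in range(spec.m) for r in range(spec.m)
             if targets[k, r] != r}
    if nonid:
        cfg["theta"] = nonid
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
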