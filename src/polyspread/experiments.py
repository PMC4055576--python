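"""Desk-scale computational experiments.

* fixed-point scans of the two-contagion competition model comparing the
  approximate against the exact deterministic backend over the
  (tau1, tau2) transmission-probability grid;
* ensemble-averaged stochastic runs against the approximated deterministic
  solver (the large-lattice oscillatory three-innovation system);
* snapshot runs for lattice visualizations;
* a deterministic fixture generator (canned graphs, configs, initial
  assignments).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import deterministic, modelspec, netio, stochastic


@dataclass
class ScanResult:
    """Approx-vs-exact fixed-point error over a transmission grid."""

    tau1: np.ndarray            # grid axis values
    tau2: np.ndarray
    errors: np.ndarray          # len(tau1) x len(tau2), max over initial fields
    variant: str
    delta1: float
    delta2: float

    def error_at(self, t1: float, t2: float) -> float:
        i = int(np.argmin(np.abs(self.tau1 - t1)))
        j = int(np.argmin(np.abs(self.tau2 - t2)))
        return float(self.errors[i, j])


@dataclass
class ComparisonResult:
    """Stochastic ensemble vs approximated deterministic trajectories."""

    stoch_mean: np.ndarray      # (T+1) x m
    stoch_stderr: np.ndarray    # (T+1) x m
    det: np.ndarray             # (T+1) x m macroscopic fractions
    state_labels: tuple
    max_gap: float = field(init=False)

    def __post_init__(self):
        self.max_gap = float(np.max(np.abs(self.stoch_mean - self.det)))

    def within_stderr_band(self, n_sigma: float = 3.0,
                           floor: float = 0.0) -> bool:
        band = np.maximum(n_sigma * self.stoch_stderr, floor)
        return bool(np.all(np.abs(self.stoch_mean - self.det) <= band))


def _variant_spec(variant: str, t1: float, t2: float,
                  delta1: float, delta2: float):
    if variant == "standard":
        return modelspec.preset_SI1I2S(t1, t2, delta1, delta2)
    if variant == "contact_only":
        return modelspec.preset_SI1I2S_contact_only(t1, t2, delta1, delta2)
    raise ValueError(f"unknown variant {variant!r}")


def scan_SI1I2S(graph: netio.Network, delta1: float = 0.2,
                delta2: float = 0.2, grid_step: float = 0.05,
                variant: str = "standard", init_seeds=(0, 1, 2),
                tol: float = 1e-9, max_iter: int = 20_000,
                taus=None, init_fields=None) -> ScanResult:
    """Fixed-point error surface of the two-contagion competition model.

    For every (tau1, tau2) on the grid and every seeded random initial
    state assignment, both deterministic backends are iterated to their
    macroscopic fixed point from the same degenerate initial field; the
    recorded error is the largest (over initial fields) Euclidean norm of
    the difference between the two macroscopic fraction vectors. The graph
    must be small enough for the exact backend.
    """
    if taus is None:
        taus = np.arange(grid_step, 1.0 + 1e-12, grid_step)
    taus = np.asarray(taus, dtype=float)
    m = 3
    if init_fields is not None:
        inits = [np.asarray(P, dtype=float) for P in init_fields]
    else:
        inits = []
        for s in init_seeds:
            rng = np.random.default_rng(s)
            inits.append(deterministic.field_from_assignment(
                stochastic.random_assignment(graph.n, m, rng), m))
    errors = np.zeros((taus.size, taus.size))
    for i, t1 in enumerate(taus):
        for j, t2 in enumerate(taus):
            spec = _variant_spec(variant, t1, t2, delta1, delta2)
            worst = 0.0
            for P0 in inits:
                fp_a = deterministic.iterate_to_fixed_point(
                    P0, spec, graph, backend="approx", tol=tol,
                    max_iter=max_iter)
                fp_e = deterministic.iterate_to_fixed_point(
                    P0, spec, graph, backend="exact", tol=tol,
                    max_iter=max_iter)
                err = float(np.linalg.norm(fp_a.fractions - fp_e.fractions))
                worst = max(worst, err)
            errors[i, j] = worst
    return ScanResult(tau1=taus, tau2=taus, errors=errors, variant=variant,
                      delta1=delta1, delta2=delta2)


def compare_stochastic_deterministic(graph: netio.Network, spec,
                                     n_runs: int, n_steps: int,
                                     seed: int = 0,
                                     assignment0=None) -> ComparisonResult:
    """Ensemble-mean state fractions of the stochastic model vs the
    approximated deterministic solver, from matching initial conditions."""
    modelspec.require_valid(spec)
    if assignment0 is None:
        rng = np.random.default_rng(seed)
        assignment0 = stochastic.random_assignment(graph.n, spec.m, rng)
    mean, stderr = stochastic.run_ensemble(assignment0, spec, graph, n_steps,
                                           n_runs, base_seed=seed)
    P0 = deterministic.field_from_assignment(assignment0, spec.m)
    traj = deterministic.run_field(P0, spec, graph, n_steps, backend="approx")
    det = traj.mean(axis=1)
    return ComparisonResult(stoch_mean=mean, stoch_stderr=stderr, det=det,
                            state_labels=spec.state_labels)


def snapshot_run(graph: netio.Network, spec, n_steps: int, snapshot_steps,
                 seed: int = 0, assignment0=None) -> stochastic.SimulationRun:
    """One seeded stochastic run with full per-node snapshots at the
    requested steps (for lattice graphs, pair with
    :func:`polyspread.netio.lattice_coords` to index states by row/col)."""
    if assignment0 is None:
        rng = np.random.default_rng(seed)
        assignment0 = stochastic.random_assignment(graph.n, spec.m, rng)
    return stochastic.run(assignment0, spec, graph, n_steps, seed=seed,
                          snapshot_steps=snapshot_steps)


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the deterministic fixture set used by the experiments.

    Graphs: complete(6), star(6), ring(6), lattice(3,3), lattice(32,32) and
    a two-layer multiplex toy; preset configs including the (synthetic)
    three-innovation transmission matrix; three seeded random initial
    assignments per graph. Regeneration is idempotent.
    """
    os.makedirs(out_dir, exist_ok=True)
    graphs = {
        "complete6": netio.make_graph("complete", 6),
        "star6": netio.make_graph("star", 6),
        "ring6": netio.make_graph("ring", 6),
        "lattice3x3": netio.make_graph("lattice2d_periodic", 3, 3),
        "lattice32x32": netio.make_graph("lattice2d_periodic", 32, 32),
    }
    for name, g in graphs.items():
        netio.write_edge_list(g, os.path.join(out_dir, f"{name}.edges"))
    ring = netio.make_graph("ring", 6)
    star = netio.make_graph("star", 6)
    toy = netio.MultiplexNetwork((ring, star))
    netio.write_edge_list(toy, os.path.join(out_dir, "multiplex_toy.edges"))
    graphs["multiplex_toy"] = toy

    configs = {
        "sis": modelspec.preset_SIS(0.4, 0.2),
        "si1i2s": modelspec.preset_SI1I2S(0.5, 0.4, 0.2, 0.2),
        "three_innovations": modelspec.preset_three_innovations(),
        "maki_thompson": modelspec.preset_MakiThompson(0.3, 0.2, 0.1),
    }
    for name, spec in configs.items():
        modelspec.to_config(spec, os.path.join(out_dir, f"{name}.yaml"))

    # three random initial state assignments per graph, m = 3
    inits = {}
    for name, g in graphs.items():
        for s in range(3):
            rng = np.random.default_rng(seed * 1000 + s)
            a = stochastic.random_assignment(g.n, 3, rng)
            path = os.path.join(out_dir, f"{name}_init{s}.csv")
            np.savetxt(path, a, fmt="%d")
            inits[(name, s)] = a
    return {"graphs": graphs, "configs": configs, "inits": inits}
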