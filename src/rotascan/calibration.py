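"""Energy-weight calibration by particle swarm optimization.

The objective is the mean best-case RMSD of the rotamer libraries generated
under candidate term weights against a set of reference residues, so the
optimizer pushes the scoring function towards ranking observed
conformations at (or near) the energy minimum.  The swarm uses the
global-best topology with standard constriction-equivalent coefficients
(inertia 0.72, cognitive = social = 1.49), positions clamped to the search
bounds, and a single seeded random generator so runs are reproducible.

Calibration scans use a coarse chi grid (30 degrees by default) — a
deliberate approximation that keeps each objective evaluation cheap while
preserving the ranking signal the weights are fitted to.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import bc_rmsd, symmetry_rules
from .forcefield import ForceFieldParameters, default_parameters
from .scanner import (GridScanSpec, ScanError, accept_rotamers, dee_scan,
                      reach_radius, select_environment)

__all__ = [
    "CalibrationError",
    "PsoConfig",
    "CalibrationResult",
    "make_objective",
    "objective",
    "pso_fit",
    "DEFAULT_WEIGHT_NAMES",
]

logger = logging.getLogger("rotascan.calibration")

DEFAULT_WEIGHT_NAMES = ("w_lj", "w_coulomb", "w_hbond", "w_torsion")


class CalibrationError(ValueError):
    """Raised for invalid calibration setups."""


@dataclass
class PsoConfig:
    """Swarm size, budget, coefficients, bounds and seed."""

    n_particles: int = 20
    iterations: int = 100
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    bounds: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_particles <= 0 or self.iterations <= 0:
            raise CalibrationError("particle count and iterations must be positive")
        if not self.bounds:
            raise CalibrationError("parameter bounds are required")
        for lo, hi in self.bounds:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise CalibrationError(f"invalid bound ({lo}, {hi})")


@dataclass
class CalibrationResult:
    """Best parameters, objective and the per-iteration best trace."""

    best_params: np.ndarray
    best_objective: float
    trace: list[float]
    seed: int


def objective(params, references, ff: ForceFieldParameters | None = None,
              spec: GridScanSpec | None = None,
              param_names=DEFAULT_WEIGHT_NAMES) -> float:
    """Mean bcRMSD over reference residues under candidate parameters.

    ``references`` is a list of (structure, residue keys) pairs; libraries
    are regenerated under the candidate weights for every evaluation.
    """
    if not references:
        raise CalibrationError("reference list is empty")
    ff = ff or default_parameters()
    spec = spec or GridScanSpec(step=30.0, window=0.0)
    ff_cand = ff.with_weights(**dict(zip(param_names, params)))

    values = []
    reach = reach_radius(ff_cand)
    for structure, keys in references:
        for key in keys:
            key = tuple(key)
            residue = structure.residue(key)
            try:
                env = select_environment(structure, key, reach, ff_cand)
                records = dee_scan(structure, key, spec, ff_cand, env=env)
                accepted = accept_rotamers(records, spec.window)
            except (ScanError, ValueError) as exc:
                raise CalibrationError(
                    f"scan failed for residue {key} ({residue.comp_id}): {exc}"
                ) from exc
            rmsd, _ = bc_rmsd(residue, accepted,
                              symmetry_rules(residue.comp_id), False, ff_cand)
            values.append(rmsd)
    # order-independent mean
    return math.fsum(sorted(values)) / len(values)


def make_objective(references, ff=None, spec=None,
                   param_names=DEFAULT_WEIGHT_NAMES):
    """Bind references and settings into an objective callable for PSO."""
    return lambda params: objective(params, references, ff, spec, param_names)


def pso_fit(objective_fn, config: PsoConfig) -> CalibrationResult:
    """Global-best particle swarm minimization, deterministic given the seed.

    One iteration = one evaluation sweep of the swarm; with a budget of a
    single iteration the result is the best particle of the initial swarm.
    Non-finite objective values reset the particle uniformly within bounds.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    dim = len(config.bounds)
    span = hi - lo

    pos = lo + rng.uniform(size=(config.n_particles, dim)) * span
    vel = rng.uniform(-1.0, 1.0, size=(config.n_particles, dim)) * span * 0.1
    pbest = pos.copy()
    pbest_val = np.full(config.n_particles, math.inf)
    gbest = pos[0].copy()
    gbest_val = math.inf
    trace = []

    for iteration in range(config.iterations):
        for i in range(config.n_particles):
            value = float(objective_fn(pos[i]))
            if not math.isfinite(value):
                logger.warning("non-finite objective at %s; resetting particle %d",
                               pos[i], i)
                pos[i] = lo + rng.uniform(size=dim) * span
                vel[i] = 0.0
                continue
            if value < pbest_val[i]:
                pbest_val[i] = value
                pbest[i] = pos[i].copy()
            if value < gbest_val:
                gbest_val = value
                gbest = pos[i].copy()
        trace.append(gbest_val)
        if iteration == config.iterations - 1:
            break
        r1 = rng.uniform(size=(config.n_particles, dim))
        r2 = rng.uniform(size=(config.n_particles, dim))
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest - pos)
               + config.social * r2 * (gbest - pos))
        pos = np.clip(pos + vel, lo, hi)

    return CalibrationResult(best_params=gbest, best_objective=gbest_val,
                             trace=trace, seed=config.seed)
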