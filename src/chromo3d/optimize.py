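"""Ensemble generation by steepest gradient ascent with backtracking.

Each model starts from coordinates drawn i.i.d. uniform on (-0.5, 0.5) and
climbs the tanh objective.  The backtracking line search accepts a step only
when it yields a sufficient increase (Armijo condition for ascent), so the
objective trace is non-decreasing across accepted iterations by
construction.  An ensemble is a set of independent runs from consecutive
seeds, making the whole pipeline a pure function of its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import ModelParameters, Structure, gradient, objective
from .normalize import ConstraintSet

__all__ = [
    "OptimizerOptions",
    "OptimizationResult",
    "Ensemble",
    "initialize_structure",
    "reconstruct",
    "build_ensemble",
]

logger = logging.getLogger(__name__)

INIT_RANGE = 0.5  # coordinates initialized uniform on (-0.5, 0.5)


@dataclass
class OptimizerOptions:
    """Gradient-ascent controls.

    The search stops when the relative objective improvement stays below
    ``tol`` for ``patience`` consecutive iterations, when the line search
    underflows, or at ``max_iterations``.
    """

    max_iterations: int = 10_000
    tol: float = 1e-7
    patience: int = 10
    armijo_c: float = 1e-4
    shrink: float = 0.5
    initial_step: float = 0.1
    max_backtracks: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.shrink < 1):
            raise ValueError("shrink must lie in (0, 1)")
        if not (0 < self.armijo_c < 1):
            raise ValueError("armijo_c must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class OptimizationResult:
    structure: Structure
    trace: np.ndarray          # objective value after each accepted iteration
    converged: bool
    n_iterations: int
    seed: int

    @property
    def final_score(self) -> float:
        return float(self.trace[-1])


@dataclass
class Ensemble:
    """Optimized structures with their seeds, scores and provenance."""

    structures: list[Structure]
    seeds: list[int]
    final_scores: list[float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.structures) == len(self.seeds) == len(self.final_scores)):
            raise ValueError("structures, seeds and final_scores must align")
        sizes = {s.n for s in self.structures}
        if len(sizes) > 1:
            raise ValueError("all ensemble structures must have equal size")

    def __len__(self) -> int:
        return len(self.structures)


def initialize_structure(
    n: int, seed: int, chrom: str = "chr", resolution: int = 1_000_000
) -> Structure:
    """Random initial structure: 3n coordinates uniform on (-0.5, 0.5)."""
    if n < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    points = rng.uniform(-INIT_RANGE, INIT_RANGE, size=(n, 3))
    return Structure(points=points, chrom=chrom, resolution=resolution)


def reconstruct(
    CS: ConstraintSet,
    P: ModelParameters | None = None,
    opts: OptimizerOptions | None = None,
    chrom: str = "chr",
    resolution: int = 1_000_000,
) -> OptimizationResult:
    """Optimize one structure from a random initialization.

    Returns the final structure (centered at the origin) together with the
    per-iteration objective trace.  A line search that underflows its step
    budget stops the run and reports ``converged=False`` rather than raising.
    """
    P = P or ModelParameters()
    opts = opts or OptimizerOptions()
    if CS.n_contacts == 0:
        raise ValueError("constraint set has no contacts; nothing to reconstruct")

    S = initialize_structure(CS.n, opts.seed, chrom=chrom, resolution=resolution)
    X = S.points
    F = objective(S, CS, P)
    trace = [F]
    stalled = 0
    converged = False
    it = 0
    for it in range(1, opts.max_iterations + 1):
        g = gradient(S, CS, P)
        gnorm = float(np.sqrt(np.sum(g * g)))
        if gnorm == 0.0:
            converged = True
            break
        # Search along the unit steepest-ascent direction, so the step size
        # is a displacement in model units; this keeps a single iteration
        # from overshooting into the saturated (flat) region of the tanh
        # terms, where violated constraints would stop exerting force.
        u = g / gnorm
        step = opts.initial_step
        F_new = None
        for _ in range(opts.max_backtracks):
            X_new = X + step * u
            S_new = Structure(points=X_new, chrom=chrom, resolution=resolution)
            F_try = objective(S_new, CS, P)
            if F_try >= F + opts.armijo_c * step * gnorm:
                F_new = F_try
                break
            step *= opts.shrink
        if F_new is None:
            logger.debug("line search underflow at iteration %d", it)
            break
        X, S = X_new, S_new
        rel = (F_new - F) / max(abs(F), 1.0)
        F = F_new
        trace.append(F)
        logger.debug("iter %d objective %.6f step %.3g", it, F, step)
        stalled = stalled + 1 if rel < opts.tol else 0
        if stalled >= opts.patience:
            converged = True
            break

    final = Structure(points=X, chrom=chrom, resolution=resolution).centered()
    return OptimizationResult(
        structure=final, trace=np.asarray(trace), converged=converged,
        n_iterations=it, seed=opts.seed,
    )


def build_ensemble(
    CS: ConstraintSet,
    P: ModelParameters | None = None,
    opts: OptimizerOptions | None = None,
    m: int = 300,
    chrom: str = "chr",
    resolution: int = 1_000_000,
) -> Ensemble:
    """Run ``m`` independent reconstructions from seeds seed, seed+1, ...

    The default ensemble size of 300 matches the standard protocol for
    selecting a representative model from independently initialized runs.
    """
    if m < 1:
        raise ValueError("ensemble size must be >= 1")
    P = P or ModelParameters()
    opts = opts or OptimizerOptions()
    structures, seeds, scores = [], [], []
    for k in range(m):
        run_opts = OptimizerOptions(**{**opts.__dict__, "seed": opts.seed + k})
        res = reconstruct(CS, P, run_opts, chrom=chrom, resolution=resolution)
        structures.append(res.structure)
        seeds.append(res.seed)
        scores.append(res.final_score)
        logger.info(
            "ensemble member %d/%d: objective %.4f (%d iterations)",
            k + 1, m, res.final_score, res.n_iterations,
        )
    provenance = {
        "n_models": m,
        "base_seed": opts.seed,
        "cutoff": CS.cutoff,
        "parameters": {
            k: v for k, v in P.__dict__.items() if not isinstance(v, np.ndarray)
        },
    }
    return Ensemble(
        structures=structures, seeds=seeds, final_scores=scores,
        provenance=provenance,
    )
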