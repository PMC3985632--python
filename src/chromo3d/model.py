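"""Structure representation, model parameters and the reconstruction objective.

The chromosome is modeled as a piece-wise linear curve through the midpoints
of fixed-size genomic bins.  A parameterized objective rewards placing bin
pairs classified as contacts within a contact distance threshold, pairs
classified as non-contacts outside it, and consecutive bins within an
adjacency band.  Every threshold applies to *squared* Euclidean distances
and each constraint is smoothed with a hyperbolic tangent, so the objective
is differentiable everywhere and is maximized by gradient ascent.

The objective for a structure with pairwise squared distances ``d2_ij`` is::

    F =   sum_{contacts}    w_ij*W1*tanh(dc2 - d2_ij) + W2*tanh(d2_ij - dmin2)
        + sum_{noncontacts} W3*tanh(d2_ij - dc2)      + W3*tanh(dmax2 - d2_ij)
        + sum_{adjacent}    W4*tanh(dmaxadj2 - d2_ij) + W4*tanh(d2_ij - dmin2)

where ``w_ij`` is the contact's normalized interaction frequency divided by
the maximum (or, optionally, the total) normalized IF of the chromosome, so
high-confidence contacts pull harder on the optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "Structure",
    "ModelParameters",
    "default_parameters",
    "balanced_parameters",
    "objective",
    "gradient",
    "objective_breakdown",
]


@dataclass
class Structure:
    """Ordered 3D coordinates of bin midpoints, one point per modeled bin.

    Coordinates live in model units nominally calibrated to micrometers;
    point order follows genomic bin order.
    """

    points: np.ndarray
    chrom: str = "chr"
    resolution: int = 1_000_000

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("structure coordinates must be finite")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def centered(self) -> "Structure":
        """Return a copy translated so the centroid sits at the origin."""
        return replace(self, points=self.points - self.points.mean(axis=0))

    def copy(self) -> "Structure":
        return replace(self, points=self.points.copy())


@dataclass
class ModelParameters:
    """Distance thresholds (squared convention) and term weights.

    dc2       -- squared contact distance threshold; a contact is satisfied
                 when its squared distance falls below it.
    dmin2     -- squared minimum distance between any two bins (excluded
                 volume floor).
    dmax2     -- squared maximum intra-chromosomal distance (territory size).
    dmaxadj2  -- squared maximum distance between genomically adjacent bins.
    W1..W4    -- nonnegative weights of the objective components: W1 contact
                 upper bound (IF-weighted), W2 contact lower bound, W3 both
                 non-contact bounds, W4 both adjacency bounds.
    weight_denominator -- whether contact weights divide the normalized IF by
                 the maximum IF ("max", bounded in (0, 1]) or the total IF
                 ("total").
    """

    dc2: float = 7.0
    dmin2: float = 0.04
    dmax2: float = 20.0
    dmaxadj2: float = 2.25
    W1: float = 1.0
    W2: float = 1.0
    W3: float = 1.0
    W4: float = 1.0
    weight_denominator: Literal["max", "total"] = "max"

    def __post_init__(self) -> None:
        if not (0 < self.dmin2 < self.dmaxadj2):
            raise ValueError("require 0 < dmin2 < dmaxadj2")
        if not (self.dmin2 < self.dc2 < self.dmax2):
            raise ValueError("require dmin2 < dc2 < dmax2")
        for name in ("W1", "W2", "W3", "W4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.weight_denominator not in ("max", "total"):
            raise ValueError("weight_denominator must be 'max' or 'total'")


#: Calibrated defaults per supported bin resolution.  The 1 MB squared
#: contact threshold of 7.0 and the territory bound of 20 come from FISH
#: calibration at that scale; the 200 KB thresholds (4.5, 0.02, 1.0, 20)
#: were chosen to keep high-resolution models consistent with 1 MB models.
#: The 1 MB excluded-volume and adjacency bounds are package defaults in the
#: same squared convention.
_RESOLUTION_DEFAULTS: dict[str, dict[str, float]] = {
    "1MB": {"dc2": 7.0, "dmin2": 0.04, "dmax2": 20.0, "dmaxadj2": 2.25},
    "200KB": {"dc2": 4.5, "dmin2": 0.02, "dmax2": 20.0, "dmaxadj2": 1.0},
}


def default_parameters(
    resolution: str = "1MB", chrom: str | None = None,
    overrides: dict | None = None,
) -> ModelParameters:
    """Return calibrated :class:`ModelParameters` for a bin resolution.

    ``resolution`` is ``"1MB"`` or ``"200KB"`` (case-insensitive).  Optional
    ``overrides`` maps parameter names to values, or chromosome names to such
    mappings (mirroring a per-chromosome weight table); when ``chrom`` is
    given and present in ``overrides``, its entry is applied on top.
    """
    key = resolution.upper().replace(" ", "")
    if key not in _RESOLUTION_DEFAULTS:
        raise ValueError(
            f"unknown resolution {resolution!r}; expected one of "
            f"{sorted(_RESOLUTION_DEFAULTS)}"
        )
    values = dict(_RESOLUTION_DEFAULTS[key])
    if overrides:
        flat = {k: v for k, v in overrides.items() if not isinstance(v, dict)}
        values.update(flat)
        if chrom is not None and isinstance(overrides.get(chrom), dict):
            values.update(overrides[chrom])
    return ModelParameters(**values)


def balanced_parameters(
    CS, resolution: str = "1MB", **overrides
) -> ModelParameters:
    """Parameters with the contact weight W1 balanced against the IF scale.

    The effective pull on a contact is w_ij * W1 with w_ij the normalized IF
    over the chromosome maximum, so when the IF distribution is heavy-tailed
    the typical pull collapses.  Following the practice of tuning the term
    weights around the average IF of the chromosome, this sets
    W1 = 1 / mean(w_ij), making the *average* contact pull comparable to the
    unit non-contact and adjacency forces.  Further keyword overrides (e.g.
    a smaller W3 to emphasise contacts) are applied on top.
    """
    P = default_parameters(resolution)
    w = np.asarray(CS.contact_weights, dtype=float)
    if w.size and w.max() > 0:
        mean_w = float(np.mean(w / w.max()))
        if mean_w > 0:
            P = replace(P, W1=1.0 / mean_w)
    return replace(P, **overrides) if overrides else P


def _pair_d2(points: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    diff = points[ii] - points[jj]
    return np.einsum("ij,ij->i", diff, diff)


def _check_inputs(S: Structure, CS) -> None:
    if S.n != CS.n:
        raise ValueError(
            f"structure has {S.n} points but constraint set expects {CS.n}"
        )
    if not np.all(np.isfinite(S.points)):
        raise ValueError("structure coordinates must be finite")


def contact_weights(CS, P: ModelParameters) -> np.ndarray:
    """Per-contact weights w_ij: normalized IF over the max (or total) IF."""
    w = np.asarray(CS.contact_weights, dtype=float)
    if w.size == 0:
        return w
    if P.weight_denominator == "max":
        denom = w.max()
    else:
        denom = w.sum()
    return w / denom if denom > 0 else w


def objective_breakdown(S: Structure, CS, P: ModelParameters) -> dict[str, float]:
    """Evaluate the objective, returning its three per-term components."""
    _check_inputs(S, CS)
    X = S.points
    w = contact_weights(CS, P)

    ci, cj = CS.contact_index_arrays()
    d2 = _pair_d2(X, ci, cj)
    contact_term = float(
        np.sum(w * P.W1 * np.tanh(P.dc2 - d2) + P.W2 * np.tanh(d2 - P.dmin2))
    )

    ni, nj = CS.noncontact_index_arrays()
    d2 = _pair_d2(X, ni, nj)
    noncontact_term = float(
        np.sum(P.W3 * np.tanh(d2 - P.dc2) + P.W3 * np.tanh(P.dmax2 - d2))
    )

    ai, aj = CS.adjacent_index_arrays()
    d2 = _pair_d2(X, ai, aj)
    adjacency_term = float(
        np.sum(P.W4 * np.tanh(P.dmaxadj2 - d2) + P.W4 * np.tanh(d2 - P.dmin2))
    )

    total = contact_term + noncontact_term + adjacency_term
    return {
        "contact_term": contact_term,
        "noncontact_term": noncontact_term,
        "adjacency_term": adjacency_term,
        "total": total,
    }


def objective(S: Structure, CS, P: ModelParameters) -> float:
    """Objective value F(S); higher is better."""
    return objective_breakdown(S, CS, P)["total"]


def _sech2(x: np.ndarray) -> np.ndarray:
    t = np.tanh(x)
    return 1.0 - t * t


def gradient(S: Structure, CS, P: ModelParameters) -> np.ndarray:
    """Exact analytic gradient of the objective, shape (n, 3).

    For a pair term g(d2_ij), the contribution to point i is
    g'(d2_ij) * 2 * (x_i - x_j) and the negative of that to point j; the
    gradient of tanh(c - d2) with respect to d2 is -sech^2(c - d2).
    """
    _check_inputs(S, CS)
    X = S.points
    grad = np.zeros_like(X)
    w = contact_weights(CS, P)

    def accumulate(ii: np.ndarray, jj: np.ndarray, dF_dd2: np.ndarray) -> None:
        diff = X[ii] - X[jj]
        contrib = (2.0 * dF_dd2)[:, None] * diff
        np.add.at(grad, ii, contrib)
        np.add.at(grad, jj, -contrib)

    ci, cj = CS.contact_index_arrays()
    d2 = _pair_d2(X, ci, cj)
    accumulate(ci, cj, -w * P.W1 * _sech2(P.dc2 - d2) + P.W2 * _sech2(d2 - P.dmin2))

    ni, nj = CS.noncontact_index_arrays()
    d2 = _pair_d2(X, ni, nj)
    accumulate(ni, nj, P.W3 * _sech2(d2 - P.dc2) - P.W3 * _sech2(P.dmax2 - d2))

    ai, aj = CS.adjacent_index_arrays()
    d2 = _pair_d2(X, ai, aj)
    accumulate(ai, aj, -P.W4 * _sech2(P.dmaxadj2 - d2) + P.W4 * _sech2(d2 - P.dmin2))

    return grad
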