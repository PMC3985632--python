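"""Model scoring, structural similarity, representative selection, robustness.

A contact is *satisfied* when its squared distance in the model falls
strictly below the squared contact threshold; a non-contact is satisfied
when its squared distance is at least the threshold.  Structures are
compared with a GDT-HA score (mean fraction of index-matched points within
thresholds 2.0/1.5/1.0/0.5 after one global least-squares superposition);
because contact data cannot distinguish a structure from its mirror image,
the score is mirror-aware by default.  The representative model of an
ensemble is the exact medoid under the distance 1/GDT-HA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model import ModelParameters, Structure
from .normalize import ConstraintSet
from .optimize import Ensemble, OptimizerOptions, reconstruct

__all__ = [
    "EvaluationReport",
    "SimilarityMatrix",
    "score_structure",
    "superimpose",
    "gdt_ha",
    "pairwise_similarity",
    "select_representative",
    "compare_ensembles",
    "robustness_test",
    "RobustnessResult",
]

GDT_HA_THRESHOLDS = (2.0, 1.5, 1.0, 0.5)
_GDT_FLOOR = 1e-6  # floor on GDT-HA when inverting into a distance


@dataclass
class EvaluationReport:
    """Satisfaction scores and violation statistics for one structure.

    Averages over empty sets are ``None`` (absent), never zero.
    """

    contact_score: float
    noncontact_score: float
    satisfied_if_pct: float
    avg_sq_dist_unsat_contacts: float | None
    avg_if_unsat_contacts: float | None
    avg_sq_dist_unsat_noncontacts: float | None
    avg_if_all: float | None
    n_contacts: int
    n_noncontacts: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SimilarityMatrix:
    values: np.ndarray        # (m, m) GDT-HA scores in [0, 1]
    mirror_used: np.ndarray   # (m, m) bool: reflected partner scored higher

    @property
    def mean_offdiagonal(self) -> float:
        m = self.values.shape[0]
        iu, ju = np.triu_indices(m, k=1)
        return float(self.values[iu, ju].mean())


def _pair_d2(points: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    diff = points[pairs[:, 0]] - points[pairs[:, 1]]
    return np.einsum("ij,ij->i", diff, diff)


def score_structure(
    S: Structure, CS: ConstraintSet, P: ModelParameters | None = None
) -> EvaluationReport:
    """Score a structure against its constraint set.

    contact_score / noncontact_score are the fractions of satisfied
    contacts / non-contacts; satisfied_if_pct is the IF-weighted analogue
    (sum of normalized IFs of satisfied contacts over the total contact IF,
    as a percentage).  Violation statistics mirror the standard per-model
    summary: mean squared distance and mean IF of unsatisfied contacts,
    mean squared distance of unsatisfied non-contacts, and the mean IF over
    all contacts for comparison.
    """
    P = P or ModelParameters()
    if S.n != CS.n:
        raise ValueError(f"structure has {S.n} points, constraints expect {CS.n}")

    d2_c = _pair_d2(S.points, CS.contacts) if CS.n_contacts else np.empty(0)
    d2_nc = _pair_d2(S.points, CS.noncontacts) if CS.n_noncontacts else np.empty(0)
    sat_c = d2_c < P.dc2
    sat_nc = d2_nc >= P.dc2
    w = CS.contact_weights

    total_if = float(w.sum()) if CS.n_contacts else 0.0
    return EvaluationReport(
        contact_score=float(sat_c.mean()) if CS.n_contacts else 1.0,
        noncontact_score=float(sat_nc.mean()) if CS.n_noncontacts else 1.0,
        satisfied_if_pct=(
            100.0 * float(w[sat_c].sum()) / total_if if total_if > 0 else 100.0
        ),
        avg_sq_dist_unsat_contacts=(
            float(d2_c[~sat_c].mean()) if np.any(~sat_c) else None
        ),
        avg_if_unsat_contacts=(float(w[~sat_c].mean()) if np.any(~sat_c) else None),
        avg_sq_dist_unsat_noncontacts=(
            float(d2_nc[~sat_nc].mean()) if np.any(~sat_nc) else None
        ),
        avg_if_all=float(w.mean()) if CS.n_contacts else None,
        n_contacts=CS.n_contacts,
        n_noncontacts=CS.n_noncontacts,
    )


def superimpose(A: Structure, B: Structure) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of B onto A (proper rotation only).

    Returns the superposed copy of B's coordinates and the RMSD.  Chirality
    is preserved: a mirror image keeps a nonzero RMSD.  Near-collinear point
    sets make the rotation ill-determined and raise a warning.
    """
    if A.n != B.n:
        raise ValueError("point counts differ")
    if A.n < 3:
        raise ValueError("superposition needs at least 3 points")
    Ac = A.points - A.points.mean(axis=0)
    Bc = B.points - B.points.mean(axis=0)
    sv = np.linalg.svd(Bc, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        warnings.warn("collinear point set: superposition is degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(Ac, Bc)
    B_fit = rot.apply(Bc) + A.points.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((B_fit - A.points) ** 2, axis=1))))
    return B_fit, rmsd


def _gdt_ha_one_way(A: Structure, B: Structure, thresholds) -> float:
    B_fit, _ = superimpose(A, B)
    dist = np.sqrt(np.sum((B_fit - A.points) ** 2, axis=1))
    return float(np.mean([np.mean(dist < t) for t in thresholds]))


def gdt_ha(
    A: Structure,
    B: Structure,
    thresholds=GDT_HA_THRESHOLDS,
    mirror_aware: bool = True,
) -> float:
    """GDT-HA similarity of two equally sized structures, in [0, 1].

    Mean over the four thresholds of the fraction of index-matched points
    within that distance after a single global superposition.  With
    ``mirror_aware`` the reflected copy of B is also scored and the larger
    value returned, since distance constraints cannot resolve handedness.
    """
    score = _gdt_ha_one_way(A, B, thresholds)
    if mirror_aware:
        B_mirror = Structure(
            points=B.points * np.array([-1.0, 1.0, 1.0]),
            chrom=B.chrom, resolution=B.resolution,
        )
        score = max(score, _gdt_ha_one_way(A, B_mirror, thresholds))
    return score


def gdt_ha_with_flag(
    A: Structure, B: Structure, thresholds=GDT_HA_THRESHOLDS
) -> tuple[float, bool]:
    """Mirror-aware GDT-HA plus whether the mirrored partner scored higher."""
    direct = _gdt_ha_one_way(A, B, thresholds)
    B_mirror = Structure(points=B.points * np.array([-1.0, 1.0, 1.0]))
    mirrored = _gdt_ha_one_way(A, B_mirror, thresholds)
    return (mirrored, True) if mirrored > direct else (direct, False)


def pairwise_similarity(
    E: Ensemble, thresholds=GDT_HA_THRESHOLDS
) -> SimilarityMatrix:
    """All-pairs GDT-HA matrix of an ensemble (diagonal = 1)."""
    m = len(E)
    if m < 2:
        raise ValueError("pairwise similarity needs at least 2 structures")
    values = np.eye(m)
    mirror = np.zeros((m, m), dtype=bool)
    for a in range(m):
        for b in range(a + 1, m):
            s, used = gdt_ha_with_flag(E.structures[a], E.structures[b], thresholds)
            values[a, b] = values[b, a] = s
            mirror[a, b] = mirror[b, a] = used
    return SimilarityMatrix(values=values, mirror_used=mirror)


def select_representative(
    E: Ensemble, similarity: SimilarityMatrix | None = None,
    distance: str = "inverse",
) -> int:
    """Index of the ensemble medoid under the GDT-HA-derived distance.

    With a single cluster the K-medoids solution is the exact medoid: the
    member minimizing the summed distance 1/GDT-HA (floored at 1e-6) to all
    others.  ``distance="one_minus"`` switches to 1 - GDT-HA.  Ties break to
    the lowest index.
    """
    if len(E) == 0:
        raise ValueError("empty ensemble")
    if len(E) == 1:
        return 0
    sim = similarity if similarity is not None else pairwise_similarity(E)
    S = np.clip(sim.values, _GDT_FLOOR, None)
    if distance == "inverse":
        D = 1.0 / S
    elif distance == "one_minus":
        D = 1.0 - np.clip(sim.values, 0.0, 1.0)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    np.fill_diagonal(D, 0.0)
    sums = D.sum(axis=1)
    return int(np.argmin(sums))  # argmin takes the first (lowest) index on ties


def compare_ensembles(
    E1: Ensemble, E2: Ensemble, mode: str = "all_pairs",
    thresholds=GDT_HA_THRESHOLDS,
) -> float:
    """Mean GDT-HA between two ensembles.

    ``all_pairs`` averages over every cross pair; ``representative``
    compares only the two medoid models.
    """
    if E1.structures[0].n != E2.structures[0].n:
        raise ValueError("ensembles have different point counts")
    if mode == "representative":
        a = E1.structures[select_representative(E1)]
        b = E2.structures[select_representative(E2)]
        return gdt_ha(a, b, thresholds)
    if mode != "all_pairs":
        raise ValueError(f"unknown mode {mode!r}")
    scores = [
        gdt_ha(a, b, thresholds)
        for a in E1.structures
        for b in E2.structures
    ]
    return float(np.mean(scores))


@dataclass
class RobustnessResult:
    recovery_pct: float
    table: pd.DataFrame       # columns: i, j, normalized_if, recovered
    structure: Structure
    kept: int
    withheld: int


def robustness_test(
    CS: ConstraintSet,
    keep_fraction: float = 0.7,
    P: ModelParameters | None = None,
    opts: OptimizerOptions | None = None,
    seed: int | None = None,
) -> RobustnessResult:
    """Withhold a random share of contacts and measure their recovery.

    A fraction ``keep_fraction`` of contacts is sampled for training; the
    withheld remainder is reclassified as non-contacts.  A model is
    reconstructed from the degraded constraint set and a withheld contact
    counts as recovered when its squared model distance falls below the
    contact threshold.  The per-contact table (normalized IF + recovery
    flag) supports ranking recovery by interaction strength.
    """
    if not (0 < keep_fraction < 1):
        raise ValueError("keep_fraction must lie in (0, 1)")
    P = P or ModelParameters()
    opts = opts or OptimizerOptions()
    rng = np.random.default_rng(opts.seed if seed is None else seed)

    k = CS.n_contacts
    n_keep = int(round(keep_fraction * k))
    if n_keep == 0 or n_keep == k:
        raise ValueError(
            f"keep_fraction {keep_fraction} leaves a degenerate split of "
            f"{k} contacts"
        )
    perm = rng.permutation(k)
    withheld_rows = perm[n_keep:]
    train = CS.replace_withheld(withheld_rows)

    res = reconstruct(train, P, opts)
    d2 = _pair_d2(res.structure.points, CS.contacts[withheld_rows])
    recovered = d2 < P.dc2
    table = pd.DataFrame(
        {
            "i": CS.contacts[withheld_rows, 0],
            "j": CS.contacts[withheld_rows, 1],
            "normalized_if": CS.contact_weights[withheld_rows],
            "recovered": recovered,
        }
    ).sort_values("normalized_if", ascending=False, ignore_index=True)
    return RobustnessResult(
        recovery_pct=100.0 * float(recovered.mean()),
        table=table,
        structure=res.structure,
        kept=n_keep,
        withheld=k - n_keep,
    )
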