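"""Two-compartment (A/B chromatin) assignment from contact maps by PCA.

Chromatin partitions into two large-scale classes with enriched intra-class
contacts.  The sign of the first principal component of the (optionally
correlation-transformed) normalized contact map splits bins into the two
classes.  Labels are the neutral {1, 2}: mapping sign groups onto
euchromatin/heterochromatin requires external annotation (gene density, GC)
that is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ContactMatrix, write_structure
from .model import Structure

__all__ = [
    "CompartmentAssignment",
    "assign_compartments",
    "compartment_profiles",
    "color_structure",
    "labels_equivalent",
]

_DEGENERACY_RTOL = 1e-6  # PC1 vs PC2 variance ratio considered degenerate


@dataclass
class CompartmentAssignment:
    labels: np.ndarray            # per-bin label in {1, 2}
    pc1: np.ndarray               # first principal-component loading per bin
    variance_explained: float     # fraction of variance carried by PC1
    degenerate: bool              # PC1 ~ PC2 spectrum, labels unreliable

    @property
    def n(self) -> int:
        return len(self.labels)


def assign_compartments(
    N: ContactMatrix, use_correlation: bool = True
) -> CompartmentAssignment:
    """Assign each bin to one of two compartments by the sign of PC1.

    With ``use_correlation`` (the field convention) the Pearson correlation
    matrix of the normalized map is analyzed; otherwise the map itself.  The
    sign convention is deterministic: the loading with the largest absolute
    value is made positive.  Label 1 marks nonnegative loadings, label 2
    negative ones.  A spectrum whose top two components are (near-)equal is
    flagged degenerate.
    """
    if N.n < 4:
        raise ValueError("compartment analysis needs at least 4 bins")
    X = np.asarray(N.values, dtype=float).copy()
    # the self-contact diagonal carries no compartment signal and, left at
    # zero, injects artifact variance; replace it with each bin's
    # off-diagonal mean before analysis
    off_mean = (X.sum(axis=1) - np.diag(X)) / (N.n - 1)
    np.fill_diagonal(X, off_mean)
    if np.allclose(X, X.flat[0]):
        raise ValueError("constant contact map has no compartment signal")
    if use_correlation:
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError(
                "zero-variance bins present; mask them before correlation PCA"
            )
        X = np.corrcoef(X)

    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(X - X.mean(axis=0))
    pc1 = pca.components_[0]
    var = pca.explained_variance_
    degenerate = bool(np.isclose(var[0], var[1], rtol=_DEGENERACY_RTOL)) or var[0] <= 0

    anchor = int(np.argmax(np.abs(pc1)))
    if pc1[anchor] < 0:
        pc1 = -pc1
    labels = np.where(pc1 >= 0, 1, 2)
    if len(np.unique(labels)) < 2:
        degenerate = True
    total_var = float(var.sum()) if var.sum() > 0 else 1.0
    return CompartmentAssignment(
        labels=labels.astype(int),
        pc1=pc1,
        variance_explained=float(pca.explained_variance_ratio_[0]),
        degenerate=degenerate,
    )


def labels_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Whether two binary labelings agree up to swapping the label names."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    swapped = np.where(b == 1, 2, 1)
    return bool(np.array_equal(a, b) or np.array_equal(a, swapped))


def compartment_profiles(
    S: Structure,
    N: ContactMatrix,
    A: CompartmentAssignment,
    max_genomic_distance_bins: int | None = None,
) -> pd.DataFrame:
    """Mean spatial distance and mean IF versus genomic separation.

    For each separation s = 2..max (in bins) and each stratum — both bins in
    compartment 1, both in 2, or one in each (between) — reports the mean
    Euclidean distance in the structure and the mean normalized IF.  Strata
    with no pairs at a separation are simply absent.
    """
    if not (S.n == N.n == A.n):
        raise ValueError("structure, matrix and assignment sizes differ")
    max_s = max_genomic_distance_bins or (S.n - 1)
    rows = []
    for s in range(2, max_s + 1):
        i = np.arange(S.n - s)
        j = i + s
        d = np.sqrt(np.sum((S.points[i] - S.points[j]) ** 2, axis=1))
        ifs = N.values[i, j]
        li, lj = A.labels[i], A.labels[j]
        strata = {
            "within-1": (li == 1) & (lj == 1),
            "within-2": (li == 2) & (lj == 2),
            "between": li != lj,
        }
        for name, mask in strata.items():
            if not np.any(mask):
                continue
            rows.append(
                {
                    "separation_bins": s,
                    "stratum": name,
                    "mean_distance": float(d[mask].mean()),
                    "mean_if": float(ifs[mask].mean()),
                    "n_pairs": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def color_structure(
    S: Structure, A: CompartmentAssignment, path
) -> None:
    """Write a PDB trace with compartment labels in the B-factor column."""
    if S.n != A.n:
        raise ValueError("structure and assignment sizes differ")
    write_structure(S, path, format="pdb", b_factors=A.labels.astype(float))
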