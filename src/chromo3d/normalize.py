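"""Observed/expected normalization and likelihood-ratio contact filtering.

Raw Hi-C counts carry strong coverage biases, so each entry is divided by
its expected value under a marginal-product null: with row totals m_i and
grand total T, the expected IF of pair (i, j) is m_i * m_j / T and the
normalized IF is

    N_ij = C_ij * T / (m_i * m_j)

N_ij is the likelihood ratio (odds) of observing the contact relative to
chance; values above a cutoff define the contact set used to constrain the
3D model.  Genomically adjacent bin pairs are handled by the objective's
adjacency term and are therefore kept out of both the contact and the
non-contact set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ContactMatrix

__all__ = [
    "ConstraintSet",
    "normalize_matrix",
    "apply_cutoff",
    "contact_percentages",
]


@dataclass
class ConstraintSet:
    """Partition of the upper-triangle bin pairs into contacts (with their
    normalized-IF weights), non-contacts and adjacent pairs."""

    n: int
    cutoff: float
    contacts: np.ndarray            # (k, 2) int pairs, i + 1 < j (or gap pairs)
    contact_weights: np.ndarray     # (k,) normalized IFs, each > cutoff
    noncontacts: np.ndarray         # (m, 2) int pairs
    adjacent: np.ndarray            # (a, 2) consecutive modeled-bin pairs

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=int).reshape(-1, 2)
        self.noncontacts = np.asarray(self.noncontacts, dtype=int).reshape(-1, 2)
        self.adjacent = np.asarray(self.adjacent, dtype=int).reshape(-1, 2)
        self.contact_weights = np.asarray(self.contact_weights, dtype=float)
        if len(self.contact_weights) != len(self.contacts):
            raise ValueError("one weight per contact required")
        seen = set()
        for arr in (self.contacts, self.noncontacts, self.adjacent):
            for i, j in arr:
                if not (0 <= i < j < self.n):
                    raise ValueError(f"invalid pair ({i}, {j}) for n={self.n}")
                if (i, j) in seen:
                    raise ValueError(f"pair ({i}, {j}) assigned twice")
                seen.add((i, j))

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def n_noncontacts(self) -> int:
        return len(self.noncontacts)

    def contact_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.contacts[:, 0], self.contacts[:, 1]

    def noncontact_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.noncontacts[:, 0], self.noncontacts[:, 1]

    def adjacent_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.adjacent[:, 0], self.adjacent[:, 1]

    def replace_withheld(self, withheld_rows: np.ndarray) -> "ConstraintSet":
        """Return a copy with the given contact rows moved to non-contacts."""
        mask = np.zeros(self.n_contacts, dtype=bool)
        mask[withheld_rows] = True
        return replace(
            self,
            contacts=self.contacts[~mask],
            contact_weights=self.contact_weights[~mask],
            noncontacts=np.vstack([self.noncontacts, self.contacts[mask]]),
        )


def normalize_matrix(C: ContactMatrix) -> ContactMatrix:
    """Normalize a raw IF matrix by the observed/expected ratio.

    Marginals and the total are taken over the matrix as given.  Bins with a
    zero marginal (e.g. unmappable regions that slipped through) are masked:
    their rows/columns are set to zero and excluded from the expectation.
    """
    if C.normalized:
        raise ValueError("matrix is already normalized")
    V = C.values
    if np.any(V < 0):
        raise ValueError("raw matrix entries must be nonnegative")
    m = V.sum(axis=1)
    T = V.sum()
    if T <= 0:
        raise ValueError("cannot normalize an all-zero matrix")
    live = m > 0
    expected = np.outer(m, m) / T
    N = np.zeros_like(V)
    mask = np.outer(live, live)
    N[mask] = V[mask] * T / (np.outer(m, m)[mask])
    return ContactMatrix(
        values=N, regions=C.regions, resolution=C.resolution,
        normalized=True, chrom=C.chrom,
    )


def _adjacency_pairs(N: ContactMatrix) -> np.ndarray:
    """Consecutive-bin pairs, skipping pairs that straddle an unmodeled gap.

    Without region metadata every (i, i+1) pair is adjacent.  With regions,
    two consecutive modeled bins are adjacent only when genomically
    contiguous (no centromere gap between them): the physical linker through
    an unmodeled gap is not represented, so no adjacency force applies.
    """
    n = N.n
    if N.regions is None:
        return np.column_stack([np.arange(n - 1), np.arange(1, n)])
    pairs = []
    for i in range(n - 1):
        a, b = N.regions[i], N.regions[i + 1]
        if a.chrom == b.chrom and a.end == b.start:
            pairs.append((i, i + 1))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def apply_cutoff(N: ContactMatrix, cutoff: float) -> ConstraintSet:
    """Partition bin pairs by the likelihood-ratio cutoff.

    A pair (i, j) with i + 1 < j is a contact iff N_ij > cutoff (strict),
    otherwise a non-contact; consecutive pairs (i, i+1) form the adjacency
    set regardless of IF.  Consecutive modeled bins flanking an unmodeled
    gap are not adjacent and are classified by the cutoff instead.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    if not N.normalized:
        raise ValueError("apply_cutoff expects a normalized matrix")
    n = N.n
    adjacent = _adjacency_pairs(N)
    adj_set = {(int(i), int(j)) for i, j in adjacent}
    iu, ju = np.triu_indices(n, k=1)
    keep = np.array([(i, j) not in adj_set for i, j in zip(iu, ju)])
    iu, ju = iu[keep], ju[keep]
    vals = N.values[iu, ju]
    is_contact = vals > cutoff
    return ConstraintSet(
        n=n,
        cutoff=float(cutoff),
        contacts=np.column_stack([iu[is_contact], ju[is_contact]]),
        contact_weights=vals[is_contact],
        noncontacts=np.column_stack([iu[~is_contact], ju[~is_contact]]),
        adjacent=adjacent,
    )


def contact_percentages(
    matrices: ContactMatrix | list[ContactMatrix], cutoff: float
) -> pd.DataFrame:
    """Percentage of bin pairs above the cutoff, per matrix.

    A reporting aid for cutoff selection: with one normalized matrix per
    chromosome (or chromosome pair), returns the fraction of upper-triangle
    pairs whose normalized IF exceeds the cutoff, as a percentage.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("no matrices given")
    rows = []
    for M in matrices:
        if M.n < 2:
            raise ValueError("matrix too small for pair statistics")
        iu, ju = np.triu_indices(M.n, k=1)
        vals = M.values[iu, ju]
        rows.append(
            {
                "chrom": M.chrom,
                "n_bins": M.n,
                "n_pairs": len(vals),
                "pct_in_contact": 100.0 * float(np.mean(vals > cutoff)),
            }
        )
    return pd.DataFrame(rows)
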