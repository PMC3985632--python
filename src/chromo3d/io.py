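"""Text-format I/O for contact matrices, region tables, structures, ensembles.

All formats are plain text so runs are bit-stable and diffable:

* dense matrix  -- whitespace/tab-delimited n rows x n columns
* coo matrix    -- lines ``i j value`` with 0-based indices, symmetrized
* region table  -- BED-like TSV: chrom, start, end, index, modeled
* structure     -- TSV ``index x y z`` at full precision, or a PDB
  pseudo-atom CA trace (one residue per bin) with a REMARK carrying the
  linear scale factor used to fit the PDB coordinate fields
* ensemble      -- JSON bundling structures, seeds, scores and provenance

Conventions: bins are 0-based, genomic intervals half-open.  Centromere or
unmappable bins appear in the region table with ``modeled`` false and are
dropped before matrix construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .model import Structure

__all__ = [
    "GenomicRegion",
    "ContactMatrix",
    "read_matrix",
    "write_matrix",
    "read_regions",
    "write_regions",
    "read_structure",
    "write_structure",
    "read_ensemble",
    "write_ensemble",
]

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class GenomicRegion:
    """A fixed-size genomic bin (0-based, half-open interval)."""

    chrom: str
    start: int
    end: int
    index: int
    modeled: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region end {self.end} must exceed start {self.start}")


def _validate_regions(regions: list[GenomicRegion]) -> None:
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        starts = [r.start for r in rs]
        if starts != sorted(starts):
            raise ValueError("regions of one chromosome must be sorted by start")
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError("regions of one chromosome must not overlap")
    modeled = sorted(r.index for r in regions if r.modeled)
    if modeled != list(range(len(modeled))):
        raise ValueError("modeled bin indices must be consecutive 0..n-1")


@dataclass
class ContactMatrix:
    """Square symmetric nonnegative matrix of interaction frequencies.

    ``values`` holds raw counts or normalized IFs for the *modeled* bins;
    ``regions`` (optional) carries bin metadata in matrix order.
    """

    values: np.ndarray
    regions: list[GenomicRegion] | None = None
    resolution: int = 1_000_000
    normalized: bool = False
    chrom: str = "chr"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("contact matrix entries must be nonnegative")
        if not np.allclose(v, v.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("contact matrix must be symmetric within 1e-9")
        if self.regions is not None:
            if len(self.regions) != v.shape[0]:
                raise ValueError(
                    f"region count {len(self.regions)} != matrix size {v.shape[0]}"
                )
            _validate_regions(self.regions)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def total_if(self) -> float:
        """Sum of upper-triangle (off-diagonal) interaction frequencies."""
        return float(self.values[np.triu_indices(self.n, k=1)].sum())

    @property
    def max_if(self) -> float:
        """Maximum off-diagonal interaction frequency."""
        if self.n < 2:
            return 0.0
        return float(self.values[np.triu_indices(self.n, k=1)].max())


def read_regions(path: str | Path) -> list[GenomicRegion]:
    """Read a BED-like region table: chrom, start, end, index, modeled."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "index", "modeled"],
        dtype={"chrom": str},
    )
    regions = [
        GenomicRegion(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            index=int(row.index), modeled=bool(int(row.modeled)),
        )
        for row in df.itertuples()
    ]
    _validate_regions(regions)
    return regions


def write_regions(regions: list[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.index}\t{int(r.modeled)}\n")


def read_matrix(
    path: str | Path,
    format: str = "dense",
    regions: str | Path | list[GenomicRegion] | None = None,
    resolution: int = 1_000_000,
    chrom: str = "chr",
) -> ContactMatrix:
    """Read a contact matrix from ``dense`` or ``coo`` text.

    COO input lists ``i j value`` triplets (0-based); the matrix is
    symmetrized on load, averaging (i, j) and (j, i) when both are present.
    When a region table accompanies the matrix, unmodeled (e.g. centromere)
    bins are dropped and the retained rows follow modeled-bin order; the
    matrix must then match the modeled bin count.
    """
    region_list: list[GenomicRegion] | None
    if regions is None:
        region_list = None
    elif isinstance(regions, (str, Path)):
        region_list = read_regions(regions)
    else:
        region_list = list(regions)

    if format == "dense":
        rows = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not rows:
            raise ValueError(f"empty matrix file: {path}")
        ncols = {len(r) for r in rows}
        if len(ncols) != 1 or ncols.pop() != len(rows):
            raise ValueError(f"non-square dense matrix in {path}")
        values = np.array(rows, dtype=float)
    elif format == "coo":
        tri = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not tri:
            raise ValueError(f"empty matrix file: {path}")
        ii = np.array([int(t[0]) for t in tri])
        jj = np.array([int(t[1]) for t in tri])
        vv = np.array([float(t[2]) for t in tri])
        n = int(max(ii.max(), jj.max())) + 1
        if region_list is not None:
            n = max(n, sum(r.modeled for r in region_list))
        if ii.min() < 0 or jj.min() < 0:
            raise ValueError("coo indices must be nonnegative")
        acc = np.zeros((n, n))
        cnt = np.zeros((n, n))
        np.add.at(acc, (ii, jj), vv)
        np.add.at(cnt, (ii, jj), 1.0)
        sym_acc = acc + acc.T
        sym_cnt = cnt + cnt.T
        # average of (i,j) and (j,i) where both given, value where one given
        with np.errstate(invalid="ignore"):
            values = np.where(sym_cnt > 0, sym_acc / np.maximum(sym_cnt, 1), 0.0)
        np.fill_diagonal(values, np.where(np.diag(cnt) > 0, np.diag(acc) / np.maximum(np.diag(cnt), 1), 0.0))
    else:
        raise ValueError(f"unknown matrix format {format!r}")

    if np.any(values < 0):
        raise ValueError("contact matrix entries must be nonnegative")

    if region_list is not None:
        modeled = [r for r in region_list if r.modeled]
        if len(modeled) != values.shape[0]:
            if len(region_list) == values.shape[0]:
                keep = [i for i, r in enumerate(region_list) if r.modeled]
                values = values[np.ix_(keep, keep)]
            else:
                raise ValueError(
                    f"region table lists {len(modeled)} modeled bins but "
                    f"matrix has {values.shape[0]} rows"
                )
        region_list = modeled
        chrom = region_list[0].chrom
        resolution = region_list[0].end - region_list[0].start

    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return ContactMatrix(
        values=values, regions=region_list, resolution=resolution,
        normalized=False, chrom=chrom,
    )


def write_matrix(M: ContactMatrix, path: str | Path, format: str = "dense") -> None:
    """Write a contact matrix as dense TSV or COO triplets (upper triangle)."""
    if format == "dense":
        np.savetxt(path, M.values, delimiter="\t", fmt="%.17g")
    elif format == "coo":
        with open(path, "w") as fh:
            ii, jj = np.nonzero(np.triu(M.values))
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\t{M.values[i, j]:.17g}\n")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


# -- structures --------------------------------------------------------------

_PDB_COORD_LIMIT = 999.0  # keep |coord| within the 8.3 PDB field


def write_structure(
    S: Structure, path: str | Path, format: str = "tsv",
    b_factors: np.ndarray | None = None,
) -> None:
    """Write a structure as TSV (``index x y z``) or a PDB CA trace.

    PDB coordinates are scaled by a linear factor so they fit the fixed-width
    fields; the factor is recorded in a ``REMARK 250 CHROMO3D SCALE`` line and
    undone by :func:`read_structure`.  ``b_factors`` (PDB only) allows e.g.
    compartment labels to ride along in the B-factor column.
    """
    if S.n < 1:
        raise ValueError("structure must have at least one point")
    if not np.all(np.isfinite(S.points)):
        raise ValueError("structure coordinates must be finite")
    if format == "tsv":
        with open(path, "w") as fh:
            for i, (x, y, z) in enumerate(S.points):
                fh.write(f"{i}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")
        return
    if format != "pdb":
        raise ValueError(f"unknown structure format {format!r}")

    extent = float(np.abs(S.points).max())
    scale = 1.0 if extent <= _PDB_COORD_LIMIT else _PDB_COORD_LIMIT / extent
    if b_factors is not None and len(b_factors) != S.n:
        raise ValueError("b_factors length must match point count")

    st = gemmi.Structure()
    st.name = S.chrom
    mdl = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (x, y, z) in enumerate(S.points * scale):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(x, y, z)
        atom.b_iso = float(b_factors[i]) if b_factors is not None else 0.0
        res.add_atom(atom)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    pdb_text = st.make_pdb_string()
    header = (
        f"REMARK 250 CHROMO3D SCALE {scale:.17g}\n"
        f"REMARK 250 CHROMO3D CHROM {S.chrom} RESOLUTION {S.resolution}\n"
    )
    Path(path).write_text(header + pdb_text)


def read_structure(path: str | Path, format: str = "tsv") -> Structure:
    """Read a structure written by :func:`write_structure`."""
    if format == "tsv":
        text = Path(path).read_text()
        rows = [ln.split() for ln in text.splitlines() if ln.strip()]
        if not rows:
            raise ValueError(f"empty structure file: {path}")
        rows.sort(key=lambda r: int(r[0]))
        points = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
        return Structure(points=points)
    if format != "pdb":
        raise ValueError(f"unknown structure format {format!r}")

    scale = 1.0
    chrom, resolution = "chr", 1_000_000
    for line in Path(path).read_text().splitlines():
        if line.startswith("REMARK 250 CHROMO3D SCALE"):
            scale = float(line.split()[-1])
        elif line.startswith("REMARK 250 CHROMO3D CHROM"):
            parts = line.split()
            chrom, resolution = parts[4], int(parts[6])
    st = gemmi.read_structure(str(path))
    points = []
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    if atom.name == "CA":
                        points.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break
    if not points:
        raise ValueError(f"no CA records found in {path}")
    return Structure(
        points=np.array(points) / scale, chrom=chrom, resolution=resolution
    )


# -- ensembles ----------------------------------------------------------------

def write_ensemble(E, path: str | Path) -> None:
    """Serialize an ensemble (structures + seeds + scores + provenance) to JSON."""
    payload = {
        "chrom": E.structures[0].chrom if E.structures else "chr",
        "resolution": E.structures[0].resolution if E.structures else None,
        "seeds": [int(s) for s in E.seeds],
        "final_scores": [float(s) for s in E.final_scores],
        "provenance": E.provenance,
        "structures": [s.points.tolist() for s in E.structures],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ensemble(path: str | Path):
    from .optimize import Ensemble

    payload = json.loads(Path(path).read_text())
    structures = [
        Structure(
            points=np.array(p), chrom=payload.get("chrom", "chr"),
            resolution=payload.get("resolution") or 1_000_000,
        )
        for p in payload["structures"]
    ]
    return Ensemble(
        structures=structures,
        seeds=list(payload["seeds"]),
        final_scores=list(payload["final_scores"]),
        provenance=payload.get("provenance", {}),
    )
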