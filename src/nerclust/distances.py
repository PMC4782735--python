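"""Occurrence matrices and Sørensen (Dice) dissimilarities.

Species occurrence data is stored species-by-sites: rows are taxa, columns
are localities, cells are specimen counts (or 0/1 presences). Because the
Sørensen index is presence/absence based, count matrices are thresholded
before dissimilarities are computed; downstream clustering then operates on
the pairwise site dissimilarity matrix, never on the raw table.

The Sørensen (Dice) dissimilarity between two sites is

    d = 1 - 2a / (2a + b + c)

where ``a`` is the number of species shared by both sites and ``b``, ``c``
the numbers unique to each. It lies in [0, 1], is 0 for identical species
sets and 1 for disjoint ones, and is in general non-Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "OccurrenceMatrix",
    "SorensenCounts",
    "to_presence_absence",
    "sorensen_dissimilarity",
    "euclidean_distance",
    "read_occurrence",
    "write_occurrence",
    "read_dissimilarity",
    "write_dissimilarity",
]

#: largest tolerated |d[i,j] - d[j,i]| when reading a full square matrix
SYMMETRY_TOL = 1e-9


@dataclass
class OccurrenceMatrix:
    """A species (rows) x sites (columns) count table.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index = species ids, columns = site ids.
    true_regions : ndarray of int, optional
        One region label per site, recorded when the matrix comes from the
        simulator (the known clustering solution). Must contain at least two
        distinct regions when present.
    """

    counts: pd.DataFrame
    true_regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.counts.to_numpy())
        if values.ndim != 2 or values.size == 0:
            raise ValueError("occurrence matrix must be a non-empty 2-D table")
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("occurrence matrix must be numeric")
        if (values < 0).any():
            raise ValueError("occurrence counts must be non-negative")
        empty = values.sum(axis=0) == 0
        if empty.any():
            bad = list(np.asarray(self.counts.columns)[empty])
            raise ValueError(f"sites with no species present: {bad}")
        if self.true_regions is not None:
            self.true_regions = np.asarray(self.true_regions)
            if self.true_regions.shape != (values.shape[1],):
                raise ValueError("true_regions needs one label per site")
            if np.unique(self.true_regions).size < 2:
                raise ValueError("true_regions must contain >= 2 regions")

    @property
    def species_ids(self) -> list:
        return list(self.counts.index)

    @property
    def site_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    def is_binary(self) -> bool:
        v = self.counts.to_numpy()
        return bool(np.isin(v, (0, 1)).all())


@dataclass(frozen=True)
class SorensenCounts:
    """Shared/unique species counts between two sites.

    ``a`` species present in both, ``b`` only in the first, ``c`` only in
    the second. Both sites must be non-empty (a+b >= 1 and a+c >= 1).
    """

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b < 1 or self.a + self.c < 1:
            raise ValueError("both sites must contain at least one species")

    @property
    def dissimilarity(self) -> float:
        return 1.0 - 2.0 * self.a / (2.0 * self.a + self.b + self.c)


def to_presence_absence(m: OccurrenceMatrix) -> OccurrenceMatrix:
    """Threshold counts to 0/1 presences. Idempotent; labels preserved."""
    binary = (m.counts.to_numpy() > 0).astype(np.int64)
    df = pd.DataFrame(binary, index=m.counts.index, columns=m.counts.columns)
    return OccurrenceMatrix(df, true_regions=m.true_regions)


def _sorensen_square(binary: np.ndarray) -> np.ndarray:
    # binary: species x sites, entries in {0, 1}
    shared = binary.T.astype(np.float64) @ binary.astype(np.float64)  # a
    richness = binary.sum(axis=0).astype(np.float64)  # a+b per site
    denom = richness[:, None] + richness[None, :]  # 2a + b + c
    d = 1.0 - 2.0 * shared / denom
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 1.0)


def sorensen_dissimilarity(m: OccurrenceMatrix) -> DistanceMatrix:
    """Pairwise Sørensen dissimilarity between sites of a binary matrix.

    Raises if the matrix still holds counts > 1 (call
    :func:`to_presence_absence` first) — keeping the thresholding step
    explicit avoids silently discarding abundance information.
    """
    if not m.is_binary():
        raise ValueError(
            "sorensen_dissimilarity expects a presence/absence matrix; "
            "apply to_presence_absence() first"
        )
    return DistanceMatrix(_sorensen_square(m.counts.to_numpy()), ids=[str(s) for s in m.site_ids])


def euclidean_distance(m: OccurrenceMatrix) -> DistanceMatrix:
    """Euclidean distances between presence/absence site vectors.

    The Euclidean counterpart used by the Euclidean k-means variant; sites
    are compared as 0/1 vectors over species, so the comparison with the
    Sørensen pipeline isolates the choice of metric.
    """
    binary = (m.counts.to_numpy() > 0).astype(np.float64).T  # sites x species
    d = squareform(pdist(binary, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(s) for s in m.site_ids])


# ---------------------------------------------------------------------------
# file I/O


def read_occurrence(
    path, truth_path=None, sep: str | None = None
) -> OccurrenceMatrix:
    """Read a species x sites CSV/TSV (first column species ids, header = site ids)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    truth = None
    if truth_path is not None:
        t = pd.read_csv(truth_path)
        t = t.set_index(t.columns[0])
        t.index = t.index.map(str)
        truth = t.iloc[:, 0].reindex([str(c) for c in df.columns])
        if truth.isna().any():
            raise ValueError("truth file does not cover every site")
        truth = truth.to_numpy()
    return OccurrenceMatrix(df, true_regions=truth)


def write_occurrence(m: OccurrenceMatrix, path, truth_path=None) -> None:
    m.counts.to_csv(path)
    if truth_path is not None:
        if m.true_regions is None:
            raise ValueError("matrix has no true_regions to write")
        pd.DataFrame({"site_id": m.site_ids, "region": m.true_regions}).to_csv(
            truth_path, index=False
        )


def _mirror_lower_triangle(rows: list[list[float]]) -> np.ndarray:
    n = len(rows) + 1
    d = np.zeros((n, n))
    for i, row in enumerate(rows, start=1):
        if len(row) != i:
            raise ValueError(
                f"strict lower-triangle row {i} should have {i} entries, got {len(row)}"
            )
        d[i, :i] = row
    return d + d.T


def read_dissimilarity(path) -> DistanceMatrix:
    """Read a dissimilarity matrix from CSV.

    Two layouts are accepted: a square matrix with matching row/column
    headers, or headerless strict lower-triangle rows (row i holds the i
    distances to earlier sites). Asymmetry beyond ``SYMMETRY_TOL`` is an
    error; below it the matrix is symmetrised exactly.
    """
    with open(path) as fh:
        first = fh.readline()

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    # A square layout starts with a header row (leading empty index-name
    # field or non-numeric site ids); strict lower-triangle rows are bare
    # numbers, the first holding a single distance.
    tokens = [t for t in first.strip().split(",") if t != ""]
    looks_square = first.startswith(",") or not all(_is_number(t) for t in tokens)
    if tokens and not looks_square:
        with open(path) as fh:
            rows = [
                [float(x) for x in line.strip().split(",") if x != ""]
                for line in fh
                if line.strip()
            ]
        d = _mirror_lower_triangle(rows)
        ids = [f"S{i + 1}" for i in range(d.shape[0])]
    else:
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ValueError("square dissimilarity matrix expected")
        if list(map(str, df.index)) != list(map(str, df.columns)):
            raise ValueError("row and column headers must match")
        d = df.to_numpy(dtype=float)
        if np.max(np.abs(d - d.T)) > SYMMETRY_TOL:
            raise ValueError(
                f"matrix asymmetric beyond tolerance {SYMMETRY_TOL:g}; refusing to average"
            )
        if np.max(np.abs(np.diag(d))) > SYMMETRY_TOL:
            raise ValueError("diagonal must be zero")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        ids = [str(c) for c in df.columns]
    return DistanceMatrix(d, ids=ids)


def write_dissimilarity(dm: DistanceMatrix, path) -> None:
    """Write the full square form with headers (the canonical output layout)."""
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path)
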