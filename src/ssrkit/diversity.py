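"""Diversity statistics and clustering for codominant diploid SSR genotypes.

Genotypes are fragment sizes (bp), two alleles per individual per locus,
with missing data allowed. Per-locus statistics follow the conventions of
the classic codominant-marker packages:

* Na — number of distinct alleles; Ng — number of distinct genotypes.
* A  — major (most frequent) allele frequency.
* Ho — observed heterozygosity: fraction of scored individuals that are
  heterozygous.
* He — Nei's gene diversity 1 - sum(p_i^2), with an optional small-sample
  (2n/(2n-1)) correction.
* PIC — polymorphism information content for codominant markers,
  1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.

Similarity between individuals uses the Dice coefficient 2a/(2a+b+c) over
binary allele-presence "bands" (simple matching available as an option),
with pairwise deletion of loci missing in either individual, and the
dendrogram is built by UPGMA on distance = 1 - similarity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

MISSING = -1


class UndefinedPairError(ValueError):
    """Two individuals share no jointly scored locus; similarity undefined."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid codominant calls for individuals x loci.

    ``calls`` has shape (n_individuals, n_loci, 2) holding fragment sizes
    (positive integers); a missing cell has both entries equal to -1. Within
    a cell the pair is unordered and stored sorted.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {m}, 2)")
        a, b = self.calls[..., 0], self.calls[..., 1]
        half = (a == MISSING) ^ (b == MISSING)
        if half.any():
            raise ValueError("half-called cells are not allowed")
        scored = a != MISSING
        if (a[scored] <= 0).any() or (b[scored] <= 0).any():
            raise ValueError("allele sizes must be positive")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (individuals x loci) mask, True where the cell is missing."""
        return self.calls[..., 0] == MISSING

    # -- round trip to the two-columns-per-locus CSV layout -----------------

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, locus in enumerate(self.loci):
            for k in (0, 1):
                col = self.calls[:, j, k].astype(object)
                col[col == MISSING] = 0
                data[f"{locus}.{k + 1}"] = col
        return pd.DataFrame(data, index=pd.Index(self.individuals, name="individual"))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        cols = list(frame.columns)
        if len(cols) % 2 != 0:
            raise ValueError("expected two columns per locus")
        loci = []
        for c1, c2 in zip(cols[::2], cols[1::2]):
            base1, base2 = c1.rsplit(".", 1)[0], c2.rsplit(".", 1)[0]
            if base1 != base2:
                raise ValueError(f"columns {c1!r}/{c2!r} do not form a locus pair")
            loci.append(base1)
        raw = frame.to_numpy(dtype=float)
        raw = np.nan_to_num(raw, nan=0.0)
        calls = raw.reshape(len(frame), len(loci), 2).astype(np.int64)
        missing = (calls[..., 0] <= 0) | (calls[..., 1] <= 0)
        calls[missing] = MISSING
        calls.sort(axis=2)
        return cls(individuals=[str(i) for i in frame.index], loci=loci, calls=calls)

    @classmethod
    def from_csv(cls, path: str | Path | StringIO) -> "GenotypeMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass(frozen=True)
class LocusStats:
    """Summary statistics for one codominant locus."""

    locus: str
    n_scored: int
    na: int
    ng: int
    major_freq: float
    ho: float
    he: float
    pic: float


def pic_from_freqs(freqs: np.ndarray) -> float:
    """Codominant polymorphism information content from allele frequencies."""
    p2 = np.asarray(freqs, dtype=float) ** 2
    cross = (p2.sum() ** 2 - (p2**2).sum()) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - p2.sum() - 2.0 * cross)


def locus_stats(matrix: GenotypeMatrix, locus: str, unbiased_he: bool = False) -> LocusStats:
    """Na, Ng, major allele frequency, Ho, He and PIC for one locus.

    Frequencies are computed from the two gene copies of every scored
    individual (per-locus deletion of missing cells). Raises ValueError if
    no individual is scored.
    """
    j = matrix.loci.index(locus)
    cell = matrix.calls[:, j, :]
    scored = cell[cell[:, 0] != MISSING]
    n = len(scored)
    if n == 0:
        raise ValueError(f"locus {locus!r} has no scored individuals")
    allele_counts = Counter(scored.ravel().tolist())
    total = 2 * n
    freqs = np.array([c / total for c in allele_counts.values()])
    he = 1.0 - float((freqs**2).sum())
    if unbiased_he:
        he *= total / (total - 1)
    genotypes = {tuple(pair) for pair in scored.tolist()}
    return LocusStats(
        locus=locus,
        n_scored=n,
        na=len(allele_counts),
        ng=len(genotypes),
        major_freq=float(freqs.max()),
        ho=float((scored[:, 0] != scored[:, 1]).mean()),
        he=he,
        pic=pic_from_freqs(freqs),
    )


def locus_stats_table(matrix: GenotypeMatrix, unbiased_he: bool = False) -> pd.DataFrame:
    """Per-locus statistics for every locus, as a table (TSV-ready)."""
    rows = [locus_stats(matrix, locus, unbiased_he) for locus in matrix.loci]
    return pd.DataFrame([vars(r) for r in rows]).set_index("locus")


def _band_matrix(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Binary allele-presence bands per individual.

    Returns (bands, locus_of_band): bands is individuals x n_bands 0/1, and
    locus_of_band maps each band column to its locus index (for pairwise
    deletion of missing loci).
    """
    band_cols: list[np.ndarray] = []
    band_locus: list[int] = []
    for j in range(matrix.n_loci):
        cell = matrix.calls[:, j, :]
        alleles = sorted(set(cell[cell > 0].tolist()))
        for allele in alleles:
            band_cols.append(((cell[:, 0] == allele) | (cell[:, 1] == allele)).astype(np.int8))
            band_locus.append(j)
    if not band_cols:
        raise ValueError("matrix has no scored alleles")
    return np.column_stack(band_cols), np.array(band_locus)


def similarity_matrix(matrix: GenotypeMatrix, coefficient: str = "dice") -> pd.DataFrame:
    """Pairwise similarity between individuals over allele-presence bands.

    ``dice``: 2a / (2a + b + c) where a, b, c count bands present in both,
    only the first, and only the second individual. ``simple_matching``:
    (a + d) / (a + b + c + d), also counting joint absences d. Loci missing
    in either individual of a pair are excluded (pairwise deletion); a pair
    with no jointly scored locus raises :class:`UndefinedPairError`.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need at least two individuals")
    if coefficient not in {"dice", "simple_matching"}:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    bands, band_locus = _band_matrix(matrix)
    missing = matrix.missing_mask()
    n = matrix.n_individuals
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            joint = ~(missing[i] | missing[j])
            if not joint.any():
                raise UndefinedPairError(
                    f"{matrix.individuals[i]} and {matrix.individuals[j]} share no scored locus"
                )
            use = joint[band_locus]
            bi, bj = bands[i, use], bands[j, use]
            a = int((bi & bj).sum())
            b = int((bi & ~bj).sum())
            c = int((~bi & bj).sum())
            if coefficient == "dice":
                s = 2 * a / (2 * a + b + c)
            else:
                d = int((~bi & ~bj).sum())
                s = (a + d) / (a + b + c + d)
            sim[i, j] = sim[j, i] = s
    return pd.DataFrame(sim, index=matrix.individuals, columns=matrix.individuals)


def upgma_tree(similarity: pd.DataFrame) -> TreeNode:
    """UPGMA dendrogram from a similarity matrix (distance = 1 - similarity).

    Agglomeration averages inter-cluster distances weighted by cluster sizes
    (the classic unweighted pair-group method); among tied minimum-distance
    pairs the one with the smallest cluster indices (creation order) merges
    first, so the result is deterministic. The returned tree is rooted,
    binary and ultrametric, with branch lengths so every leaf sits at the
    same depth; serialize with ``str(tree)`` or ``tree.write()`` (Newick).
    """
    labels = list(similarity.index)
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    dist = 1.0 - similarity.to_numpy(dtype=float)
    if not np.allclose(dist, dist.T):
        raise ValueError("similarity matrix must be symmetric")

    # active clusters: id -> (node, size, height); distances in a dict
    nodes = {i: TreeNode(name=labels[i]) for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    heights = {i: 0.0 for i in range(len(labels))}
    d = {(i, j): float(dist[i, j]) for i in range(len(labels)) for j in range(i + 1, len(labels))}
    next_id = len(labels)
    while len(nodes) > 1:
        (i, j) = min(d, key=lambda ij: (d[ij], ij))
        dij = d.pop((i, j))
        height = dij / 2.0
        left, right = nodes.pop(i), nodes.pop(j)
        left.length = height - heights.pop(i)
        right.length = height - heights.pop(j)
        parent = TreeNode(children=[left, right])
        for k in list(nodes):
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(k, next_id), max(k, next_id))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        nodes[next_id] = parent
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        heights[next_id] = height
        next_id += 1
    root = nodes.popitem()[1]
    root.length = None
    return root
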