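"""Classification of SSR loci by genomic context against GFF3 gene models.

Each locus gets exactly one label, chosen by priority when it touches more
than one feature class:

    exon (coding) > 5' UTR > 3' UTR > intron
    > upstream_1kb / downstream_1kb / between_genes_1kb > intergenic

"Upstream" and "downstream" are strand-aware 1 kb windows beyond the gene
span (transcription start / termination side respectively); a locus falling
simultaneously downstream of one gene and upstream of another is
``between_genes_1kb``. A 1 bp overlap suffices for membership. When several
genes compete at the same priority, the gene whose feature starts closest
wins, with a final lexicographic tie-break on gene id, so labels are
deterministic. Only intergenic loci carry no associated gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .repeat_scan import SSRLocus

CONTEXT_LABELS = (
    "exon",
    "five_prime_utr",
    "three_prime_utr",
    "intron",
    "upstream_1kb",
    "downstream_1kb",
    "between_genes_1kb",
    "intergenic",
)

Interval = tuple[int, int]


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _covered(intervals: Sequence[Interval], outer: Interval) -> bool:
    return all(outer[0] <= s and e <= outer[1] for s, e in intervals)


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene: span plus exon/CDS/UTR sub-intervals,
    1-based inclusive, all on the gene's scaffold."""

    gene_id: str
    seq_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[Interval, ...] = ()
    cds: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError("gene span inverted")
        span = (self.start, self.end)
        for name, ivs in (("exon", self.exons), ("CDS", self.cds),
                          ("5'UTR", self.utr5), ("3'UTR", self.utr3)):
            if not _covered(ivs, span):
                raise ValueError(f"{name} intervals of {self.gene_id} fall outside the gene span")

    def upstream_window(self, flank: int) -> Interval:
        if self.strand == "+":
            return (max(1, self.start - flank), self.start - 1)
        return (self.end + 1, self.end + flank)

    def downstream_window(self, flank: int) -> Interval:
        if self.strand == "+":
            return (self.end + 1, self.end + flank)
        return (max(1, self.start - flank), self.start - 1)


@dataclass(frozen=True)
class AnnotatedSSR:
    locus: SSRLocus
    context: str
    gene_ids: tuple[str, ...] = ()


def load_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS/UTR features),
    merging sub-features across transcripts of a gene."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        parts: dict[str, list[Interval]] = {
            "exon": [], "CDS": [], "five_prime_UTR": [], "three_prime_UTR": []
        }
        for ftype in parts:
            for feat in db.children(gene, featuretype=ftype):
                parts[ftype].append((feat.start, feat.end))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=tuple(_merge(parts["exon"])),
                cds=tuple(_merge(parts["CDS"])),
                utr5=tuple(_merge(parts["five_prime_UTR"])),
                utr3=tuple(_merge(parts["three_prime_UTR"])),
            )
        )
    return genes


def _overlap_distance(locus: SSRLocus, intervals: Sequence[Interval]) -> int | None:
    """Distance from the locus start to the start of the nearest overlapped
    interval, or None when nothing overlaps."""
    best = None
    for s, e in intervals:
        if locus.start <= e and locus.end >= s:
            d = abs(locus.start - s)
            best = d if best is None else min(best, d)
    return best


def _gene_label(locus: SSRLocus, gene: GeneModel) -> tuple[int, int] | None:
    """(priority rank, tie-break distance) of the locus within one gene body."""
    for rank, intervals in enumerate((gene.cds, gene.utr5, gene.utr3, gene.exons)):
        d = _overlap_distance(locus, intervals)
        if d is not None:
            return (rank, d)
    if locus.start <= gene.end and locus.end >= gene.start:
        return (4, abs(locus.start - gene.start))  # inside the span: intron
    return None

_RANK_TO_LABEL = {0: "exon", 1: "five_prime_utr", 2: "three_prime_utr", 3: "exon", 4: "intron"}


class GeneIndex:
    """Interval index over gene spans (plus flank) keyed by scaffold."""

    def __init__(self, genes: Iterable[GeneModel], flank: int = 1000) -> None:
        self.flank = flank
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes:
            tree = self._trees.setdefault(gene.seq_id, IntervalTree())
            lo = max(1, gene.start - flank)
            tree[lo : gene.end + flank + 1] = gene

    def nearby(self, locus: SSRLocus) -> list[GeneModel]:
        tree = self._trees.get(locus.seq_id)
        if tree is None:
            return []
        hits = tree[locus.start : locus.end + 1]
        return sorted((h.data for h in hits), key=lambda g: g.gene_id)


def classify_context(
    locus: SSRLocus, genes: Iterable[GeneModel] | GeneIndex, flank: int = 1000
) -> AnnotatedSSR:
    """Assign the single genomic-context label of one SSR locus."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, flank)
    flank = index.flank
    candidates: list[tuple[int, int, str]] = []
    upstream_of: list[GeneModel] = []
    downstream_of: list[GeneModel] = []
    for gene in index.nearby(locus):
        hit = _gene_label(locus, gene)
        if hit is not None:
            candidates.append((hit[0], hit[1], gene.gene_id))
            continue
        us, ue = gene.upstream_window(flank)
        if locus.start <= ue and locus.end >= us:
            upstream_of.append(gene)
        ds, de = gene.downstream_window(flank)
        if locus.start <= de and locus.end >= ds:
            downstream_of.append(gene)
    if candidates:
        rank, _, gene_id = min(candidates)
        return AnnotatedSSR(locus, _RANK_TO_LABEL[rank], (gene_id,))
    if upstream_of and downstream_of:
        ids = tuple(sorted({g.gene_id for g in upstream_of + downstream_of}))
        return AnnotatedSSR(locus, "between_genes_1kb", ids)
    if upstream_of:
        ids = tuple(sorted(g.gene_id for g in upstream_of))
        return AnnotatedSSR(locus, "upstream_1kb", ids)
    if downstream_of:
        ids = tuple(sorted(g.gene_id for g in downstream_of))
        return AnnotatedSSR(locus, "downstream_1kb", ids)
    return AnnotatedSSR(locus, "intergenic", ())


def classify_contexts(
    loci: Iterable[SSRLocus], genes: Iterable[GeneModel], flank: int = 1000
) -> list[AnnotatedSSR]:
    index = GeneIndex(genes, flank)
    return [classify_context(locus, index) for locus in loci]


def summarize_contexts(annotated: Iterable[AnnotatedSSR]) -> pd.DataFrame:
    """Counts and grand-total percentages per context label."""
    counts = Counter(a.context for a in annotated)
    total = sum(counts.values())
    rows = [
        {
            "context": label,
            "count": counts.get(label, 0),
            "percent": round(100.0 * counts.get(label, 0) / total, 2) if total else 0.0,
        }
        for label in CONTEXT_LABELS
    ]
    return pd.DataFrame(rows)


def annotated_to_frame(annotated: Iterable[AnnotatedSSR]) -> pd.DataFrame:
    from .repeat_scan import loci_to_frame

    annotated = list(annotated)
    frame = loci_to_frame(a.locus for a in annotated)
    frame["context"] = [a.context for a in annotated]
    frame["gene_ids"] = [",".join(a.gene_ids) for a in annotated]
    return frame
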