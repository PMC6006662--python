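"""Anchoring scaffolds to a genetic map and naming SSR markers.

A scaffold's genetic position is the arithmetic mean of the centimorgan
positions of the mapped SNPs it carries. Scaffolds whose SNPs all lie on
one linkage group anchor there ("single"); SNPs spread over 2-3 linkage
groups leave the scaffold "ambiguous" (the candidate set is kept); more
than 3 groups, or no mapped SNP at all, leaves it "unknown". SSR loci
inherit their scaffold's anchor.

Markers are named ``Pb`` + motif length + ``L`` + linkage group (``U`` when
not single-anchored) + ``N`` + a zero-padded serial, e.g. ``Pb3L11N5758``
for a trinucleotide marker on linkage group 11.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .primer_design import MarkerCandidate
from .repeat_scan import SSRLocus

MAX_AMBIGUOUS_LGS = 3  # larger candidate sets collapse to unknown
N_LINKAGE_GROUPS = 17


@dataclass(frozen=True)
class SnpMapRecord:
    """One mapped SNP: its scaffold, linkage group (1-17) and position (cM)."""

    snp_id: str
    scaffold: str
    lg: int
    position: float

    def __post_init__(self) -> None:
        if not 1 <= self.lg <= N_LINKAGE_GROUPS:
            raise ValueError(f"linkage group {self.lg} outside 1..{N_LINKAGE_GROUPS}")
        if self.position < 0:
            raise ValueError("genetic position must be >= 0 cM")


@dataclass(frozen=True)
class ScaffoldAnchor:
    scaffold: str
    status: str  # single | ambiguous | unknown
    lg: int | None = None
    lg_set: frozenset[int] = frozenset()
    position: float | None = None


def read_snp_map(path: str | Path) -> list[SnpMapRecord]:
    """Load a genetic-map table (TSV: snp_id, scaffold, lg, position)."""
    frame = pd.read_csv(path, sep="\t")
    return [
        SnpMapRecord(str(r.snp_id), str(r.scaffold), int(r.lg), float(r.position))
        for r in frame.itertuples()
    ]


def compute_scaffold_anchors(map_records: Iterable[SnpMapRecord]) -> list[ScaffoldAnchor]:
    """Anchor every scaffold appearing in the map (see module docstring)."""
    by_scaffold: dict[str, list[SnpMapRecord]] = {}
    for rec in map_records:
        by_scaffold.setdefault(rec.scaffold, []).append(rec)
    anchors = []
    for scaffold in sorted(by_scaffold):
        snps = by_scaffold[scaffold]
        lgs = frozenset(s.lg for s in snps)
        if len(lgs) == 1:
            anchors.append(
                ScaffoldAnchor(
                    scaffold=scaffold,
                    status="single",
                    lg=next(iter(lgs)),
                    lg_set=lgs,
                    position=sum(s.position for s in snps) / len(snps),
                )
            )
        elif len(lgs) <= MAX_AMBIGUOUS_LGS:
            anchors.append(ScaffoldAnchor(scaffold=scaffold, status="ambiguous", lg_set=lgs))
        else:
            anchors.append(ScaffoldAnchor(scaffold=scaffold, status="unknown"))
    return anchors


def anchor_ssr_loci(
    loci: Iterable[SSRLocus], anchors: Iterable[ScaffoldAnchor]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Propagate scaffold anchors to SSR loci.

    Returns a per-locus table (seq_id, start, end, status, lg, position) and
    status counts; loci on scaffolds absent from the map are "unknown". The
    three status counts partition the input.
    """
    index = {a.scaffold: a for a in anchors}
    rows = []
    counts = {"single": 0, "ambiguous": 0, "unknown": 0}
    for locus in loci:
        anchor = index.get(locus.seq_id, ScaffoldAnchor(locus.seq_id, "unknown"))
        counts[anchor.status] += 1
        rows.append(
            {
                "seq_id": locus.seq_id,
                "start": locus.start,
                "end": locus.end,
                "status": anchor.status,
                "lg": anchor.lg,
                "lg_set": ",".join(map(str, sorted(anchor.lg_set))) or None,
                "position": anchor.position,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["seq_id", "start", "end", "status", "lg", "lg_set", "position"]
    )
    return frame, counts


def name_marker(motif_length: int, lg: int | None, serial: int, pad: int = 0) -> str:
    """Marker name: Pb<motif length>L<lg or U>N<zero-padded serial>."""
    if serial < 0:
        raise ValueError("serial must be >= 0")
    lg_code = "U" if lg is None else str(lg)
    return f"Pb{motif_length}L{lg_code}N{serial:0{pad}d}"


_NAME_RE = re.compile(r"^Pb(?P<mlen>[1-6])L(?P<lg>U|\d+)N(?P<serial>\d+)$")


def parse_marker_name(name: str) -> tuple[int, int | None, int]:
    """Inverse of :func:`name_marker`: (motif_length, lg or None, serial)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a valid marker name: {name!r}")
    lg = None if m["lg"] == "U" else int(m["lg"])
    return int(m["mlen"]), lg, int(m["serial"])


def assign_marker_names(
    candidates: Iterable[MarkerCandidate],
    anchors: Iterable[ScaffoldAnchor],
    pad: int | None = None,
) -> list[MarkerCandidate]:
    """Name all candidates, serials consecutive within each motif-length
    series ordered by (linkage group, genetic position, physical position),
    with non-single-anchored loci last. ``pad`` defaults to the natural
    width of the largest serial in each series."""
    candidates = list(candidates)
    index = {a.scaffold: a for a in anchors}

    def sort_key(item: tuple[int, MarkerCandidate]):
        _, cand = item
        anchor = index.get(cand.locus.seq_id, ScaffoldAnchor(cand.locus.seq_id, "unknown"))
        mapped = anchor.status == "single"
        return (
            cand.locus.motif_length,
            not mapped,
            anchor.lg if mapped else 0,
            anchor.position if mapped else 0.0,
            cand.locus.seq_id,
            cand.locus.start,
        )

    ordered = sorted(enumerate(candidates), key=sort_key)
    series_sizes: dict[int, int] = {}
    for _, cand in ordered:
        k = cand.locus.motif_length
        series_sizes[k] = series_sizes.get(k, 0) + 1
    serial_counter: dict[int, int] = {}
    named: list[tuple[int, MarkerCandidate]] = []
    for orig_idx, cand in ordered:
        k = cand.locus.motif_length
        serial_counter[k] = serial_counter.get(k, 0) + 1
        anchor = index.get(cand.locus.seq_id, ScaffoldAnchor(cand.locus.seq_id, "unknown"))
        lg = anchor.lg if anchor.status == "single" else None
        width = pad if pad is not None else len(str(series_sizes[k]))
        name = name_marker(k, lg, serial_counter[k], pad=width)
        named.append((orig_idx, replace(cand, name=name)))
    named.sort(key=lambda t: t[0])
    return [cand for _, cand in named]
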