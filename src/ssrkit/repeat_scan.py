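"""Detection and classification of perfect microsatellites (SSRs).

An SSR is a perfect tandem repeat of a 1-6 bp motif. Detection reports
every maximal perfect tract whose number of complete repeat units meets a
per-class minimum (default 12/8/5/5/5/5 for mono- through hexa-nucleotide
motifs). Motifs are reported at their minimal period (a poly-A run is mono,
never (AA)n) and grouped into canonical classes: the equivalence class of a
motif under cyclic rotation and reverse complement, named by its
lexicographically smallest member (so CT, TC, GA and AG all belong to class
AG).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import is_primitive, reverse_complement, validate_nucleotides

#: Minimum number of complete repeat units per motif length (1..6).
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 8, 3: 5, 4: 5, 5: 5, 6: 5}

CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet A/C/G/T/N (uppercase)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        validate_nucleotides(self.sequence, allow_n=True)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScanConfig:
    """Scan thresholds: minimum full-unit counts per motif length, and the
    maximum gap (bp) below which neighbouring tracts form a compound SSR."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    compound_max_gap: int = 0

    def __post_init__(self) -> None:
        for length, thr in self.min_repeats.items():
            if length not in range(1, 7):
                raise ValueError(f"motif length {length} outside 1..6")
            if thr < 2:
                raise ValueError("minimum repeat thresholds must be >= 2")
        if self.compound_max_gap < 0:
            raise ValueError("compound_max_gap must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat tract (1-based inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    motif_length: int
    n_repeats: int
    compound: bool = False

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1


def canonicalize_motif(motif: str) -> str:
    """Canonical class representative of a repeat motif.

    Returns the lexicographically smallest string among all cyclic rotations
    of the motif and of its reverse complement, so that every member of one
    rotation/strand equivalence class (e.g. AG, GA, CT, TC) maps to the same
    name (AG).

    Raises
    ------
    ValueError
        If the motif is empty, longer than 6 bp, contains characters other
        than ACGT, or is itself a tandem power of a shorter unit.
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside 1..6")
    validate_nucleotides(motif, allow_n=False)
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = reverse_complement(motif)
    n = len(motif)
    rotations = [motif[i:] + motif[:i] for i in range(n)]
    rotations += [rc[i:] + rc[:i] for i in range(n)]
    return min(rotations)


def scan_sequence(record: SequenceRecord, config: ScanConfig | None = None) -> list[SSRLocus]:
    """Find every maximal perfect SSR tract in one sequence.

    A tract is maximal when it cannot be extended by a further repeat unit on
    either side; a trailing partial unit terminates the tract and only full
    units are counted. Motifs are reported at their minimal period on the
    forward strand, anchored at the leftmost position of the maximal perfect
    region. N bases never participate in a tract. Tracts of different periods
    may overlap at their borders; both are reported.
    """
    if config is None:
        config = ScanConfig()
    seq = record.sequence
    n = len(seq)
    loci: list[SSRLocus] = []
    if n == 0:
        return loci
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")
    for period, threshold in sorted(config.min_repeats.items()):
        if n < period * threshold:
            continue
        eq = (arr[period:] == arr[:-period]) & (arr[period:] != n_code) & (arr[:-period] != n_code)
        if not eq.any():
            continue
        # boundaries of maximal runs of True
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive
        for i, j in zip(starts, ends):
            region_len = (j - i) + period  # perfect region incl. final unit
            n_units = region_len // period
            if n_units < threshold:
                continue
            motif = seq[i : i + period]
            if not is_primitive(motif):
                continue  # reported at its true minimal period instead
            loci.append(
                SSRLocus(
                    seq_id=record.id,
                    start=int(i) + 1,
                    end=int(i + n_units * period),
                    motif=motif,
                    canonical_motif=canonicalize_motif(motif),
                    motif_length=period,
                    n_repeats=int(n_units),
                )
            )
    loci.sort(key=lambda l: (l.start, l.motif_length))
    return loci


def flag_compound(loci: Iterable[SSRLocus], config: ScanConfig | None = None) -> list[SSRLocus]:
    """Mark loci that abut (or nearly abut) another tract as compound.

    Two tracts on the same sequence whose gap (start2 - end1 - 1) is at most
    ``config.compound_max_gap`` are both compound; the relation is closed
    transitively along chains, so three mutually adjacent tracts are all
    compound. Overlapping tracts (negative gap) always chain.
    """
    if config is None:
        config = ScanConfig()
    gap_max = config.compound_max_gap
    by_seq: dict[str, list[SSRLocus]] = {}
    for locus in loci:
        by_seq.setdefault(locus.seq_id, []).append(locus)
    out: list[SSRLocus] = []
    for seq_id in by_seq:
        group = sorted(by_seq[seq_id], key=lambda l: (l.start, l.end))
        # connected components of the "gap <= gap_max" interval graph
        cluster: list[SSRLocus] = []
        max_end = 0
        for locus in group:
            if cluster and locus.start - max_end - 1 <= gap_max:
                cluster.append(locus)
                max_end = max(max_end, locus.end)
            else:
                out.extend(_mark_cluster(cluster))
                cluster = [locus]
                max_end = locus.end
        out.extend(_mark_cluster(cluster))
    out.sort(key=lambda l: (l.seq_id, l.start, l.motif_length))
    return out


def _mark_cluster(cluster: list[SSRLocus]) -> list[SSRLocus]:
    compound = len(cluster) > 1
    return [replace(l, compound=compound) for l in cluster]


@dataclass(frozen=True)
class ClassSummary:
    """Counts and grand-total percentages of SSRs per motif-length class,
    per canonical motif, and per (class, repeat-number) cell."""

    total: int
    by_class: dict[int, int]
    by_motif: dict[str, int]
    by_class_repeats: dict[tuple[int, int], int]
    class_percent: dict[int, float]
    motif_percent: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": CLASS_NAMES[k],
                "motif_length": k,
                "count": self.by_class.get(k, 0),
                "percent": self.class_percent.get(k, 0.0),
            }
            for k in range(1, 7)
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "by_class": {CLASS_NAMES[k]: v for k, v in sorted(self.by_class.items())},
                "class_percent": {
                    CLASS_NAMES[k]: v for k, v in sorted(self.class_percent.items())
                },
                "by_motif": dict(sorted(self.by_motif.items())),
                "motif_percent": dict(sorted(self.motif_percent.items())),
            },
            indent=2,
        )


def summarize_classes(loci: Iterable[SSRLocus]) -> ClassSummary:
    """Tabulate SSR counts by motif-length class with percentages of the
    grand total (rounded to 2 decimals). Empty input yields zero counts."""
    loci = list(loci)
    by_class = Counter(l.motif_length for l in loci)
    by_motif = Counter(l.canonical_motif for l in loci)
    by_cell = Counter((l.motif_length, l.n_repeats) for l in loci)
    return summarize_class_counts(by_class, by_motif, by_cell)


def summarize_class_counts(
    by_class: Mapping[int, int],
    by_motif: Mapping[str, int] | None = None,
    by_class_repeats: Mapping[tuple[int, int], int] | None = None,
) -> ClassSummary:
    """Build a :class:`ClassSummary` directly from count tables (e.g. from a
    published survey) rather than from locus objects."""
    total = sum(by_class.values())

    def pct(c: int) -> float:
        return round(100.0 * c / total, 2) if total else 0.0

    by_motif = dict(by_motif or {})
    return ClassSummary(
        total=total,
        by_class=dict(by_class),
        by_motif=by_motif,
        by_class_repeats=dict(by_class_repeats or {}),
        class_percent={k: pct(v) for k, v in by_class.items()},
        motif_percent={m: pct(v) for m, v in by_motif.items()},
    )


def loci_to_frame(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """SSR loci as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "seq_id": l.seq_id,
                "start": l.start,
                "end": l.end,
                "motif": l.motif,
                "canonical_motif": l.canonical_motif,
                "motif_length": l.motif_length,
                "n_repeats": l.n_repeats,
                "compound": l.compound,
            }
            for l in loci
        ],
        columns=[
            "seq_id",
            "start",
            "end",
            "motif",
            "canonical_motif",
            "motif_length",
            "n_repeats",
            "compound",
        ],
    )


def loci_from_frame(frame: pd.DataFrame) -> list[SSRLocus]:
    return [
        SSRLocus(
            seq_id=str(r.seq_id),
            start=int(r.start),
            end=int(r.end),
            motif=str(r.motif),
            canonical_motif=str(r.canonical_motif),
            motif_length=int(r.motif_length),
            n_repeats=int(r.n_repeats),
            compound=bool(r.compound),
        )
        for r in frame.itertuples()
    ]
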