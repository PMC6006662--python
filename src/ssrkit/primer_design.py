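"""Locus-specific PCR primer design for SSR markers.

Primers are chosen by a deterministic exhaustive search of both flanks of a
repeat tract under a fixed constraint box: primer length 18-28 bp (optimum
20), product size 100-300 bp spanning the tract, melting temperature
55-65 C (optimum 60) with at most 1 C difference within a pair, no
homopolymer run of 5+ bases and no self-reverse-complement of 8+ bases
(both filters toggleable). Among all feasible pairs the one minimizing

    |len_f - opt| + |len_r - opt| + |Tm_f - opt| + |Tm_r - opt| + |dTm|

is returned, with ties broken by genomic position, so the design is fully
reproducible. Compound (abutting) SSRs are skipped outright, and after
bulk design any primer sequence recurring across pairs disqualifies every
pair involved, so each retained pair targets a single locus.

Melting temperatures use the unified nearest-neighbor thermodynamic
parameters (Allawi & SantaLucia 1997) at 50 mM monovalent salt and 50 nM
total strand concentration, with the entropic salt correction
0.368 (N-1) ln[Na+].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import reverse_complement, validate_nucleotides
from .repeat_scan import SequenceRecord, SSRLocus

R_GAS = 1.987  # cal / (mol K)

# (dH kcal/mol, dS cal/mol/K) per nearest-neighbor step, unified parameters
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
_SYM_DS = -1.4


class CompoundLocusError(ValueError):
    """Primer design was requested for a compound SSR, which is discarded."""


class NoValidPairError(ValueError):
    """No primer pair satisfies the constraint box for this locus."""


def melting_temperature(oligo: str, na_mM: float = 50.0, oligo_nM: float = 50.0) -> float:
    """Nearest-neighbor duplex melting temperature in degrees C.

    Tm = 1000 dH / (dS + dS_salt + R ln(C_T/x)) - 273.15 with x = 4 for a
    non-self-complementary duplex (x = 1, plus the symmetry entropy term,
    for a self-complementary one). Requires length >= 8 and pure ACGT.
    """
    if len(oligo) < 8:
        raise ValueError("oligo shorter than 8 bases")
    validate_nucleotides(oligo, allow_n=False)
    dh, ds = 0.0, 0.0
    for terminal in (oligo[0], oligo[-1]):
        h, s = _INIT[terminal]
        dh += h
        ds += s
    for i in range(len(oligo) - 1):
        h, s = _NN[oligo[i : i + 2]]
        dh += h
        ds += s
    conc = oligo_nM * 1e-9
    if oligo == reverse_complement(oligo):
        ds += _SYM_DS
        ct_term = math.log(conc)
    else:
        ct_term = math.log(conc / 4.0)
    ds_salt = 0.368 * (len(oligo) - 1) * math.log(na_mM * 1e-3)
    return 1000.0 * dh / (ds + ds_salt + R_GAS * ct_term) - 273.15


@dataclass(frozen=True)
class DesignConstraints:
    """The primer-design constraint box (lengths in bp, temperatures in C)."""

    primer_min: int = 18
    primer_opt: int = 20
    primer_max: int = 28
    product_min: int = 100
    product_max: int = 300
    tm_min: float = 55.0
    tm_opt: float = 60.0
    tm_max: float = 65.0
    max_pair_tm_diff: float = 1.0
    max_homopolymer: int | None = 4  # longest allowed single-base run; None disables
    max_self_complement: int | None = 7  # longest allowed self-revcomp match; None disables

    def __post_init__(self) -> None:
        if not self.primer_min <= self.primer_opt <= self.primer_max:
            raise ValueError("primer length bounds must satisfy min <= opt <= max")
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            raise ValueError("Tm bounds must satisfy min <= opt <= max")
        if self.product_min > self.product_max:
            raise ValueError("product size bounds inverted")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; reverse is written 5'->3' on the opposite strand.

    forward_start and reverse_end are 1-based genome positions of the
    amplicon boundaries, so product_size = reverse_end - forward_start + 1.
    """

    forward: str
    reverse: str
    forward_start: int
    reverse_end: int
    tm_forward: float
    tm_reverse: float
    product_size: int
    ta: float | None = None


@dataclass(frozen=True)
class MarkerCandidate:
    """An SSR locus with its designed pair, uniqueness status and name."""

    locus: SSRLocus
    pair: PrimerPair
    unique: bool = True
    name: str | None = None


def _has_long_homopolymer(seq: str, max_run: int) -> bool:
    run, prev = 1, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        if run > max_run:
            return True
        prev = ch
    return False


def _has_self_complement(seq: str, max_len: int) -> bool:
    """True if seq contains a word of length max_len+1 whose reverse
    complement also occurs in seq (a fold-back/hairpin risk)."""
    w = max_len + 1
    if len(seq) < w:
        return False
    words = {seq[i : i + w] for i in range(len(seq) - w + 1)}
    return any(reverse_complement(word) in words for word in words)


def primer_is_valid(seq: str, constraints: DesignConstraints) -> bool:
    """Single-primer feasibility: alphabet, Tm box and sequence filters.
    Length is assumed already within bounds by construction."""
    if "N" in seq:
        return False
    if constraints.max_homopolymer is not None and _has_long_homopolymer(
        seq, constraints.max_homopolymer
    ):
        return False
    if constraints.max_self_complement is not None and _has_self_complement(
        seq, constraints.max_self_complement
    ):
        return False
    tm = melting_temperature(seq)
    return constraints.tm_min <= tm <= constraints.tm_max


def _flank_candidates(
    genome_seq: str,
    lo: int,
    hi: int,
    constraints: DesignConstraints,
    reverse_strand: bool,
) -> list[tuple[int, int, str, float]]:
    """All valid primers fully inside the 1-based window [lo, hi].

    Returns (start, end, primer_sequence, tm); for the reverse strand the
    primer sequence is the reverse complement of the genomic slice.
    """
    out = []
    for start in range(lo, hi + 1):
        for length in range(constraints.primer_min, constraints.primer_max + 1):
            end = start + length - 1
            if end > hi:
                break
            seq = genome_seq[start - 1 : end]
            primer = reverse_complement(seq) if reverse_strand else seq
            if primer_is_valid(primer, constraints):
                out.append((start, end, primer, melting_temperature(primer)))
    return out


def design_primer_pair(
    locus: SSRLocus,
    genome: SequenceRecord,
    constraints: DesignConstraints | None = None,
) -> PrimerPair:
    """Best feasible primer pair for one SSR locus (exhaustive search).

    Both flanks are enumerated over every start and length allowed by the
    product-size box; feasible combinations are ranked by the length/Tm
    penalty and the minimum returned, ties broken by (forward_start,
    forward length, reverse_end, reverse length). Raises
    :class:`CompoundLocusError` for compound loci and
    :class:`NoValidPairError` when the constraint box is infeasible.
    """
    if constraints is None:
        constraints = DesignConstraints()
    if locus.compound:
        raise CompoundLocusError(f"locus {locus.seq_id}:{locus.start}-{locus.end} is compound")
    seq = genome.sequence
    n = len(seq)
    s, e = locus.start, locus.end
    # forward primer entirely in the left flank, close enough for max product
    f_lo = max(1, e - constraints.product_max + 1)
    f_hi = s - 1
    r_lo = e + 1
    r_hi = min(n, s + constraints.product_max - 1)
    if f_hi - f_lo + 1 < constraints.primer_min or r_hi - r_lo + 1 < constraints.primer_min:
        raise NoValidPairError("flanks too short for any primer")
    fwd = _flank_candidates(seq, f_lo, f_hi, constraints, reverse_strand=False)
    rev = _flank_candidates(seq, r_lo, r_hi, constraints, reverse_strand=True)
    if not fwd or not rev:
        raise NoValidPairError("no feasible single primer in a flank")

    f_start = np.array([c[0] for c in fwd])
    f_len = np.array([c[1] - c[0] + 1 for c in fwd])
    f_tm = np.array([c[3] for c in fwd])
    r_end = np.array([c[1] for c in rev])
    r_len = np.array([c[1] - c[0] + 1 for c in rev])
    r_tm = np.array([c[3] for c in rev])

    product = r_end[None, :] - f_start[:, None] + 1
    dtm = np.abs(f_tm[:, None] - r_tm[None, :])
    feasible = (
        (product >= constraints.product_min)
        & (product <= constraints.product_max)
        & (dtm <= constraints.max_pair_tm_diff)
    )
    if not feasible.any():
        raise NoValidPairError("no pair satisfies product size and Tm-difference limits")
    pen = (
        np.abs(f_len - constraints.primer_opt)[:, None]
        + np.abs(r_len - constraints.primer_opt)[None, :]
        + np.abs(f_tm - constraints.tm_opt)[:, None]
        + np.abs(r_tm - constraints.tm_opt)[None, :]
        + dtm
    )
    pen = np.where(feasible, pen, np.inf)
    best = pen.min()
    ties = np.argwhere(pen <= best + 1e-12)
    keys = [(f_start[i], f_len[i], r_end[j], r_len[j], i, j) for i, j in ties]
    _, _, _, _, i, j = min(keys)
    return PrimerPair(
        forward=fwd[i][2],
        reverse=rev[j][2],
        forward_start=int(f_start[i]),
        reverse_end=int(r_end[j]),
        tm_forward=float(f_tm[i]),
        tm_reverse=float(r_tm[j]),
        product_size=int(product[i, j]),
    )


def assign_annealing_temperature(pair: PrimerPair) -> PrimerPair:
    """Annealing temperature rule: round the lower primer Tm, subtract 3 C,
    clip to [50, 65]. Returns a copy with ``ta`` set."""
    ta = round(min(pair.tm_forward, pair.tm_reverse)) - 3
    ta = min(65, max(50, ta))
    return replace(pair, ta=float(ta))


def deduplicate_pairs(candidates: Iterable[MarkerCandidate]) -> list[MarkerCandidate]:
    """Disqualify every candidate whose forward or reverse primer sequence
    also occurs (in either role) in another candidate; idempotent."""
    candidates = list(candidates)
    owners: dict[str, set[int]] = {}
    for idx, cand in enumerate(candidates):
        for primer in {cand.pair.forward, cand.pair.reverse}:
            owners.setdefault(primer, set()).add(idx)
    shared = {idx for ids in owners.values() if len(ids) > 1 for idx in ids}
    return [
        replace(cand, unique=idx not in shared) for idx, cand in enumerate(candidates)
    ]


def design_markers(
    loci: Iterable[SSRLocus],
    genome: SequenceRecord | dict[str, SequenceRecord],
    constraints: DesignConstraints | None = None,
) -> tuple[list[MarkerCandidate], dict[str, int]]:
    """Design primers for a batch of loci with full retention bookkeeping.

    Returns the candidate list (including non-unique ones, flagged) and a
    count dict whose categories partition the input:
    skipped_compound + no_valid_pair + dedup_removed + retained == n_loci.
    """
    if constraints is None:
        constraints = DesignConstraints()
    genomes = genome if isinstance(genome, dict) else {genome.id: genome}
    counts = {"n_loci": 0, "designed": 0, "skipped_compound": 0, "no_valid_pair": 0}
    candidates = []
    for locus in loci:
        counts["n_loci"] += 1
        if locus.compound:
            counts["skipped_compound"] += 1
            continue
        try:
            pair = design_primer_pair(locus, genomes[locus.seq_id], constraints)
        except NoValidPairError:
            counts["no_valid_pair"] += 1
            continue
        candidates.append(MarkerCandidate(locus=locus, pair=assign_annealing_temperature(pair)))
        counts["designed"] += 1
    candidates = deduplicate_pairs(candidates)
    counts["dedup_removed"] = sum(not c.unique for c in candidates)
    counts["retained"] = sum(c.unique for c in candidates)
    return candidates, counts


def markers_to_frame(candidates: Iterable[MarkerCandidate]) -> pd.DataFrame:
    """Marker table with primer sequences, temperatures and coordinates."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "name": c.name,
                "motif": c.locus.motif,
                "canonical_motif": c.locus.canonical_motif,
                "n_repeats": c.locus.n_repeats,
                "forward": c.pair.forward,
                "reverse": c.pair.reverse,
                "tm_f": round(c.pair.tm_forward, 2),
                "tm_r": round(c.pair.tm_reverse, 2),
                "ta": c.pair.ta,
                "expected_product": c.pair.product_size,
                "seq_id": c.locus.seq_id,
                "start": c.locus.start,
                "end": c.locus.end,
                "unique": c.unique,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "motif", "canonical_motif", "n_repeats", "forward", "reverse",
            "tm_f", "tm_r", "ta", "expected_product", "seq_id", "start", "end", "unique",
        ],
    )
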