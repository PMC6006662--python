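"""Synthetic genomes with planted SSRs and simulated genotype panels.

Two generators make every pipeline stage testable without any download:

* :func:`generate_genome_with_planted_ssrs` builds a random background
  sequence guaranteed (by rejection sampling) to contain no SSR at the
  default thresholds, then splices in repeat tracts at known coordinates,
  returning both the sequence and a truth table.

* :func:`simulate_genotypes` draws diploid codominant genotypes (allele =
  fragment size in bp) for a panel of individuals from population-specific
  allele frequencies. The :func:`pear44_preset` emulates a diversity panel
  of 44 cultivars typed at 18 loci with 5-15 alleles per locus: two diverged
  populations (14 and 29 individuals, mirroring a European and an Asian
  group) plus a single outlier individual drawn from private frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import GenotypeMatrix
from .repeat_scan import ScanConfig, SequenceRecord, scan_sequence

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedRepeatSpec:
    """One repeat tract to plant: motif repeated n_repeats times starting at
    a 1-based position."""

    motif: str
    n_repeats: int
    position: int
    seq_id: str = "synthetic"

    @property
    def tract(self) -> str:
        return self.motif * self.n_repeats

    @property
    def end(self) -> int:
        return self.position + len(self.tract) - 1


def _random_clean_background(length: int, rng: np.random.Generator, config: ScanConfig,
                             max_tries: int = 200) -> str:
    """Uniform-ACGT sequence with no SSR at or above the scan thresholds."""
    for _ in range(max_tries):
        seq = bytes(rng.choice(BASES, size=length)).decode("ascii")
        if not scan_sequence(SequenceRecord("bg", seq), config):
            return seq
    raise RuntimeError("could not sample an SSR-free background; length too large?")


def generate_genome_with_planted_ssrs(
    specs: list[PlantedRepeatSpec],
    length: int,
    seed: int,
    config: ScanConfig | None = None,
    seq_id: str = "synthetic",
) -> tuple[SequenceRecord, pd.DataFrame]:
    """Build a synthetic sequence containing exactly the planted tracts.

    The background is rejection-sampled to be SSR-free under ``config`` so the
    truth table below is the complete expected scanner output. Planted tracts
    must fit inside ``length`` and not overlap. Splice boundaries can in
    principle extend a planted tract by chance; the truth table records the
    planted coordinates, and generation re-rolls the background until a scan
    of the final sequence matches the planted tracts exactly, so the result
    is a guaranteed round-trip fixture.

    Returns
    -------
    (record, truth) where truth has columns seq_id, start, end, motif,
    n_repeats sorted by start.
    """
    if config is None:
        config = ScanConfig()
    rng = np.random.default_rng(seed)
    specs = sorted(specs, key=lambda s: s.position)
    prev_end = 0
    for s in specs:
        if s.position <= prev_end:
            raise ValueError(f"planted tract at {s.position} overlaps the previous tract")
        if s.end > length:
            raise ValueError(f"planted tract at {s.position} does not fit in length {length}")
        prev_end = s.end
    for _ in range(200):
        background = _random_clean_background(length, rng, config)
        chars = list(background)
        for s in specs:
            chars[s.position - 1 : s.end] = s.tract
        seq = "".join(chars)
        record = SequenceRecord(seq_id, seq)
        found = {(l.start, l.end, l.motif) for l in scan_sequence(record, config)}
        wanted = {(s.position, s.end, s.motif) for s in specs}
        if found == wanted:
            truth = pd.DataFrame(
                [
                    {
                        "seq_id": seq_id,
                        "start": s.position,
                        "end": s.end,
                        "motif": s.motif,
                        "n_repeats": s.n_repeats,
                    }
                    for s in specs
                ],
                columns=["seq_id", "start", "end", "motif", "n_repeats"],
            )
            return record, truth
    raise RuntimeError("planted tracts interact with the background; adjust the layout")


@dataclass(frozen=True)
class PopulationSimSpec:
    """Parameters of a simulated codominant genotype panel.

    ``divergence`` is an F_ST-like drift parameter in (0, 1): population
    allele frequencies follow the Balding-Nichols model, a Dirichlet draw
    with concentration base x (1 - F)/F around the shared base vector, so
    divergence -> 0 makes the populations identical while larger values
    drift them strongly apart. Outlier individuals draw from a private
    frequency vector concentrated on alleles that are rare in the shared
    pool, emulating a distinct, independently evolved accession.
    """

    n_individuals: int = 44
    n_loci: int = 18
    alleles_min: int = 5
    alleles_max: int = 15
    k_true: int = 2
    pop_sizes: tuple[int, ...] | None = (14, 29)
    divergence: float = 0.2
    outliers: int = 1
    missing_rate: float = 0.0
    allele_size_min: int = 100
    allele_size_max: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < self.k_true:
            raise ValueError("need at least one individual per population")
        if not 0 < self.divergence < 1:
            raise ValueError("divergence must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.alleles_max < 2 and self.k_true > 1:
            raise ValueError("cannot diverge populations with < 2 alleles per locus")
        if self.pop_sizes is not None:
            if len(self.pop_sizes) != self.k_true:
                raise ValueError("pop_sizes must have k_true entries")
            if sum(self.pop_sizes) + self.outliers != self.n_individuals:
                raise ValueError("pop_sizes plus outliers must sum to n_individuals")


def pear44_preset(seed: int = 0, divergence: float = 0.2, missing_rate: float = 0.0) -> PopulationSimSpec:
    """Default panel emulating a 44-cultivar diversity study: 18 loci with
    5-15 alleles each, two populations of 14 and 29 plus one outlier."""
    return PopulationSimSpec(seed=seed, divergence=divergence, missing_rate=missing_rate)


def simulate_genotypes(spec: PopulationSimSpec) -> tuple[GenotypeMatrix, pd.Series]:
    """Simulate a diploid codominant genotype matrix with known structure.

    Per locus, a shared base frequency vector is drawn over a random number
    of alleles in [alleles_min, alleles_max]; each population's frequencies
    are a Balding-Nichols (Dirichlet) perturbation of the base whose drift
    grows with ``spec.divergence``; outlier individuals draw from a private
    vector weighted toward alleles rare in the base. A locus is redrawn (up
    to a fixed number of attempts) until the panel actually shows at least
    ``alleles_min`` distinct alleles, matching how published panels report
    observed allele counts. Allele states are emitted as distinct plausible
    fragment sizes (bp). Returns the matrix and the truth labels
    ("pop1".."popK" / "outlier") indexed by individual id.
    """
    rng = np.random.default_rng(spec.seed)
    n_pop_members = spec.n_individuals - spec.outliers
    if spec.pop_sizes is not None:
        sizes = list(spec.pop_sizes)
    else:
        base_size = n_pop_members // spec.k_true
        sizes = [base_size] * spec.k_true
        for i in range(n_pop_members - base_size * spec.k_true):
            sizes[i] += 1
    labels = []
    for k, size in enumerate(sizes):
        labels += [f"pop{k + 1}"] * size
    labels += ["outlier"] * spec.outliers

    individuals = [f"ind{i + 1:02d}" for i in range(spec.n_individuals)]
    loci = [f"locus{j + 1:02d}" for j in range(spec.n_loci)]
    calls = np.full((spec.n_individuals, spec.n_loci, 2), -1, dtype=np.int64)

    f_st = spec.divergence
    for j in range(spec.n_loci):
        for _attempt in range(20):
            n_alleles = int(rng.integers(spec.alleles_min, spec.alleles_max + 1))
            sizes_bp = _allele_sizes(n_alleles, spec, rng)
            base = rng.dirichlet(np.full(n_alleles, 2.0))
            conc = np.clip(base * (1.0 - f_st) / f_st, 1e-3, None)
            pop_freqs = [rng.dirichlet(conc) for _ in range(spec.k_true)]
            private_weight = 1.0 / (base + 1e-2)
            outlier_freq = rng.dirichlet(0.3 * n_alleles * private_weight / private_weight.sum())
            column = np.zeros((spec.n_individuals, 2), dtype=np.int64)
            for i, label in enumerate(labels):
                freqs = outlier_freq if label == "outlier" else pop_freqs[int(label[3:]) - 1]
                pair = rng.choice(n_alleles, size=2, p=freqs)
                column[i] = sorted(sizes_bp[a] for a in pair)
            if len(np.unique(column)) >= spec.alleles_min:
                break
        calls[:, j] = column
    if spec.missing_rate > 0:
        mask = rng.random((spec.n_individuals, spec.n_loci)) < spec.missing_rate
        calls[mask] = -1
    matrix = GenotypeMatrix(individuals=individuals, loci=loci, calls=calls)
    return matrix, pd.Series(labels, index=individuals, name="population")


def _allele_sizes(n_alleles: int, spec: PopulationSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Distinct fragment sizes in bp, e.g. a ladder of dinucleotide steps."""
    lo, hi = spec.allele_size_min, spec.allele_size_max
    start = int(rng.integers(lo, max(lo + 1, hi - 2 * n_alleles)))
    return start + 2 * np.arange(n_alleles)
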