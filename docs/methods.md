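# Methods

This note records the models, conventions and numerical choices behind
each stage of the toolkit, and what the synthetic fixtures do and do not
establish about behaviour on real genomes.

## Perfect-repeat detection

An SSR locus is a maximal perfect tandem repeat of a primitive 1–6 bp
motif. "Maximal" means the tract cannot be extended by a further repeat
unit on either side; a trailing partial unit terminates the tract, and
only complete units are counted (repeat numbers are integers). Tracts are
anchored at the leftmost base of the maximal perfect region, so a phase
ambiguity such as `TATATATAT` is reported once, starting at its first
base. Motifs are reported at their minimal period — a poly-A run is a
mono-nucleotide SSR, never (AA)n — by discarding candidate tracts whose
motif is itself a power of a shorter unit (those reappear at the true
period). `N` bases never participate in a tract; IUPAC ambiguity codes
other than N are rejected outright. Overlapping maximal tracts of
different periods at tract borders are all reported and then subject to
compound flagging.

Default per-class minimum repeat counts are 12 (mono), 8 (di) and 5
(tri–hexa), the thresholds conventionally used in genome-wide SSR surveys
of fruit-tree assemblies; all thresholds are configurable but must be
at least 2. The scanner is vectorized (per-period shifted equality plus
run-length extraction) and is cross-checked in the tests against an
independent base-by-base oracle; coordinates are 1-based inclusive on the
forward strand for direct GFF3/TSV compatibility.

**Canonical motif classes.** Two motifs belong to one class when one is a
cyclic rotation of the other or of its reverse complement; the class is
named by its lexicographically smallest member (AG for {AG, GA, CT, TC}).
For primitive motifs this partitions the motif space into 2 / 4 / 10 / 33
/ 102 / 350 classes for periods 1–6, which the tests verify by
enumeration.

**Compound SSRs.** Two tracts on one sequence whose gap is at most
`compound_max_gap` (default 0, i.e. directly abutting or overlapping) are
compound, and the relation is closed transitively along chains. The gap
is a configuration knob because interrupt handling differs between
published mining tools; the default is deliberately conservative, and
compound loci are excluded from primer design.

## Genomic-context classification

Each locus receives exactly one label by priority: coding exon > 5′ UTR >
3′ UTR > intron > flanking categories > intergenic. A 1 bp overlap
suffices. "Upstream" and "downstream" are strand-aware 1 kb windows
beyond the gene span; a locus simultaneously downstream of one gene and
upstream of another is `between_genes_1kb`. The downstream window is
taken beyond the transcription termination site (a "downstream of the
transcription start" reading would duplicate the gene body). When several
genes compete at equal priority the gene whose feature start is nearest
wins, with a final lexicographic tie-break on gene id, so labels are
deterministic. Gene models come from GFF3 via gffutils, merging
exon/CDS/UTR intervals across transcripts; models whose sub-features
escape the gene span are rejected.

## Primer design

The design replaces an external designer with a deterministic exhaustive
search so results are exactly reproducible: published surveys state the
constraint box but not the internal penalty weights of the tool they ran.
The box is primer length 18–28 bp (optimum 20), product 100–300 bp
containing the whole tract with both primers outside it, Tm 55–65 °C
(optimum 60) and pair ΔTm ≤ 1 °C. Two sequence filters are added for
realism and can be disabled: no homopolymer run of five or more bases,
and no internal reverse-complement match of eight or more bases
(fold-back risk). Among feasible pairs the penalty

    |len_f − 20| + |len_r − 20| + |Tm_f − 60| + |Tm_r − 60| + |ΔTm|

is minimized, ties broken by (forward start, forward length, reverse end,
reverse length). Melting temperatures use the unified nearest-neighbor
parameters (Allawi & SantaLucia 1997) with duplex initiation and symmetry
terms, 50 mM monovalent salt via the entropic correction
0.368 (N−1) ln[Na⁺], and 50 nM total strand concentration; the tests
verify agreement with an independently coded implementation to
< 0.01 °C. The annealing-temperature rule Ta = round(min Tm) − 3 °C,
clipped to [50, 65], is a simple laboratory heuristic: published Ta
values are typically re-optimized per assay and cannot be derived from
the primer sequences alone.

Cross-pair deduplication takes the strictest reading of "each primer pair
must amplify a single locus": any primer sequence occurring (in either
orientation role) in more than one pair disqualifies every pair involved.
The operation is idempotent, and the bulk designer reports counts
(skipped-compound, no-valid-pair, dedup-removed, retained) that always
partition the input.

## Map anchoring and naming

A scaffold's genetic position is the arithmetic mean cM of its mapped
SNPs. All SNPs on one linkage group → `single`; 2–3 groups → `ambiguous`
(candidate set kept, no position); more than 3 groups or no SNPs →
`unknown`. The 3-group cap mirrors how such surveys report "located in
one of 2–3 linkage groups". Markers are named
`Pb<motif length>L<LG|U>N<serial>`; serials run consecutively within each
motif-length series ordered by (linkage group, genetic position, physical
position) with non-single-anchored loci last, and zero-padding defaults
to the natural width of the series (published tables are inconsistent
here, so the scheme is fixed and round-trip parseable).

## Diversity statistics

Allele frequencies at a locus come from the two gene copies of every
scored individual (per-locus deletion of missing cells). He is Nei's gene
diversity 1 − Σpᵢ²; the unbiased small-sample factor 2n/(2n−1) is an
option, off by default, because the classic software this mirrors reports
the plain form. PIC is the codominant Botstein form
1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ², which satisfies PIC ≤ He ≤ 1 − 1/Na with
equality at equifrequent alleles. Ho is the heterozygous fraction of
scored individuals and is bounded in [0, 1] by construction.

Similarity between individuals treats each observed allele as a binary
band; the Dice coefficient 2a/(2a+b+c) is the default (simple matching
available), with pairwise deletion of loci missing in either individual;
a pair with no jointly scored locus is an error rather than a silent 0.
UPGMA agglomerates on distance 1 − similarity with size-weighted
averaging; tied minimum distances merge the pair with the smallest
cluster indices (creation order), so trees are deterministic. Output is a
rooted binary ultrametric scikit-bio tree serializable as Newick; the
tests check the cophenetic round-trip on random ultrametric matrices and
agreement with scipy's average-linkage cophenetic distances.

## Population structure and Evanno ΔK

The clustering model is a finite mixture without admixture: conditional
on its (latent) source population, an individual's two allele copies per
locus are independent draws from that population's frequency vector
(Hardy–Weinberg within populations, linkage equilibrium across loci).
EM alternates soft assignments (responsibilities) with reweighted allele
frequency and mixing-proportion updates; the log-likelihood is monotone
non-decreasing and convergence is declared when it changes by less than
`tol` (default 1e-6, max 500 iterations). Because EM is local, `fit()`
restarts from 10 random initializations (sub-seeded deterministically)
and keeps the best; a full Bayesian treatment with admixture and
correlated frequencies is out of scope — the model-selection mechanics,
not any particular posterior, are the reproducible surface here.

Replicate runs across K feed the Evanno statistics: L′(K) = L(K) − L(K−1),
|L″(K)| = |L(K+1) − 2L(K) + L(K−1)| and ΔK = |L″(K)|/sd(K), computed
exactly as defined; ΔK is undefined (reported as NaN, never an exception)
at the ends of the K range and wherever the replicate standard deviation
is zero. With well-converged multi-start EM, however, sd = 0 arises
precisely when every replicate reaches the identical optimum — the
strongest possible signal — so model selection treats sd = 0 with
|L″| > 0 as the ΔK → ∞ limit and prefers such K over any finite peak.
A result is flagged `low_signal` when no ΔK reaches 10; the threshold is
a heuristic calibrated against simulations of a panmictic panel (null ΔK
values cluster below ~5 but have a heavy tail, so the flag is advisory,
not a test). Replicate seeds derive from the master seed by counter
hashing (`SeedSequence(entropy=seed, spawn_key=(K, replicate))`), making
whole analyses bit-reproducible.

## Synthetic fixtures

**Genomes.** Backgrounds are uniform-ACGT sequences rejection-sampled to
contain no SSR at the scan thresholds; planted tracts are spliced in
verbatim, and generation re-rolls until a scan of the final sequence
equals the planted truth table exactly, giving a guaranteed round-trip
fixture (splice boundaries could otherwise extend a tract by chance).

**Genotype panels.** The default preset emulates a 44-accession diversity
panel typed at 18 loci with 5–15 observed alleles per locus: two
populations of 14 and 29 individuals plus one outlier accession.
Population frequencies follow the Balding–Nichols model — a Dirichlet
draw with concentration base × (1 − F)/F around a shared base vector —
with `divergence` the F_ST-like drift parameter (default 0.2, a strong
but realistic divergence for two long-separated cultivated gene pools;
F → 0 recovers a panmictic panel). The outlier draws from a private
frequency vector concentrated on alleles rare in the shared pool,
emulating a distinct, independently evolved germplasm; with the plain
shared-pool draw the "outlier" is often no farther from either population
than they are from each other, which is not the scenario being emulated.
Loci are redrawn (bounded attempts) until the panel shows at least the
minimum number of observed alleles, because published allele counts are
observed, not parametric. Alleles are emitted as distinct fragment sizes
on a dinucleotide ladder within 100–300 bp. Under these defaults the
simulated panels show mean Ho ≈ 0.65–0.72 and mean PIC ≈ 0.70–0.74,
in the range reported for highly polymorphic pear SSR panels.

What the fixtures do **not** capture: mutation-model realism (no stepwise
mutation process), linkage between loci, null alleles and genotyping
error, imperfect or interrupted repeats, and base-composition
heterogeneity of real assemblies. Passing tests therefore demonstrate
algorithmic correctness and recovery under the stated generative model,
not performance guarantees on any particular genome.

## Problem sizes and tolerances

The test suite and the acceptance script run on one CPU in well under a
minute each, using: 100 (tests) / 25 (script) seeded 50 kb sequences for
scanner–oracle equivalence; 50 seeded panel replicates for the
UPGMA-outlier and K = 2 recovery rates; k_max = 4 with 4 EM replicates
per K for structure runs (the CLI default is k_max 6 × 10 replicates);
and 200 random ≤ 6-individual panels for brute-force agreement of the
diversity statistics. Numerical comparisons use absolute tolerances of
1e-9 (exact algebraic identities), 0.01 °C (Tm cross-implementation) and
1e-6 (EM log-likelihood convergence).
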