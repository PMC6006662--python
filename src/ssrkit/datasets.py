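"""Published summary tables from the genome-wide SSR survey of the Chinese
white pear ('Dangshansuli') assembly.

The full pear run requires downloading the scaffold assembly, but the
survey's printed count tables are small and serve as worked-example inputs
for the summary and bookkeeping routines (class percentages, primer
retention, linkage-group placement totals).
"""

#: SSRs identified per motif-length class (1 = mono .. 6 = hexa).
PEAR_SSR_CLASS_COUNTS: dict[int, int] = {
    1: 98_939,
    2: 41_546,
    3: 11_798,
    4: 3_271,
    5: 593,
    6: 249,
}

#: SSR loci retained after primer design and cross-pair deduplication.
PEAR_RETAINED_CLASS_COUNTS: dict[int, int] = {
    1: 63_317,
    2: 27_561,
    3: 8_261,
    4: 1_962,
    5: 409,
    6: 184,
}

#: Primer pairs successfully designed from the identified SSRs.
PEAR_PRIMER_PAIRS_DESIGNED = 153_008

#: Linkage-group placement of the retained loci.
PEAR_ANCHOR_COUNTS: dict[str, int] = {
    "single": 61_160,  # placed on exactly one linkage group
    "ambiguous": 19_255,  # narrowed to 2-3 candidate linkage groups
    "unknown": 21_279,  # no placement
}

#: Genomic-context counts of the identified SSRs (gene-model overlap).
PEAR_CONTEXT_COUNTS: dict[str, int] = {
    "intergenic": 62_984,
    "intron": 20_085,
    "flank_1kb": 23_953,  # within 1 kb of a gene (up-, down- or between)
    "utr": 5_052,
    "exon": 2_135,
}

#: Diversity panel: 18 markers typed on 44 cultivars.
PEAR_PANEL = {
    "n_individuals": 44,
    "n_loci": 18,
    "alleles_min": 5,
    "alleles_max": 15,
    "mean_alleles": 10.56,
    "mean_genotypes": 19.22,
    "mean_ho": 0.6763,
    "mean_pic": 0.7808,
}
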