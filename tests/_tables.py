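"""Published genotype counts and state-level allele frequencies used as
fixed inputs by several tests (field-study report tables for soybean
looper collections)."""

# (n_del_hom, n_plus_hom, n_het) per collection; pheromone-trap males
MALE_COUNTS = {
    "AL2017": (1, 56, 25),
    "FL2017": (11, 125, 26),
    "FL2019": (4, 24, 0),
    "KS2017": (13, 29, 11),
    "MS2019a": (3, 17, 4),
    "TX2017": (11, 90, 44),
}
MALE_FIS = {
    "AL2017": -0.11,
    "FL2017": 0.36,
    "FL2019": 1.00,
    "KS2017": 0.54,
    "MS2019a": 0.49,
    "TX2017": 0.14,
}
# The published Total row prints 109 heterozygotes, but the printed
# per-collection column sums to 110; the pooled F_is rounds to 0.30
# under either count.
MALE_TOTAL_PUBLISHED = (43, 341, 109)
MALE_COLUMN_SUM = (43, 341, 110)
MALE_POOLED_FIS = 0.30
MALE_MEAN_FIS = 0.41

# larval/colony collections of unknown sex (hemizygotes scored as
# homozygotes under the diploid convention)
LARVAL_COUNTS = {
    "AL2016": (5, 31, 7),
    "GA2016": (0, 24, 0),
    "LA2016": (7, 28, 5),
    "LA2019": (5, 34, 13),
    "MS2016": (6, 28, 9),
    "NC2016": (10, 16, 11),
    "PR2019": (3, 21, 3),
    "SC2016": (9, 43, 19),
    "VA2019": (9, 10, 2),
}
LARVAL_FIS = {
    "AL2016": 0.49,
    "GA2016": None,  # monomorphic: no i65del alleles detected
    "LA2016": 0.65,
    "LA2019": 0.27,
    "MS2016": 0.43,
    "NC2016": 0.39,
    "PR2019": 0.60,
    "SC2016": 0.31,
    "VA2019": 0.81,
}
LARVAL_TOTAL = (54, 235, 69)
LARVAL_POOLED_FIS = 0.48
LARVAL_MEAN_FIS = 0.49

# state-level i65del percent frequency within the C1035 and T1035
# mito-haplotype classes (combined colony + field data, nine units)
STATE_DEL_FREQ_PAIRS = [
    ("AL", 16, 26),
    ("FL", 14, 46),
    ("KS", 27, 42),
    ("LA", 13, 54),
    ("MS", 24, 29),
    ("NC", 21, 44),
    ("SC", 14, 36),
    ("TX", 20, 42),
    ("GA-VA-TN-PR", 13, 48),
]
STATE_T = 5.808
STATE_DF = 8
STATE_MEAN_C = (18, 5)
STATE_MEAN_T = (41, 9)
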