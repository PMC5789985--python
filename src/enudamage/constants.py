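"""Closed vocabularies and published reference numbers used as shipped defaults.

The mutation-class vocabulary follows PolyPhen-2 (PP2, HumDiv-trained)
categories for missense changes, plus two "probably null" classes for
non-missense coding/splice mutations: class I covers nonsense, makesense
(stop-loss) and start-loss SNVs; class II covers indels and splice defects.
"""

from __future__ import annotations

#: Closed set of mutation class tokens used throughout the package.
MUTATION_CLASSES: tuple[str, ...] = (
    "probably_benign",
    "possibly_damaging",
    "probably_damaging",
    "null_class_I",
    "null_class_II",
)

#: Classes that carry a PP2 score.
MISSENSE_CLASSES: tuple[str, ...] = MUTATION_CLASSES[:3]

#: Putative-null classes (no PP2 score).
NULL_CLASSES: tuple[str, ...] = MUTATION_CLASSES[3:]

#: Mapping from snake_case tokens to the labels conventionally printed in
#: reports of PP2-classified ENU screens.
PRINTED_LABELS: dict[str, str] = {
    "probably_benign": "Probably benign (score ≤0.45)",
    "possibly_damaging": "Possibly damaging (score 0.45–0.95)",
    "probably_damaging": "Probably damaging (score 0.95–1.0)",
    "null_class_I": "Probably null class I",
    "null_class_II": "Probably null class II",
}

#: PP2 score interval per missense class, as (low, high]; benign is [0, 0.45].
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "probably_benign": (0.0, 0.45),
    "possibly_damaging": (0.45, 0.95),
    "probably_damaging": (0.95, 1.0),
}

#: Genotype call vocabulary: homozygous reference, heterozygous, homozygous variant.
GENOTYPES: tuple[str, ...] = ("REF", "HET", "HOM")

GENERATIONS: tuple[str, ...] = ("G1", "G2", "G3")

#: Mendelian expectation for HOM offspring of a HET x HET cross.
MENDELIAN_HOM_RATE: float = 0.25

#: Default center of the partial-lethality subgroup of HOM proportions.
DEFAULT_THETA: float = 0.125

#: Default ratio of partially to totally essential genes (250/635 from
#: IMPC viability calls on MGI essential genes, rounded to 0.39).
DEFAULT_PARTIAL_RATIO: float = 0.39

#: IMPC classification of MGI-essential genes used to derive the 39% ratio.
IMPC_ESSENTIAL_LETHALITY_COUNTS: dict[str, int] = {"partially": 250, "totally": 635}

#: IMPC viability calls after discarding genes with conflicting records.
IMPC_VIABILITY_COUNTS: dict[str, int] = {"viable": 1784, "sub_viable": 258, "lethal": 649}
IMPC_VIABILITY_TOTAL: int = 2691

#: Per-class mutation counts across the progressive filtering cascade of the
#: reference ENU cohort (all genotyped -> isolated -> >=3 G3 -> essential genes).
COHORT_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "all": {
        "probably_benign": 26004,
        "possibly_damaging": 14412,
        "probably_damaging": 32669,
        "null_class_I": 5170,
        "null_class_II": 2618,
    },
    "isolated": {
        "probably_benign": 2406,
        "possibly_damaging": 1314,
        "probably_damaging": 3077,
        "null_class_I": 462,
        "null_class_II": 273,
    },
    "min_g3": {
        "probably_benign": 2311,
        "possibly_damaging": 1270,
        "probably_damaging": 2982,
        "null_class_I": 441,
        "null_class_II": 268,
    },
    "essential": {
        "probably_benign": 477,
        "possibly_damaging": 281,
        "probably_damaging": 690,
        "null_class_I": 78,
        "null_class_II": 60,
    },
}

#: Published per-class probabilities of phenotypically detectable protein
#: damage, estimated on 1,586 mutations in essential genes.
PUBLISHED_DAMAGE_PROBABILITIES: dict[str, float] = {
    "probably_benign": 0.045,
    "possibly_damaging": 0.099,
    "probably_damaging": 0.167,
    "null_class_I": 0.594,
    "null_class_II": 0.626,
}

#: 95% bootstrap confidence intervals accompanying the published estimates.
PUBLISHED_DAMAGE_CI: dict[str, tuple[float, float]] = {
    "probably_benign": (0.0, 0.108),
    "possibly_damaging": (0.012, 0.182),
    "probably_damaging": (0.111, 0.22),
    "null_class_I": (0.449, 0.736),
    "null_class_II": (0.464, 0.786),
}

#: Approximate mm10 autosome lengths in bp (used for synthetic positions).
MOUSE_AUTOSOME_LENGTHS_BP: dict[str, int] = {
    "1": 195_000_000, "2": 182_000_000, "3": 160_000_000, "4": 157_000_000,
    "5": 152_000_000, "6": 150_000_000, "7": 145_000_000, "8": 129_000_000,
    "9": 124_000_000, "10": 131_000_000, "11": 122_000_000, "12": 120_000_000,
    "13": 120_000_000, "14": 125_000_000, "15": 104_000_000, "16": 98_000_000,
    "17": 95_000_000, "18": 91_000_000, "19": 61_000_000,
}

#: Default isolation distance: 100 Mb (1 Mb = 1e6 bp exactly).
DEFAULT_ISOLATION_BP: int = 100_000_000
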