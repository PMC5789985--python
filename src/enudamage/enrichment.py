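"""Phenotype-enrichment analysis of screen/mutation linkage results.

For a set of mutations, the fraction of screen/mutation combinations whose
Bonferroni-adjusted linkage P value falls below a threshold estimates the
probability that a mutation induces a detectable (viable) phenotype.  The
comparison of interest is mutations in essential vs. non-essential genes;
exact (Clopper-Pearson) binomial intervals quantify the uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from .constants import NULL_CLASSES
from .types import EssentialityAnnotation, MutationRecord, ScreenLinkageRecord


@dataclass(frozen=True)
class EnrichmentResult:
    """Significant-combination proportion for one gene set."""

    gene_set: str
    n_combinations: int
    n_significant: int
    proportion: float
    ci_low: float
    ci_high: float

    @property
    def proportion_pct(self) -> float:
        return self.proportion * 100.0


def _collapse(
    records: Sequence[ScreenLinkageRecord], collapse_models: str
) -> list[ScreenLinkageRecord]:
    if collapse_models == "none":
        return list(records)
    if collapse_models != "min":
        raise ValueError("collapse_models must be 'min' or 'none'")
    best: dict[tuple[str, str], ScreenLinkageRecord] = {}
    for rec in records:
        key = (rec.screen_id, rec.mutation_id)
        cur = best.get(key)
        if cur is None or rec.p_value < cur.p_value:
            best[key] = rec
    return list(best.values())


def significant_fraction(
    records: Sequence[ScreenLinkageRecord],
    p_threshold: float = 1e-5,
    collapse_models: str = "min",
    level: float = 0.95,
    gene_set: str = "all",
) -> EnrichmentResult:
    """Fraction of screen/mutation combinations with linkage P < threshold.

    The threshold comparison is strict.  With ``collapse_models='min'`` the
    recessive/additive/dominant records for a screen/mutation pair count as
    one combination carrying the smallest adjusted P; with ``'none'`` every
    model record counts separately.  The interval is Clopper-Pearson exact.
    """
    combos = _collapse(records, collapse_models)
    n = len(combos)
    if n == 0:
        raise ValueError("no screen/mutation combinations to analyze")
    k = sum(1 for rec in combos if rec.p_value < p_threshold)
    ci = binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return EnrichmentResult(
        gene_set=gene_set,
        n_combinations=n,
        n_significant=k,
        proportion=k / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def class_composition(mutations: Iterable[MutationRecord]) -> dict[str, float]:
    """Fractions of probably_damaging and probably_null mutations in a set."""
    muts = list(mutations)
    if not muts:
        return {"probably_damaging": 0.0, "probably_null": 0.0}
    n = len(muts)
    n_dmg = sum(1 for m in muts if m.mutation_class == "probably_damaging")
    n_null = sum(1 for m in muts if m.mutation_class in NULL_CLASSES)
    return {"probably_damaging": n_dmg / n, "probably_null": n_null / n}


def compare_gene_sets(
    records: Sequence[ScreenLinkageRecord],
    mutations: Sequence[MutationRecord],
    annotations: Iterable[EssentialityAnnotation],
    p_threshold: float = 1e-5,
    collapse_models: str = "min",
    level: float = 0.95,
) -> dict[str, dict]:
    """Enrichment comparison between essential and non-essential gene sets.

    Returns, per gene set, the :class:`EnrichmentResult` and the set's
    mutation-class composition (fractions of probably-damaging and
    probably-null mutations), the latter serving as a confounding check:
    a higher significant fraction in essential genes is only meaningful if
    the class mixes are comparable.
    """
    essential_genes = {a.gene_id for a in annotations if a.essential}
    gene_of = {m.mutation_id: m.gene_id for m in mutations}
    mut_of = {m.mutation_id: m for m in mutations}

    split: dict[str, list[ScreenLinkageRecord]] = {"essential": [], "non_essential": []}
    for rec in records:
        gene = gene_of.get(rec.mutation_id)
        if gene is None:
            continue
        key = "essential" if gene in essential_genes else "non_essential"
        split[key].append(rec)

    out: dict[str, dict] = {}
    for key, recs in split.items():
        mut_ids = {r.mutation_id for r in recs}
        muts = [mut_of[mid] for mid in mut_ids]
        out[key] = {
            "enrichment": significant_fraction(
                recs,
                p_threshold=p_threshold,
                collapse_models=collapse_models,
                level=level,
                gene_set=key,
            )
            if recs
            else None,
            "composition": class_composition(muts),
            "n_mutations": len(muts),
        }
    return out
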