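"""Mutation filtering cascade and per-mutation HOM-proportion computation.

The cascade restricts analysis to mutations whose phenotypic effects are
attributable to a single gene: each retained mutation is >= 100 Mb from any
other mutation on the same chromosome of the same pedigree, comes from a
pedigree with at least three genotyped G3 mice, and (for damage estimation)
lies in a known essential gene.  For each mutation the proportion ``p_hom``
of HOM G3 mice among offspring of HET dams is then computed; 0.25 is the
Mendelian expectation for a HET x HET backcross with no lethality.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .constants import DEFAULT_ISOLATION_BP
from .types import EssentialityAnnotation, Mouse, MutationRecord

logger = logging.getLogger("enudamage")


class PedigreeLookupError(KeyError):
    """A mutation references a pedigree with no genotyped mice."""


@dataclass(frozen=True)
class FilteredMutation:
    """A mutation that passed filtering, with its HOM-proportion statistics.

    ``p_hom`` is None (and the record flagged undefined) when no G3 mouse
    descends from a dam heterozygous for the mutation — such records are
    excluded from downstream estimation.
    """

    record: MutationRecord
    n_g3: int
    n_hom: int

    @property
    def p_hom(self) -> float | None:
        if self.n_g3 == 0:
            return None
        return self.n_hom / self.n_g3

    @property
    def defined(self) -> bool:
        return self.n_g3 > 0

    @property
    def mutation_class(self) -> str:
        return self.record.mutation_class


def filter_isolated(
    mutations: Sequence[MutationRecord],
    threshold_bp: int = DEFAULT_ISOLATION_BP,
) -> list[MutationRecord]:
    """Keep mutations with no same-pedigree, same-chromosome neighbor closer
    than ``threshold_bp``.

    The boundary is strict: two mutations exactly ``threshold_bp`` apart do
    not exclude each other.  Mutations on differently named chromosomes never
    interact, and the rule applies within pedigrees only.
    """
    by_group: dict[tuple[str, str], list[MutationRecord]] = defaultdict(list)
    for rec in mutations:
        by_group[(rec.pedigree_id, rec.chromosome)].append(rec)

    keep: set[str] = set()
    for group in by_group.values():
        ordered = sorted(group, key=lambda r: r.position)
        for i, rec in enumerate(ordered):
            near_prev = i > 0 and rec.position - ordered[i - 1].position < threshold_bp
            near_next = (
                i + 1 < len(ordered)
                and ordered[i + 1].position - rec.position < threshold_bp
            )
            if not (near_prev or near_next):
                keep.add(rec.mutation_id)
    return [rec for rec in mutations if rec.mutation_id in keep]


def count_g3_per_pedigree(mice: Iterable[Mouse]) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    pedigrees_seen: set[str] = set()
    for mouse in mice:
        pedigrees_seen.add(mouse.pedigree_id)
        if mouse.generation == "G3":
            counts[mouse.pedigree_id] += 1
    for ped in pedigrees_seen:
        counts.setdefault(ped, 0)
    return dict(counts)


def filter_min_g3(
    mutations: Sequence[MutationRecord],
    mice: Iterable[Mouse],
    min_g3: int = 3,
) -> list[MutationRecord]:
    """Keep mutations from pedigrees with at least ``min_g3`` genotyped G3 mice
    of any genotype.  A mutation whose pedigree has no recorded mice at all is
    an error (the pedigree cannot be resolved)."""
    counts = count_g3_per_pedigree(mice)
    out = []
    for rec in mutations:
        if rec.pedigree_id not in counts:
            raise PedigreeLookupError(
                f"mutation {rec.mutation_id} references unknown pedigree "
                f"{rec.pedigree_id!r}"
            )
        if counts[rec.pedigree_id] >= min_g3:
            out.append(rec)
    return out


def filter_essential(
    mutations: Sequence[MutationRecord],
    annotations: Iterable[EssentialityAnnotation],
) -> list[MutationRecord]:
    """Keep mutations in genes annotated essential.

    Genes absent from the annotation set are treated as non-essential (the
    annotation databases are not exhaustive); each such gene is logged once.
    """
    essential = {a.gene_id for a in annotations if a.essential}
    annotated = {a.gene_id for a in annotations}
    unannotated: set[str] = set()
    out = []
    for rec in mutations:
        if rec.gene_id in essential:
            out.append(rec)
        elif rec.gene_id not in annotated:
            unannotated.add(rec.gene_id)
    if unannotated:
        logger.warning(
            "%d gene(s) had no essentiality annotation; treated as non-essential",
            len(unannotated),
        )
    return out


def compute_p_hom(
    mutation: MutationRecord, mice: Iterable[Mouse]
) -> FilteredMutation:
    """Compute the proportion of HOM G3 mice for one mutation.

    The denominator is every genotyped G3 mouse of the mutation's pedigree
    whose dam is HET for the mutation (a HET G2 x HET G1 backcross is the
    only cross that can yield HOM pups); the numerator counts HOM calls among
    them.  With no such mice the proportion is undefined and the record is
    flagged for downstream exclusion.
    """
    by_id = {m.mouse_id: m for m in mice}
    n_g3 = 0
    n_hom = 0
    for mouse in by_id.values():
        if mouse.generation != "G3" or mouse.pedigree_id != mutation.pedigree_id:
            continue
        call = mouse.genotypes.get(mutation.mutation_id)
        if call is None:
            continue
        dam = by_id.get(mouse.dam_id) if mouse.dam_id else None
        if dam is None or dam.genotypes.get(mutation.mutation_id) != "HET":
            continue
        n_g3 += 1
        if call == "HOM":
            n_hom += 1
    return FilteredMutation(record=mutation, n_g3=n_g3, n_hom=n_hom)


def compute_p_hom_table(
    mutations: Sequence[MutationRecord], mice: Sequence[Mouse]
) -> list[FilteredMutation]:
    """Vectorized-by-lookup version of :func:`compute_p_hom` for many mutations."""
    by_id = {m.mouse_id: m for m in mice}
    g3_by_pedigree: dict[str, list[Mouse]] = defaultdict(list)
    for m in by_id.values():
        if m.generation == "G3":
            g3_by_pedigree[m.pedigree_id].append(m)

    out = []
    for rec in mutations:
        n_g3 = 0
        n_hom = 0
        for mouse in g3_by_pedigree.get(rec.pedigree_id, ()):
            call = mouse.genotypes.get(rec.mutation_id)
            if call is None:
                continue
            dam = by_id.get(mouse.dam_id) if mouse.dam_id else None
            if dam is None or dam.genotypes.get(rec.mutation_id) != "HET":
                continue
            n_g3 += 1
            if call == "HOM":
                n_hom += 1
        out.append(FilteredMutation(record=rec, n_g3=n_g3, n_hom=n_hom))
    return out


def filter_for_phenotype(
    mutations: Sequence[FilteredMutation],
    mice: Iterable[Mouse],
    min_g3: int = 4,
    min_p_hom: float = 0.25,
) -> list[FilteredMutation]:
    """Keep mutations suitable for phenotype-linkage comparison: pedigree has
    at least ``min_g3`` G3 mice of any genotype and ``p_hom >= min_p_hom``
    (both boundaries inclusive).  Input is assumed already isolation-filtered.
    """
    counts = count_g3_per_pedigree(mice)
    out = []
    for fm in mutations:
        if counts.get(fm.record.pedigree_id, 0) < min_g3:
            continue
        if fm.p_hom is None or fm.p_hom < min_p_hom:
            continue
        out.append(fm)
    return out


def apply_cascade(
    mutations: Sequence[MutationRecord],
    mice: Sequence[Mouse],
    annotations: Iterable[EssentialityAnnotation] | None = None,
    threshold_bp: int = DEFAULT_ISOLATION_BP,
    min_g3: int = 3,
) -> tuple[list[FilteredMutation], dict[str, int]]:
    """Run the full cascade (isolation -> pedigree size -> essential genes)
    and compute p_hom for the survivors.

    Returns the filtered mutations and a stage-count dictionary mirroring the
    columns of a progressive-filtering table.
    """
    stages = {"all": len(mutations)}
    step = filter_isolated(mutations, threshold_bp=threshold_bp)
    stages["isolated"] = len(step)
    step = filter_min_g3(step, mice, min_g3=min_g3)
    stages["min_g3"] = len(step)
    if annotations is not None:
        step = filter_essential(step, annotations)
        stages["essential"] = len(step)
    filtered = compute_p_hom_table(step, mice)
    return filtered, stages
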