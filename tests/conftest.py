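"""Shared fixtures: a small hand-built pedigree and a reusable synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from enudamage import GeneratorConfig, Mouse, MutationRecord, generate_dataset


def make_mutation(
    mutation_id="mutA",
    pedigree_id="P1",
    gene_id="geneA",
    chromosome="1",
    position=10_000_000,
    mutation_class="probably_damaging",
    score=0.97,
):
    return MutationRecord(
        mutation_id=mutation_id,
        pedigree_id=pedigree_id,
        gene_id=gene_id,
        chromosome=chromosome,
        position=position,
        mutation_class=mutation_class,
        score=score,
    )


@pytest.fixture
def toy_mutation():
    return make_mutation()


@pytest.fixture
def toy_pedigree(toy_mutation):
    """One pedigree, one mutation: G1 sire HET, dam D1 HET (8 G3: 2 HOM,
    3 HET, 3 REF), dam D2 REF (4 G3: 2 HET, 2 REF).

    Hand enumeration: the HET-dam denominator is 8, with 2 HOM, so
    p_hom = 0.25; D2's pups are excluded (a REF dam cannot produce HOM).
    """
    mut = toy_mutation.mutation_id
    mice = [
        Mouse("S1", "P1", "G1", genotypes={mut: "HET"}),
        Mouse("D1", "P1", "G2", genotypes={mut: "HET"}),
        Mouse("D2", "P1", "G2", genotypes={mut: "REF"}),
    ]
    d1_calls = ["HOM", "HOM", "HET", "HET", "HET", "REF", "REF", "REF"]
    for i, call in enumerate(d1_calls):
        mice.append(
            Mouse(f"K1_{i}", "P1", "G3", dam_id="D1", litter_id="L1",
                  genotypes={mut: call})
        )
    for i, call in enumerate(["HET", "HET", "REF", "REF"]):
        mice.append(
            Mouse(f"K2_{i}", "P1", "G3", dam_id="D2", litter_id="L2",
                  genotypes={mut: call})
        )
    return mice


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-pedigree synthetic cohort at the default study conditions."""
    return generate_dataset(GeneratorConfig(n_pedigrees=40, seed=12345))


@pytest.fixture(scope="session")
def small_cohort_records(small_cohort):
    return small_cohort.to_records()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
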