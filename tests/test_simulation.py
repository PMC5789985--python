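"""Virtual breeding, culling, pedigree-size regression and the fraction scan."""

import numpy as np
import pandas as pd
import pytest

from enudamage import (
    DamageProbabilityMap,
    EssentialFractionScan,
    GeneratorConfig,
    SimScenario,
    assign_essentiality_and_damage,
    breed_virtual_g3,
    cull,
    fit_pedigree_size_model,
    generate_dataset,
    observed_genes_with_hom,
    scan_essential_fraction,
    simulate_replicate,
)
from enudamage.simulation import CollinearityError, neutral_pedigree_sizes
from tests.conftest import make_mutation
from enudamage import Mouse


class TestPedigreeSizeModel:
    def test_intercept_only_predicts_mean(self):
        table = pd.DataFrame({"g3_count": [10, 20, 30]})
        model = fit_pedigree_size_model(table)
        assert (model.predict(table) == 20).all()

    def test_known_coefficients_recovered(self, rng):
        n = 400
        litters = rng.integers(1, 6, size=n)
        counts = rng.poisson(5, size=n)
        noise = rng.normal(0, 1, size=n)
        table = pd.DataFrame(
            {
                "g3_count": 2 + 7 * litters - 0.5 * counts + noise,
                "n_litters": litters,
                "n_probably_damaging": counts,
            }
        )
        model = fit_pedigree_size_model(table)
        assert model.params["n_litters"] == pytest.approx(7, abs=0.1)
        assert model.params["n_probably_damaging"] == pytest.approx(-0.5, abs=0.1)

    def test_neutral_prediction_zeroes_mutation_counts(self, rng):
        litters = rng.integers(1, 6, size=200)
        counts = rng.poisson(5, size=200)
        table = pd.DataFrame(
            {
                "g3_count": 2 + 7 * litters - 0.5 * counts,
                "n_litters": litters,
                "n_probably_damaging": counts,
            }
        )
        model = fit_pedigree_size_model(table)
        neutral = model.predict_neutral(table)
        fitted = model.predict(table)
        # negative mutation coefficients: zeroing counts raises the prediction
        assert (neutral >= fitted).all()
        assert neutral.mean() > fitted.mean()

    def test_collinear_design_rejected(self):
        table = pd.DataFrame(
            {
                "g3_count": [10.0, 12, 14, 16],
                "n_litters": [1.0, 2, 3, 4],
                "n_probably_benign": [2.0, 4, 6, 8],  # 2 x n_litters
            }
        )
        with pytest.raises(CollinearityError, match="n_"):
            fit_pedigree_size_model(table)


class TestBreeding:
    def test_het_by_het_quarter_hom(self):
        pups = breed_virtual_g3(["HET"], ["HET"], 5000, seed=1)
        frac = (pups == 2).mean()
        se = np.sqrt(0.25 * 0.75 / 5000)
        assert abs(frac - 0.25) < 3 * se

    def test_ref_dam_never_hom(self):
        pups = breed_virtual_g3(["REF"], ["HET"], 2000, seed=2)
        assert (pups != 2).all()

    def test_hom_dam_half_hom(self):
        pups = breed_virtual_g3(["HOM"], ["HET"], 5000, seed=3)
        frac = (pups == 2).mean()
        se = np.sqrt(0.5 * 0.5 / 5000)
        assert abs(frac - 0.5) < 3 * se

    def test_unknown_parental_genotype_errors(self):
        with pytest.raises(ValueError, match="HOMO"):
            breed_virtual_g3(["HOMO"], ["HET"], 1)

    def test_loci_independent(self):
        pups = breed_virtual_g3(["HET"] * 2, ["HET"] * 2, 20000, seed=4)
        hom = pups == 2
        both = (hom[:, 0] & hom[:, 1]).mean()
        assert both == pytest.approx(0.0625, abs=0.01)


class TestCull:
    def test_total_essential_hom_removed(self):
        pups = np.array([[2], [1], [0]])
        alive = cull(pups, np.array([True]), np.array([2]), seed=0)
        assert alive.tolist() == [False, True, True]

    def test_non_damaging_hom_survives(self):
        pups = np.array([[2]])
        alive = cull(pups, np.array([False]), np.array([2]), seed=0)
        assert alive.tolist() == [True]

    def test_partial_cull_rate_half(self):
        pups = np.full((10000, 1), 2)
        alive = cull(pups, np.array([True]), np.array([1]),
                     partial_cull_rate=0.5, seed=5)
        se = np.sqrt(0.25 / 10000)
        assert abs(alive.mean() - 0.5) < 3 * se

    def test_total_rule_dominates(self):
        # HOM in one total and one partial lethal locus: always dead
        pups = np.full((200, 2), 2)
        alive = cull(pups, np.array([True, True]), np.array([2, 1]),
                     partial_cull_rate=0.0, seed=6)
        assert not alive.any()


class TestAssignment:
    def test_zero_fraction_no_essential(self):
        scenario = SimScenario(essential_fraction_grid=[0.0, 0.5])
        labels, _ = assign_essentiality_and_damage(
            500, np.arange(500), np.zeros(500, dtype=int), 0.0, scenario, seed=1
        )
        assert (labels == 0).all()

    def test_binomial_fraction(self):
        scenario = SimScenario(essential_fraction_grid=[0.0, 0.5])
        labels, _ = assign_essentiality_and_damage(
            10000, np.arange(10000), np.zeros(10000, dtype=int), 0.34, scenario,
            seed=2,
        )
        n_ess = (labels > 0).sum()
        se = np.sqrt(10000 * 0.34 * 0.66)
        assert abs(n_ess - 3400) < 3 * se

    def test_partial_total_ratio(self):
        scenario = SimScenario(essential_fraction_grid=[0.0, 0.5])
        labels, _ = assign_essentiality_and_damage(
            50000, np.arange(10), np.zeros(10, dtype=int), 1.0, scenario, seed=3
        )
        ratio = (labels == 1).sum() / (labels == 2).sum()
        assert ratio == pytest.approx(0.39, abs=0.02)


@pytest.fixture(scope="module")
def scan_dataset():
    return generate_dataset(GeneratorConfig(n_pedigrees=30, seed=777))


class TestScan:
    def test_single_grid_point_rejected(self, scan_dataset):
        scenario = SimScenario(essential_fraction_grid=[0.3], seed=0)
        with pytest.raises(ValueError, match="2 distinct"):
            EssentialFractionScan(scan_dataset.breeding, scenario)

    def test_flat_response_slope_error(self, scan_dataset, monkeypatch):
        scenario = SimScenario(essential_fraction_grid=[0.0, 0.5], seed=0)
        scan = EssentialFractionScan(scan_dataset.breeding, scenario)
        flat = pd.DataFrame(
            {"essential_fraction": [0.0, 0.0, 0.5, 0.5],
             "genes_with_hom": [100, 100, 100, 100],
             "replicate": [0, 1, 0, 1],
             "virtual_g3_count": [10] * 4}
        )
        monkeypatch.setattr(scan, "simulate", lambda: flat)
        with pytest.raises(ValueError, match="slope"):
            scan.fit(100)

    def test_zero_fraction_equals_no_culling_pathway(self, scan_dataset):
        """At essential fraction 0 the replicate must reproduce, pup for pup,
        a simulation in which no mutation can kill (damage map all zero)."""
        ds = scan_dataset.breeding
        neutral = neutral_pedigree_sizes(ds)
        scenario = SimScenario(essential_fraction_grid=[0.0, 0.5], seed=0)
        no_damage = SimScenario(
            essential_fraction_grid=[0.0, 0.5],
            damage_map=DamageProbabilityMap(
                dict.fromkeys(DamageProbabilityMap.published().as_dict(), 0.0)
            ),
            seed=0,
        )
        seed = np.random.SeedSequence(31)
        a = simulate_replicate(ds, neutral, 0.0, scenario, seed)
        b = simulate_replicate(ds, neutral, 0.9, no_damage, np.random.SeedSequence(31))
        assert a.genes_with_hom == b.genes_with_hom
        assert a.virtual_g3_count == b.virtual_g3_count

    def test_genes_with_hom_decreases_with_fraction(self, scan_dataset):
        scenario = SimScenario(
            essential_fraction_grid=[0.0, 0.3, 0.6], replicates=3, seed=5
        )
        scan = EssentialFractionScan(scan_dataset.breeding, scenario)
        frame = scan.simulate()
        means = frame.groupby("essential_fraction")["genes_with_hom"].mean()
        assert means.loc[0.0] > means.loc[0.6]

    def test_recovers_generating_fraction(self):
        """End-to-end: a cohort generated at essential fraction 0.34 is
        recovered within a loose single-seed tolerance."""
        ds = generate_dataset(
            GeneratorConfig(n_pedigrees=60, seed=4, essential_fraction=0.34)
        )
        muts, mice, _ = ds.to_records()
        observed = observed_genes_with_hom(muts, mice)
        scenario = SimScenario(
            essential_fraction_grid=np.round(np.arange(0.0, 0.65, 0.05), 3),
            replicates=3,
            seed=9,
        )
        result = scan_essential_fraction(ds.breeding, scenario, observed)
        assert result.estimated_fraction == pytest.approx(0.34, abs=0.15)
        assert result.slope < 0
        assert "essential fraction" in str(result.summary())


def test_observed_genes_with_hom_counts_unique_genes():
    muts = [
        make_mutation("m1", gene_id="gA"),
        make_mutation("m2", gene_id="gA", position=150_000_000),
        make_mutation("m3", gene_id="gB", chromosome="2"),
    ]
    mice = [
        Mouse("k1", "P1", "G3", dam_id="D", litter_id="L",
              genotypes={"m1": "HOM", "m2": "HOM", "m3": "HET"}),
        Mouse("k2", "P1", "G3", dam_id="D", litter_id="L",
              genotypes={"m3": "REF"}),
    ]
    assert observed_genes_with_hom(muts, mice) == 1
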