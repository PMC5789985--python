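"""Method-of-moments estimator: closed form, clamping, bootstrap, windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enudamage import (
    HomFractionMixtureModel,
    MixtureModelParams,
    bootstrap_ci,
    estimate_by_class,
    estimate_by_score_window,
    mm_estimate,
    weighted_average_damage,
)
from enudamage.constants import COHORT_CLASS_COUNTS, PUBLISHED_DAMAGE_PROBABILITIES
from enudamage.filtering import FilteredMutation
from enudamage.synthetic import sample_hom_proportions
from tests.conftest import make_mutation


def _fm(p_hom_num, p_hom_den, cls="probably_damaging", score=0.97, mid="m"):
    return FilteredMutation(
        record=make_mutation(mid, mutation_class=cls, score=score),
        n_g3=p_hom_den,
        n_hom=p_hom_num,
    )


class TestPointEstimate:
    def test_mendelian_null_gives_zero(self):
        rho_raw, rho = mm_estimate([0.25, 0.25, 0.25])
        assert rho_raw == pytest.approx(0.0) and rho == 0.0

    def test_printed_closed_form_half_mix(self):
        # mean p = 0.125: 1.39 * 0.125 / 0.29875
        rho_raw, rho = mm_estimate([0.0, 0.25])
        assert rho_raw == pytest.approx(1.39 * 0.125 / 0.29875)
        assert rho_raw == pytest.approx(0.58159, abs=1e-5)

    def test_all_lethal_clamps_to_one(self):
        rho_raw, rho = mm_estimate([0.0] * 10)
        assert rho_raw == pytest.approx(1.16318, abs=1e-5)
        assert rho == 1.0

    def test_default_denominator_matches_printed_constant(self):
        assert MixtureModelParams().denominator == pytest.approx(0.29875)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_generalized_formula_equals_printed_form_at_defaults(self, p_list):
        rho_raw, _ = mm_estimate(p_list)
        printed = 1.39 * (0.25 - np.mean(p_list)) / 0.29875
        assert rho_raw == pytest.approx(printed, abs=1e-12)

    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=20),
        st.floats(0.001, 0.2),
    )
    @settings(derandomize=True, max_examples=50)
    def test_affine_and_decreasing_in_mean(self, p_list, shift):
        """The estimator is affine and strictly decreasing in mean(p)."""
        rho1, _ = mm_estimate(p_list)
        shifted = np.clip(np.asarray(p_list) + shift, 0, 1)
        if shifted.mean() > np.mean(p_list):
            rho2, _ = mm_estimate(shifted)
            assert rho2 < rho1

    def test_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            mm_estimate([])
        with pytest.raises(ValueError, match="theta"):
            MixtureModelParams(theta=0.3)
        with pytest.raises(ValueError, match="theta"):
            MixtureModelParams(theta=0.0)


class TestBootstrap:
    def test_degenerate_sample_zero_width(self):
        lo, hi = bootstrap_ci([0.25] * 50, reps=500, seed=1)
        assert (lo, hi) == (0.0, 0.0)

    def test_single_value_zero_width(self):
        lo, hi = bootstrap_ci([0.1], reps=200, seed=1)
        assert lo == pytest.approx(hi)

    def test_two_seeds_consistent_and_cover_point(self):
        p = sample_hom_proportions(690, 0.167, seed=7)
        _, rho = mm_estimate(p)
        ints = [bootstrap_ci(p, reps=2000, seed=s) for s in (1, 2)]
        for lo, hi in ints:
            assert lo <= rho <= hi
        (lo1, hi1), (lo2, hi2) = ints
        assert max(lo1, lo2) < min(hi1, hi2)  # intervals overlap

    def test_width_shrinks_like_sqrt_n(self):
        """Percentile-interval width scales roughly as 1/sqrt(n) on a fixed
        mixture distribution."""
        rng = np.random.default_rng(5)
        widths = {}
        for n in (100, 400, 1600):
            p = sample_hom_proportions(n, 0.3, seed=rng)
            lo, hi = bootstrap_ci(p, reps=2000, seed=rng)
            widths[n] = hi - lo
        assert widths[400] == pytest.approx(widths[100] / 2, rel=0.4)
        assert widths[1600] == pytest.approx(widths[400] / 2, rel=0.4)


class TestEstimateByClass:
    def test_single_class_input_single_row(self):
        filtered = [_fm(1, 8, mid=f"m{i}") for i in range(5)]
        res = estimate_by_class(filtered, reps=100, seed=0)
        assert len(res.estimates) == 1
        assert res.estimates[0].label == "probably_damaging"
        assert res["probably_damaging"].n == 5

    def test_undefined_p_hom_excluded(self):
        filtered = [_fm(1, 8, mid="a"), _fm(0, 0, mid="b")]
        res = estimate_by_class(filtered, reps=100, seed=0)
        assert res["probably_damaging"].n == 1

    def test_results_frame_and_summary(self):
        filtered = [_fm(1, 8, mid=f"m{i}") for i in range(4)]
        res = estimate_by_class(filtered, reps=100, seed=0)
        frame = res.frame
        assert set(frame.columns) >= {"label", "n", "rho", "ci_low", "ci_high"}
        assert "probably_damaging" in str(res.summary())

    def test_five_class_recovery_within_ci(self):
        """Each class's configured damaging fraction falls inside its own
        bootstrap CI on a moderately sized mixture draw."""
        rng = np.random.default_rng(99)
        filtered = []
        for cls, frac in PUBLISHED_DAMAGE_PROBABILITIES.items():
            score = {"probably_benign": 0.1, "possibly_damaging": 0.6,
                     "probably_damaging": 0.97}.get(cls)
            p = sample_hom_proportions(400, frac, seed=rng)
            den = np.maximum(1, rng.poisson(15, size=400))
            for i, pi in enumerate(p):
                num = int(round(pi * den[i]))
                filtered.append(
                    _fm(min(num, den[i]), int(den[i]), cls=cls, score=score,
                        mid=f"{cls}_{i}")
                )
        res = estimate_by_class(filtered, reps=1000, seed=11)
        assert len(res.estimates) == 5
        for cls, frac in PUBLISHED_DAMAGE_PROBABILITIES.items():
            est = res[cls]
            assert est.ci_low - 0.02 <= frac <= est.ci_high + 0.02


class TestScoreWindows:
    def _filtered(self):
        out = []
        scores = [0.1, 0.3, 0.5, 0.5, 0.7, 0.95, 1.0]
        for i, s in enumerate(scores):
            cls = ("probably_benign" if s <= 0.45
                   else "possibly_damaging" if s <= 0.95 else "probably_damaging")
            out.append(_fm(2, 8, cls=cls, score=s, mid=f"w{i}"))
        return out

    def test_partition_each_mutation_once(self):
        res = estimate_by_score_window(
            self._filtered(), [(0.0, 0.5), (0.5, 1.0)], reps=50, seed=0
        )
        assert sum(e.n for e in res.estimates) == 7

    def test_boundary_score_goes_to_lower_window(self):
        res = estimate_by_score_window(
            self._filtered(), [(0.0, 0.5), (0.5, 1.0)], reps=50, seed=0
        )
        assert res["(0,0.5]"].n == 4  # 0.1, 0.3 and both 0.5 scores

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            estimate_by_score_window(self._filtered(), [(0.0, 0.6), (0.5, 1.0)])

    def test_monotone_estimates_when_damage_rises_with_score(self):
        """Windows binning scores generated with increasing true damage give
        nondecreasing estimates (up to noise at n=300 per window)."""
        rng = np.random.default_rng(3)
        filtered = []
        for w, (score, frac) in enumerate([(0.2, 0.03), (0.6, 0.3), (0.98, 0.7)]):
            cls = ("probably_benign" if score <= 0.45
                   else "possibly_damaging" if score <= 0.95 else "probably_damaging")
            p = sample_hom_proportions(300, frac, seed=rng)
            for i, pi in enumerate(p):
                den = max(1, int(rng.poisson(15)))
                filtered.append(
                    _fm(int(round(pi * den)), den, cls=cls, score=score,
                        mid=f"s{w}_{i}")
                )
        res = estimate_by_score_window(
            filtered, [(0.0, 0.45), (0.45, 0.95), (0.95, 1.0)], reps=100, seed=5
        )
        rhos = [e.rho for e in res.estimates]
        assert rhos == sorted(rhos)


class TestWeightedAverage:
    def test_reference_counts_give_sixteen_percent(self):
        value = weighted_average_damage(
            PUBLISHED_DAMAGE_PROBABILITIES, COHORT_CLASS_COUNTS["all"]
        )
        assert value == pytest.approx(0.158, abs=5e-4)
        assert round(value * 100) == 16

    def test_equal_rho_returns_rho(self):
        rho = {"a": 0.3, "b": 0.3}
        assert weighted_average_damage(rho, {"a": 10, "b": 90}) == pytest.approx(0.3)

    def test_single_class(self):
        assert weighted_average_damage({"a": 0.7}, {"a": 5}) == pytest.approx(0.7)

    def test_class_mismatch_errors(self):
        with pytest.raises(KeyError, match="b"):
            weighted_average_damage({"a": 0.1}, {"a": 1, "b": 2})


def test_model_results_roundtrip():
    p = sample_hom_proportions(200, 0.4, seed=1)
    res = HomFractionMixtureModel(p, label="demo").fit(bootstrap_reps=500, seed=2)
    est = res.estimates[0]
    assert est.ci_low <= est.rho <= est.ci_high
    assert est.n == 200 and est.bootstrap_reps == 500
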