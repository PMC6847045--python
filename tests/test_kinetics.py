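import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import linregress

from pdcovar.errors import FitError, NormalizationError, TransformError
from pdcovar.kinetics import (
    _ols,
    barcode_relative_cleavage,
    clr_table,
    clr_transform,
    depletion_rates,
    differential_substrates,
    preference_summary,
)


class TestClrTransform:
    def test_equal_counts_give_zeros(self):
        assert clr_transform(np.full(256, 17)) == pytest.approx(np.zeros(256), abs=1e-12)

    def test_hand_example(self):
        # log2(c + 0.5) centered: counts (1,1,2) -> (-0.2457, -0.2457, 0.4913)
        v = clr_transform([1, 1, 2], pseudocount=0.5)
        assert v == pytest.approx([-0.2456552, -0.2456552, 0.4913104], abs=1e-6)
        assert v.sum() == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        c = np.array([3, 0, 10, 7])
        a = clr_transform(c, pseudocount=0.5)
        b = clr_transform(10 * c, pseudocount=5.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_zero_without_pseudocount_rejected(self):
        with pytest.raises(TransformError):
            clr_transform(np.zeros(4), pseudocount=0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(TransformError):
            clr_transform([1, -1, 2])

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=50))
    def test_output_sums_to_zero(self, counts):
        assert abs(clr_transform(counts).sum()) < 1e-9

    def test_dirichlet_mc_mode_is_seeded_and_consistent(self):
        c = np.array([500, 900, 100, 2500])
        a = clr_transform(c, n_mc=64, rng=np.random.default_rng(5))
        b = clr_transform(c, n_mc=64, rng=np.random.default_rng(5))
        assert a == pytest.approx(b, abs=0)
        assert a == pytest.approx(clr_transform(c), abs=0.1)


def _clr_frame(values, times):
    cols = [("WT", 1, t) for t in times]
    return pd.DataFrame(values, index=[f"s{i}" for i in range(len(values))], columns=cols)


class TestDepletionRates:
    def test_constant_clr_gives_zero_slope_and_se(self):
        times = [0, 5, 10, 30]
        clr = _clr_frame([[1.0] * 4, [-2.0] * 4], times)
        fit = depletion_rates(clr, times)
        assert fit.k_rel.to_numpy() == pytest.approx([0, 0], abs=1e-12)
        assert fit.se_slope.to_numpy() == pytest.approx([0, 0], abs=1e-12)

    def test_exact_linear_decay_recovered(self):
        times = np.array([0.0, 5, 10, 15, 30])
        clr = _clr_frame([2.0 - 0.5 * times, 0.1 * times], times)
        fit = depletion_rates(clr, times)
        assert fit.k_rel.to_numpy() == pytest.approx([-0.5, 0.1], abs=1e-12)
        assert fit.sigma.to_numpy() == pytest.approx([0, 0], abs=1e-9)
        assert fit.intercept.to_numpy() == pytest.approx([2.0, 0.0], abs=1e-12)

    def test_replicates_pooled_into_one_fit(self):
        times = [0, 10, 0, 10]  # two replicates of two timepoints
        clr = _clr_frame([[0.0, -1.0, 0.2, -0.8]], times)
        fit = depletion_rates(clr, times)
        slope = linregress([0, 10, 0, 10], [0.0, -1.0, 0.2, -0.8]).slope
        assert fit.k_rel.iloc[0] == pytest.approx(slope, abs=1e-12)
        assert fit.n_points.iloc[0] == 4

    def test_fewer_than_two_distinct_times_rejected(self):
        clr = _clr_frame([[1.0, 2.0]], [5, 5])
        with pytest.raises(FitError):
            depletion_rates(clr, [5, 5])

    def test_compositional_shift_leaves_slope_differences_unchanged(self):
        rng = np.random.default_rng(8)
        times = np.array([0.0, 5, 10, 30, 60])
        Y = rng.normal(size=(6, 5))
        fit0 = depletion_rates(_clr_frame(Y, times), times)
        shift = rng.normal(size=5)  # one constant per timepoint
        fit1 = depletion_rates(_clr_frame(Y + shift, times), times)
        d0 = fit0.k_rel.to_numpy() - fit0.k_rel.to_numpy()[0]
        d1 = fit1.k_rel.to_numpy() - fit1.k_rel.to_numpy()[0]
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_ols_matches_scipy_linregress(self):
        rng = np.random.default_rng(2)
        t = np.array([0.0, 5, 10, 15, 30, 60, 120])
        Y = rng.normal(size=(5, 7))
        slope, intercept, sigma, se = _ols(Y, t)
        for i in range(5):
            ref = linregress(t, Y[i])
            assert slope[i] == pytest.approx(ref.slope, abs=1e-12)
            assert intercept[i] == pytest.approx(ref.intercept, abs=1e-12)
            assert se[i] == pytest.approx(ref.stderr, abs=1e-12)


def _rates(k, sd=0.05):
    idx = [f"s{i}" for i in range(len(k))]
    return pd.DataFrame({"k_rel": k, "sigma": sd, "se_slope": sd}, index=idx)


class TestDifferentialSubstrates:
    def test_identical_rates_flag_nothing(self):
        r = _rates([-0.1, -0.2, -0.3])
        assert differential_substrates(r, r.copy(), 2.0).empty

    def test_five_sd_displacement_flagged_on_correct_side(self):
        a = _rates([-0.1, -0.2, -0.3])
        b = a.copy()
        b.loc["s1", "k_rel"] -= 5 * 0.05  # faster in B only
        flagged = differential_substrates(a, b, 2.0)
        assert list(flagged.index) == ["s1"]
        assert flagged.loc["s1", "side"] == "B"

    def test_side_A_when_A_depletes_faster(self):
        a = _rates([-0.5, -0.2])
        b = _rates([-0.1, -0.2])
        flagged = differential_substrates(a, b, 2.0)
        assert flagged.loc["s0", "side"] == "A"

    def test_zero_sd_flags_any_difference(self):
        a = _rates([-0.1, -0.2], sd=0.0)
        b = _rates([-0.1, -0.3], sd=0.0)
        flagged = differential_substrates(a, b, 2.0)
        assert list(flagged.index) == ["s1"]

    def test_mismatched_substrate_sets_rejected(self):
        a = _rates([-0.1, -0.2])
        b = _rates([-0.1, -0.2, -0.3])
        with pytest.raises(ValueError):
            differential_substrates(a, b)

    def test_threshold_matches_ellipse_geometry(self):
        # equal sigmas s: flagged iff |kA - kB| > sqrt(2) * n_sd * s
        s, n_sd = 0.05, 2.0
        crit = np.sqrt(2) * n_sd * s
        a = _rates([0.0, 0.0], sd=s)
        b = _rates([-(crit * 0.99), -(crit * 1.01)], sd=s)
        flagged = differential_substrates(a, b, n_sd)
        assert list(flagged.index) == ["s1"]


class TestPreferenceSummary:
    def test_single_substrate_is_one_hot(self):
        m = preference_summary(["CAAC"])
        assert m.loc["+2", "C"] == 1 and m.loc["+3", "A"] == 1
        assert m.loc["+4", "A"] == 1 and m.loc["+5", "C"] == 1

    def test_all_substrates_uniform(self):
        from pdcovar.depletion_counts import enumerate_substrates

        m = preference_summary(enumerate_substrates(4))
        assert m.to_numpy() == pytest.approx(np.full((4, 4), 0.25), abs=1e-12)

    def test_two_substrates_split_first_position(self):
        m = preference_summary(["TAAC", "CAAC"])
        assert m.loc["+2", "T"] == 0.5 and m.loc["+2", "C"] == 0.5

    def test_rows_sum_to_one(self):
        m = preference_summary(["CAAC", "GTTG", "ACGT"])
        assert m.sum(axis=1).to_numpy() == pytest.approx(np.ones(4), abs=1e-12)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            preference_summary([])


class TestBarcodeRelativeCleavage:
    def _timecourses(self):
        t = np.array([0.0, 10, 20, 30])
        return pd.DataFrame(
            {
                "substrate": ["A"] * 4 + ["G"] * 4 + ["T"] * 4,
                "time_min": np.tile(t, 3),
                "cleaved_fraction": np.concatenate([0.02 * t, 0.01 * t, 0.0 * t]),
            }
        )

    def test_reference_normalizes_to_one_and_ratios_follow(self):
        rel = barcode_relative_cleavage(self._timecourses(), reference="A")
        assert rel["A"] == pytest.approx(1.0, abs=1e-12)
        assert rel["G"] == pytest.approx(0.5, abs=1e-12)
        assert rel["T"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_reference_slope_rejected(self):
        with pytest.raises(NormalizationError):
            barcode_relative_cleavage(self._timecourses(), reference="T")

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            barcode_relative_cleavage(self._timecourses(), reference="C")

    def test_single_timepoint_rejected(self):
        tc = pd.DataFrame(
            {"substrate": ["A", "A"], "time_min": [5, 5], "cleaved_fraction": [0.1, 0.2]}
        )
        with pytest.raises(FitError):
            barcode_relative_cleavage(tc, reference="A")


def test_clr_table_applies_per_sample():
    counts = pd.DataFrame(
        {("WT", 1, 0.0): [4, 4, 8], ("WT", 1, 5.0): [1, 1, 2]},
        index=["a", "b", "c"],
    )
    out = clr_table(counts, pseudocount=0.5)
    assert out.to_numpy().sum(axis=0) == pytest.approx([0, 0], abs=1e-9)
    assert out[("WT", 1, 0.0)].to_numpy() == pytest.approx(
        clr_transform([4, 4, 8]), abs=1e-12
    )
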