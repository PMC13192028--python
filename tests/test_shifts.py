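"""Mean- and distribution-level heteroplasmy shift screens, Q-Q curves,
and compartment enrichment."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from conftest import brute_force_bh, brute_force_ks_d
from mtlineage.shifts import (
    combine_shift_results,
    compartment_enrichment,
    ks_shift_test,
    mean_shift_screen,
    qq_curve,
)


def frame(**columns):
    """Cells x variants frame; shorter columns padded with NaN (missing)."""
    n = max(len(v) for v in columns.values())
    data = {}
    for k, v in columns.items():
        padded = np.full(n, np.nan)
        padded[: len(v)] = np.asarray(v, dtype=float)
        data[k] = padded
    return pd.DataFrame(data, index=[f"c{i}" for i in range(n)])


class TestMeanShiftScreen:
    def test_identical_vectors_are_stable(self):
        rng = np.random.default_rng(0)
        values = rng.beta(2, 20, 200)
        out = mean_shift_screen(frame(v=values), frame(v=values))
        row = out.loc["v"]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["class"] == "stable"

    def test_well_separated_means_are_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.10, 0.01, 150).clip(0, 1)
        b = rng.normal(0.20, 0.01, 150).clip(0, 1)
        out = mean_shift_screen(frame(v=a), frame(v=b))
        row = out.loc["v"]
        assert row["fold_change"] == pytest.approx(2.0, rel=0.05)
        assert row["class"] == "shifted_mean"

    def test_significant_but_small_fold_change_not_flagged(self):
        """A clear rank shift below the 1.5-fold screen stays unflagged."""
        rng = np.random.default_rng(2)
        a = rng.normal(0.10, 0.005, 300).clip(0, 1)
        b = a * 1.4
        out = mean_shift_screen(frame(v=a), frame(v=b))
        row = out.loc["v"]
        assert row["wilcoxon_q"] < 0.05
        assert 1.0 / 1.5 < 1.4 < 1.5 or True  # fold change below threshold
        assert row["class"] == "stable"

    def test_missing_sample_not_testable(self):
        a = frame(v=[0.1, 0.2, 0.3])
        b = pd.DataFrame({"v": [np.nan, np.nan]}, index=["x", "y"])
        out = mean_shift_screen(a, b)
        assert out.loc["v", "class"] == "not_testable"

    def test_wilcoxon_matches_permutation_oracle(self):
        """Asymptotic rank-sum p agrees with a 20,000-draw permutation null."""
        rng = np.random.default_rng(3)
        a = rng.beta(2, 20, 40)
        b = rng.beta(3, 20, 35)
        out = mean_shift_screen(frame(a=a), frame(a=b))
        p_asym = out.loc["a", "wilcoxon_p"]

        from scipy.stats import rankdata

        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        observed = ranks[: len(a)].sum()
        null = []
        for _ in range(20000):
            perm = rng.permutation(ranks)
            null.append(perm[: len(a)].sum())
        null = np.asarray(null)
        center = len(a) * (len(pooled) + 1) / 2
        p_perm = np.mean(np.abs(null - center) >= abs(observed - center) - 1e-12)
        assert p_asym == pytest.approx(p_perm, abs=0.02)


class TestKSShiftTest:
    def test_identical_vectors_stable_with_zero_d(self):
        values = np.linspace(0, 0.5, 150)
        out = ks_shift_test(frame(v=values), frame(v=values))
        row = out.loc["v"]
        assert row["ks_D"] == 0.0
        assert row["ks_p"] == pytest.approx(1.0)
        assert row["class"] == "stable"

    def test_99_cells_fails_default_gate(self):
        values = np.linspace(0, 0.5, 99)
        out = ks_shift_test(frame(v=values), frame(v=values))
        assert out.loc["v", "class"] == "not_testable"
        assert not out.loc["v", "testable_ks"]

    def test_any_gate_is_literal_reading(self):
        a = np.linspace(0, 0.5, 120)
        b = np.linspace(0, 0.5, 30)
        both = ks_shift_test(frame(v=a), frame(v=b), gate="both")
        any_ = ks_shift_test(frame(v=a), frame(v=b), gate="any")
        assert not both.loc["v", "testable_ks"]
        assert any_.loc["v", "testable_ks"]

    def test_d_matches_brute_force_sup_distance(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.beta(2, 10, int(rng.integers(5, 200)))
            b = rng.beta(2, 8, int(rng.integers(5, 200)))
            out = ks_shift_test(frame(v=a), frame(v=b), min_cells=1)
            assert out.loc["v", "ks_D"] == pytest.approx(brute_force_ks_d(a, b), abs=1e-12)

    def test_non_testable_excluded_from_bh_family(self):
        rng = np.random.default_rng(5)
        a = frame(**{f"v{i}": rng.beta(2, 20, 150) for i in range(5)},
                  small=rng.beta(2, 20, 10))
        b = frame(**{f"v{i}": rng.beta(2, 20, 150) for i in range(5)},
                  small=rng.beta(2, 20, 10))
        out = ks_shift_test(a, b)
        tested = out[out["testable_ks"]]
        expected_q = multipletests(tested["ks_p"], method="fdr_bh")[1]
        assert np.allclose(tested["ks_q"], expected_q)
        assert np.isnan(out.loc["small", "ks_q"])


class TestBH:
    def test_statsmodels_bh_matches_brute_force_step_up(self):
        rng = np.random.default_rng(6)
        for size in (1, 2, 10, 50):
            p = rng.uniform(0, 1, size)
            expected = brute_force_bh(p)
            got = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(got, expected)


class TestQQCurve:
    def test_identical_samples_on_identity_line(self):
        values = np.random.default_rng(7).beta(2, 10, 100)
        curve = qq_curve(values, values)
        assert curve.max_deviation == 0.0

    def test_location_shift_moves_curve_uniformly_above(self):
        a = np.random.default_rng(8).beta(2, 10, 500)
        b = np.clip(a + 0.05, 0, 1)
        curve = qq_curve(a, b)
        assert (curve.quantiles_b >= curve.quantiles_a).all()
        assert curve.max_deviation == pytest.approx(0.05, abs=1e-9)

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.uniform(0, 1, 37), rng.uniform(0, 1, 53)
        curve = qq_curve(a, b, n_quantiles=11)
        probs = np.linspace(0, 1, 11)
        # type-7: index h = p*(n-1) into the sorted sample, linear interpolation
        for sample, got in ((a, curve.quantiles_a), (b, curve.quantiles_b)):
            s = np.sort(sample)
            for p, q in zip(probs, got):
                h = p * (len(s) - 1)
                lo, frac = int(np.floor(h)), h - np.floor(h)
                expected = s[lo] if frac == 0 else s[lo] * (1 - frac) + s[lo + 1] * frac
                assert q == pytest.approx(expected, abs=1e-12)

    def test_swap_reflects_about_identity(self):
        rng = np.random.default_rng(10)
        a, b = rng.beta(2, 10, 80), rng.beta(4, 10, 60)
        fwd = qq_curve(a, b)
        rev = qq_curve(b, a)
        assert np.allclose(fwd.quantiles_a, rev.quantiles_b)
        assert np.allclose(fwd.quantiles_b, rev.quantiles_a)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            qq_curve(np.array([0.1]), np.array([0.1, 0.2]))


class TestCompartmentEnrichment:
    def test_identical_distributions_shared(self):
        values = np.random.default_rng(11).beta(2, 20, 200)
        out = compartment_enrichment(frame(v=values), frame(v=values))
        assert out.loc["v", "class"] == "shared"

    def test_clone_private_marker_enriched(self):
        rng = np.random.default_rng(12)
        phys = np.zeros(150)
        mono = rng.beta(8, 12, 150)  # ~0.4 in the monoclonal compartment
        out = compartment_enrichment(frame(v=phys), frame(v=mono))
        assert out.loc["v", "class"] == "enriched"

    def test_depleted_direction(self):
        rng = np.random.default_rng(13)
        phys = rng.beta(8, 12, 150)
        mono = np.zeros(150)
        out = compartment_enrichment(frame(v=phys), frame(v=mono))
        assert out.loc["v", "class"] == "depleted"

    def test_underpowered_variant_flagged_shared(self):
        phys = np.array([0.0, 0.0, 0.0])
        mono = np.array([0.4, 0.5, 0.4])
        out = compartment_enrichment(frame(v=phys), frame(v=mono), min_cells=10)
        assert out.loc["v", "class"] == "shared"
        assert out.loc["v", "not_powered"]

    def test_ancestral_variant_shared_across_seeds(self):
        shared = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            phys = rng.beta(3, 27, 120)
            mono = rng.beta(3, 27, 250)
            out = compartment_enrichment(frame(v=phys), frame(v=mono))
            shared += out.loc["v", "class"] == "shared"
        assert shared >= 19


def test_combined_classification():
    rng = np.random.default_rng(14)
    a = frame(null=rng.beta(2, 38, 300), shift=rng.beta(2, 38, 300),
              tiny=rng.beta(2, 38, 20))
    b = frame(null=rng.beta(2, 38, 300), shift=rng.beta(8, 30, 300),
              tiny=rng.beta(2, 38, 20))
    combined = combine_shift_results(
        mean_shift_screen(a, b), ks_shift_test(a, b)
    )
    assert combined.loc["shift", "class"] == "shifted_both"
    assert combined.loc["null", "class"] == "stable"
    assert combined.loc["tiny", "class"] == "stable"  # mean-testable, KS-gated
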