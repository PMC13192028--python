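"""Heteroplasmy computation, the high-confidence filter stack, burden,
recurrence and targeted genotyping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_heteroplasmy
from mtlineage.genome import parse_variant_id, variant_id
from mtlineage.simulate import SimulationConfig, simulate_population
from mtlineage.variants import (
    VariantCall,
    call_variants,
    compute_heteroplasmy,
    filter_variants,
    genotype_cells,
    mutation_burden,
    passing_ids,
    recurrence_table,
    variant_statistics,
)


class TestVariantIds:
    def test_round_trip(self):
        assert parse_variant_id(variant_id(7161, "G", "A")) == (7161, "G", "A")

    @pytest.mark.parametrize("bad", ["7161G>G", "0A>C", "20000A>C", "xyz", "12G-A"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_variant_id(bad)


class TestComputeHeteroplasmy:
    def test_simple_fraction_and_missing(self, tiny_tensor):
        het = compute_heteroplasmy(tiny_tensor, ["9C>T"], min_coverage=5)["9C>T"]
        assert het["c0"] == 0.0  # 8x C, no T
        assert het["c1"] == pytest.approx(4 / 8)
        assert het["c2"] == pytest.approx(1.0)  # 6x T of coverage 6
        # raising min_coverage above c2's 6 reads turns the entry missing
        het2 = compute_heteroplasmy(tiny_tensor, ["9C>T"], min_coverage=7)["9C>T"]
        assert np.isnan(het2["c2"])

    def test_zero_coverage_is_missing(self, tiny_tensor):
        het = compute_heteroplasmy(tiny_tensor, ["5A>G"], min_coverage=1)["5A>G"]
        assert np.isnan(het["c2"])  # no reads at position 5 in c2
        assert het["c0"] == pytest.approx(2 / 12)

    def test_alt_equal_ref_rejected(self, tiny_tensor):
        with pytest.raises(ValueError, match="REF"):
            compute_heteroplasmy(tiny_tensor, ["5C>G"])

    def test_matches_brute_force_on_random_fixture(self, default_sim):
        _config, sample, truth = default_sim
        vids = list(truth.variants.index)
        sub = sample.tensor.subset_cells(sample.tensor.barcodes[:50])
        expected = brute_force_heteroplasmy(sub, vids, min_coverage=5)
        got = compute_heteroplasmy(sub, vids, min_coverage=5)
        pd.testing.assert_frame_equal(got, expected, check_exact=False)

    def test_entries_in_unit_interval_and_idempotent(self, default_sim):
        _config, sample, truth = default_sim
        vids = list(truth.variants.index)
        het1 = compute_heteroplasmy(sample.tensor, vids)
        het2 = compute_heteroplasmy(sample.tensor, vids)
        values = het1.to_numpy()
        finite = values[~np.isnan(values)]
        assert ((finite >= 0) & (finite <= 1)).all()
        pd.testing.assert_frame_equal(het1, het2)


class TestVariantStatistics:
    def _uniform_tensor(self, per_cell_alt, per_cell_total, n_cells=10):
        """All cells identical: `alt` of 'T' and the rest 'A' at position 3."""
        from mtlineage.counts import BaseCountTensor

        counts = np.zeros((n_cells, 1, 4, 2), dtype=np.int64)
        for i, (alt, total) in enumerate(zip(per_cell_alt, per_cell_total)):
            counts[i, 0, 3, 0] = alt // 2
            counts[i, 0, 3, 1] = alt - alt // 2
            ref = total - alt
            counts[i, 0, 0, 0] = ref // 2
            counts[i, 0, 0, 1] = ref - ref // 2
        return BaseCountTensor(
            barcodes=[f"c{i}" for i in range(n_cells)],
            positions=np.array([3]),
            ref_bases=np.array(["A"]),
            counts=counts,
        )

    def test_constant_heteroplasmy_gives_zero_vmr(self):
        tensor = self._uniform_tensor([10] * 10, [20] * 10)
        call = variant_statistics(tensor, "3A>T")
        assert call.vmr == 0.0
        assert call.mean_heteroplasmy == pytest.approx(0.5)

    def test_identical_strand_counts_give_perfect_concordance(self):
        alts = [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]
        tensor = self._uniform_tensor(alts, [40] * 10)
        call = variant_statistics(tensor, "3A>T")
        assert call.strand_concordance == pytest.approx(1.0)

    def test_fewer_than_two_detected_cells_fails_concordance(self):
        tensor = self._uniform_tensor([10] + [0] * 9, [20] * 10)
        call = variant_statistics(tensor, "3A>T")
        assert call.n_cells_detected == 1
        assert call.strand_concordance == float("-inf")

    def test_detection_monotone_in_threshold(self, default_sim):
        _config, sample, truth = default_sim
        vid = truth.variants.index[0]
        detected = [
            variant_statistics(sample.tensor, vid, detection_threshold=t).n_cells_detected
            for t in (0.0, 0.01, 0.05, 0.2, 0.5)
        ]
        assert detected == sorted(detected, reverse=True)


class TestFilterVariants:
    def _call(self, **kw):
        defaults = dict(
            variant_id="100A>T", n_cells_detected=10, mean_heteroplasmy=0.3,
            vmr=0.05, strand_concordance=0.9,
        )
        defaults.update(kw)
        return VariantCall(**defaults)

    def test_boundary_four_cells_rejected(self):
        out = filter_variants([self._call(n_cells_detected=4)])
        assert not out[0].pass_filters and "n_cells" in out[0].fail_reasons

    def test_five_cells_pass(self):
        out = filter_variants([self._call(n_cells_detected=5, vmr=0.02)])
        assert out[0].pass_filters

    def test_blacklisted_variant_rejected_despite_perfect_stats(self):
        out = filter_variants([self._call(variant_id="310T>C")])
        assert out[0].fail_reasons == frozenset({"blacklist"})

    def test_homoplasmy_requires_every_compartment(self):
        call = self._call(mean_heteroplasmy=0.95)
        everywhere = filter_variants(
            [call], compartment_means={"100A>T": [0.95, 0.93]}
        )[0]
        one_compartment = filter_variants(
            [call], compartment_means={"100A>T": [0.95, 0.4]}
        )[0]
        assert "homoplasmic" in everywhere.fail_reasons
        assert one_compartment.pass_filters

    def test_matches_brute_force_reevaluation(self):
        rng = np.random.default_rng(0)
        calls = [
            self._call(
                variant_id=f"{i + 1}A>T",
                n_cells_detected=int(rng.integers(0, 12)),
                vmr=float(rng.uniform(0, 0.05)),
                strand_concordance=float(rng.uniform(-1, 1)),
                mean_heteroplasmy=float(rng.uniform(0, 1)),
            )
            for i in range(200)
        ]
        out = filter_variants(calls, blacklist=frozenset({"3A>T"}))
        for call in out:
            expected = (
                call.n_cells_detected > 4
                and call.vmr > 0.01
                and call.strand_concordance > 0.65
                and call.variant_id != "3A>T"
                and call.mean_heteroplasmy < 0.9
            )
            assert call.pass_filters == expected, call


class TestMutationBurden:
    def test_no_variant_above_threshold_gives_zero(self):
        het = pd.DataFrame(
            0.005, index=[f"c{i}" for i in range(120)], columns=["1A>T", "2A>T"]
        )
        groups = pd.Series("g", index=het.index)
        cov = pd.Series(50.0, index=het.index)
        out = mutation_burden(het, groups, cov, seed=0)
        assert out["burden"].iloc[0] == 0

    def test_identical_groups_same_seed_identical_burden(self):
        rng = np.random.default_rng(1)
        het = pd.DataFrame(
            rng.uniform(0, 0.2, size=(240, 5)),
            index=[f"c{i}" for i in range(240)],
            columns=[f"{p}A>T" for p in range(1, 6)],
        )
        groups = pd.Series(["g1"] * 120 + ["g2"] * 120, index=het.index)
        cov = pd.Series(50.0, index=het.index)
        # both groups see identical heteroplasmy and coverage patterns
        het.iloc[120:] = het.iloc[:120].to_numpy()
        out = mutation_burden(het, groups, cov, seed=3).set_index("group")
        assert out.loc["g1", "burden"] == out.loc["g2", "burden"]

    def test_small_groups_skipped(self):
        het = pd.DataFrame(0.1, index=["a", "b"], columns=["1A>T"])
        out = mutation_burden(
            het, pd.Series("g", index=het.index), pd.Series(10.0, index=het.index)
        )
        assert out.empty

    def test_marker_rich_population_has_higher_burden(self):
        """More clonal marker mutations -> higher normalized burden (10 seeds)."""
        wins = 0
        for seed in range(10):
            burdens = {}
            for name, markers in (("mbl", 8), ("bcell", 2)):
                config = SimulationConfig(
                    n_cells=150, n_clones=1, polyclonal_fraction=0.0,
                    markers_per_clone=markers, n_artifact_variants=0,
                    n_germline_variants=0, seed=seed,
                )
                sample, truth = simulate_population(config, with_fragments=False)
                het = compute_heteroplasmy(sample.tensor, list(truth.variants.index))
                cov = pd.Series(
                    sample.tensor.mean_coverage_per_cell(), index=het.index
                )
                groups = pd.Series(name, index=het.index)
                out = mutation_burden(het, groups, cov, seed=seed)
                burdens[name] = out["burden"].iloc[0]
            wins += burdens["mbl"] > burdens["bcell"]
        assert wins >= 9


class TestRecurrence:
    def test_counts_match_brute_force_on_three_donors(self):
        donors = {
            "d1": ["1A>T", "2C>G"],
            "d2": ["1A>T", "3G>A"],
            "d3": ["1A>T"],
        }
        table, summary = recurrence_table(donors)
        counts = dict(zip(table["variant_id"], table["n_donors"]))
        assert counts == {"1A>T": 3, "2C>G": 1, "3G>A": 1}
        assert summary["n_non_recurrent"] == 2
        assert summary["fraction_non_recurrent"] == pytest.approx(2 / 3)
        assert summary["max_recurrence"] == 3

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            recurrence_table({})


class TestGenotyping:
    @pytest.mark.parametrize(
        "mutant,wildtype,expected",
        [
            (9, 0, "unassigned"),  # below the 10-read minimum
            (6, 5, "mutant"),
            (5, 6, "wildtype"),
            (5, 5, "wildtype"),  # tie is not "more reads supporting the mutant"
            (10, 0, "mutant"),
        ],
    )
    def test_rule_boundaries(self, mutant, wildtype, expected):
        out = genotype_cells(
            pd.DataFrame({"mutant_reads": [mutant], "wildtype_reads": [wildtype]})
        )
        assert out["call"].iloc[0] == expected

    @settings(derandomize=True, max_examples=200)
    @given(
        mutant=st.integers(min_value=0, max_value=50),
        wildtype=st.integers(min_value=0, max_value=50),
    )
    def test_rule_matches_direct_predicate(self, mutant, wildtype):
        out = genotype_cells(
            pd.DataFrame({"mutant_reads": [mutant], "wildtype_reads": [wildtype]})
        )["call"].iloc[0]
        if mutant + wildtype < 10:
            assert out == "unassigned"
        elif mutant > wildtype:
            assert out == "mutant"
        else:
            assert out == "wildtype"


def test_pipeline_filters_are_seed_free(default_sim):
    """Variant statistics involve no randomness: recomputation is identical."""
    _config, sample, _truth = default_sim
    calls_1 = passing_ids(filter_variants(call_variants(sample.tensor)))
    calls_2 = passing_ids(filter_variants(call_variants(sample.tensor)))
    assert calls_1 == calls_2
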