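"""Nested SSQ/MSQ decomposition against literal brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from oracles import brute_nested, random_hierarchy
from woodvar.anova import (
    HierarchyDesign,
    compute_dof,
    nested_decomposition,
    normalize_msq,
    per_lot_decomposition,
)
from woodvar.errors import DesignError
from woodvar.simulate import generate_dataset


class TestDof:
    def test_study_design_arithmetic(self):
        dof, total = compute_dof([16, 64, 126, 26_192])
        assert list(dof.values()) == [15, 48, 62, 26_066]
        assert total == 26_191

    def test_degenerate_level_rejected_by_name(self):
        with pytest.raises(DesignError, match="level1"):
            compute_dof([1, 1, 1, 2])

    def test_matches_recount_on_random_designs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            values, labels = random_hierarchy(rng)
            design = HierarchyDesign.from_labels(labels)
            try:
                dof, total = design.dof()
            except DesignError:
                continue  # unreplicated level somewhere: correctly rejected
            # brute-force recount of unique units per level
            n1 = labels["lot"].nunique()
            n2 = labels[["lot", "subsample"]].drop_duplicates().shape[0]
            n3 = labels[["lot", "subsample", "replicate"]].drop_duplicates().shape[0]
            n4 = len(labels)
            assert list(dof.values()) == [n1 - 1, n2 - n1, n3 - n2, n4 - n3]
            assert total == n4 - 1


class TestDecomposition:
    def test_constant_input_gives_zero_everywhere(self):
        labels = pd.DataFrame(
            {"lot": ["a"] * 4 + ["b"] * 4, "subsample": ["s1", "s1", "s2", "s2"] * 2}
        )
        dec = nested_decomposition(np.full((8, 3), 2.5), labels)
        for lvl in dec.levels:
            assert np.allclose(dec.ssq[lvl], 0.0)
            if lvl not in dec.undefined:
                assert np.allclose(dec.msq[lvl], 0.0)

    def test_toy_hierarchy_matches_hand_oracle(self):
        # 2 lots x 2 subsamples x 2 scans with hand-listed values
        labels = pd.DataFrame(
            {
                "lot": ["L1"] * 4 + ["L2"] * 4,
                "subsample": ["a", "a", "b", "b", "c", "c", "d", "d"],
            }
        )
        values = np.array([1.0, 3.0, 2.0, 6.0, 10.0, 12.0, 20.0, 14.0])
        dec = nested_decomposition(values, labels)
        ssq, msq, dof = brute_nested(values, labels)
        for lvl in dec.levels:
            assert dec.ssq[lvl] == pytest.approx(ssq[lvl], rel=1e-12)
            if dof[lvl] > 0:
                assert dec.msq[lvl] == pytest.approx(msq[lvl], rel=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_random_hierarchies_match_brute_force(self, weighted):
        rng = np.random.default_rng(42)
        for _ in range(30):
            values, labels = random_hierarchy(rng, n_cols=2)
            dec = nested_decomposition(values, labels, weighted=weighted)
            ssq, _, dof = brute_nested(values, labels, weighted=weighted)
            for lvl in dec.levels:
                np.testing.assert_allclose(dec.ssq[lvl], ssq[lvl], rtol=1e-12, atol=1e-12)
                assert dec.dof[lvl] == dof[lvl]

    def test_msq_times_dof_equals_ssq(self):
        rng = np.random.default_rng(7)
        values, labels = random_hierarchy(rng, n_cols=3)
        dec = nested_decomposition(values, labels)
        for lvl in dec.levels:
            if lvl not in dec.undefined:
                np.testing.assert_allclose(
                    dec.msq[lvl] * dec.dof[lvl], dec.ssq[lvl], rtol=1e-12
                )
        assert sum(dec.dof.values()) == dec.total_dof

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        values, labels = random_hierarchy(rng, n_cols=2)
        a = nested_decomposition(values, labels)
        b = nested_decomposition(3.0 * values, labels)
        for lvl in a.levels:
            np.testing.assert_allclose(b.ssq[lvl], 9.0 * a.ssq[lvl], rtol=1e-10)

    def test_weighted_levels_sum_to_total_ss(self):
        # balanced design: count-weighted SSQs across levels telescope to
        # the total sum of squares about the grand mean
        ds, _, _ = generate_dataset(small_config())
        dec = nested_decomposition(
            ds.absorbance, ds.labels[["lot", "subsample", "replicate"]], weighted=True
        )
        total = sum(dec.ssq[lvl] for lvl in dec.levels)
        np.testing.assert_allclose(total, dec.total_ssq, rtol=1e-8)

    def test_zero_dof_level_reported_not_dropped(self):
        labels = pd.DataFrame({"lot": ["a"] * 4, "subsample": ["s", "s", "t", "t"]})
        with pytest.warns(UserWarning, match="zero degrees of freedom"):
            dec = nested_decomposition(np.arange(4.0), labels)
        assert "lot" in dec.undefined
        assert np.isnan(dec.msq["lot"])
        assert np.isfinite(dec.msq["subsample"])

    def test_uncovered_rows_rejected(self):
        labels = pd.DataFrame({"lot": ["a", "a"]})
        with pytest.raises(ValueError, match="cover"):
            nested_decomposition(np.arange(3.0), labels)

    def test_nonfinite_rows_dropped_with_warning(self):
        labels = pd.DataFrame({"lot": ["a", "a", "b", "b"]})
        values = np.array([1.0, np.nan, 2.0, 4.0])
        with pytest.warns(UserWarning, match="non-finite"):
            dec = nested_decomposition(values, labels)
        assert dec.n_units["scan"] == 3

    def test_ordering_recovered_from_matched_variances(self):
        cfg = small_config(
            variance_components={"lot": 0.05, "subsample": 0.005,
                                 "replicate": 0.002, "scan": 0.0005},
            scatter_slope_sd=0.0, scatter_offset_sd=0.0,
        )
        ds, _, _ = generate_dataset(cfg)
        dec = nested_decomposition(ds.absorbance, ds.labels[["lot", "subsample", "replicate"]])
        water = int(np.argmin(np.abs(ds.axis - 5189.0)))
        assert dec.msq["lot"][water] > dec.msq["subsample"][water] > dec.msq["scan"][water]


class TestPerLot:
    def test_zero_within_lot_variance_gives_zero_msq(self, flat_bundle):
        ds, _, _ = flat_bundle
        for dec in per_lot_decomposition(ds).values():
            for lvl in dec.levels:
                assert np.allclose(dec.ssq[lvl], 0.0)

    def test_subsample_ssq_partitions_across_lots(self, small_bundle):
        ds, _, _ = small_bundle
        global_dec = nested_decomposition(
            ds.absorbance, ds.labels[["lot", "subsample", "replicate"]]
        )
        per_lot = per_lot_decomposition(ds)
        summed = sum(d.ssq["subsample"] for d in per_lot.values())
        np.testing.assert_allclose(summed, global_dec.ssq["subsample"], rtol=1e-10)

    def test_inflated_lot_has_max_water_band_msq(self):
        # inflate lot 3's within-lot water variability tenfold: it must own
        # the largest subsample-level MSQ at the water band
        cfg = small_config(
            bwc_sd_subsample=0.3,
            bwc_lot_sd_scale={"L03": 10.0},
            variance_components={"lot": 0.0, "subsample": 0.0, "replicate": 0.0, "scan": 0.0},
            scatter_slope_sd=0.0, scatter_offset_sd=0.0, additive_noise_sd=0.0,
        )
        ds, _, _ = generate_dataset(cfg)
        per_lot = per_lot_decomposition(ds)
        water = int(np.argmin(np.abs(ds.axis - 5189.0)))
        at_water = {lot: d.msq["subsample"][water] for lot, d in per_lot.items()}
        assert max(at_water, key=at_water.get) == "L03"

    def test_single_subsample_lot_flagged(self):
        cfg = small_config(n_subsamples_per_lot=1)
        ds, _, _ = generate_dataset(cfg)
        for dec in per_lot_decomposition(ds).values():
            assert "subsample" in dec.undefined


class TestNormalize:
    def test_unit_maximum(self, small_bundle):
        ds, _, _ = small_bundle
        dec = nested_decomposition(ds.absorbance, ds.labels[["lot", "subsample", "replicate"]])
        normed = normalize_msq(dec, ["lot", "subsample"])
        for v in normed.values():
            assert np.max(v) == pytest.approx(1.0)

    def test_scale_invariance_and_oracle(self):
        labels = pd.DataFrame({"lot": ["a", "a", "b", "b", "c", "c"]})
        values = np.random.default_rng(1).random((6, 5))
        dec = nested_decomposition(values, labels)
        normed = normalize_msq(dec, ["lot"])
        np.testing.assert_allclose(normed["lot"], dec.msq["lot"] / dec.msq["lot"].max())

    def test_all_zero_vector_left_as_zeros(self):
        labels = pd.DataFrame({"lot": ["a", "a", "b", "b"]})
        dec = nested_decomposition(np.ones((4, 3)), labels)
        with pytest.warns(UserWarning, match="all zero"):
            normed = normalize_msq(dec, ["lot"])
        assert np.allclose(normed["lot"], 0.0)
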