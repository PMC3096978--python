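"""Expression-prep transforms: centring, standardisation, filtering,
probe collapse, HER2 assignment, multi-source merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnegsig import (
    assign_her2_status,
    collapse_probes,
    mean_center_within_source,
    merge_cohorts,
    variance_filter,
    z_transform_within_source,
)
from conftest import make_bundle


class TestMeanCenter:
    def test_single_source_hand_example(self):
        b = make_bundle([[1.0, 2.0, 3.0]])
        out = mean_center_within_source(b)
        np.testing.assert_allclose(out.expression.iloc[0], [-1, 0, 1])

    def test_removes_first_order_batch_offsets(self):
        base = np.array([[1.0, 2.0, 0.5, 1.5]])
        b = make_bundle(
            np.c_[base[:, :2] + 5, base[:, 2:] - 5], sources=["A", "A", "B", "B"]
        )
        out = mean_center_within_source(b)
        for src in ("A", "B"):
            cols = out.source_mask(src)
            assert abs(out.expression[cols].mean(axis=1).iloc[0]) < 1e-9

    def test_idempotent(self, small_cohort):
        b, _ = small_cohort
        once = mean_center_within_source(b)
        twice = mean_center_within_source(once)
        np.testing.assert_allclose(
            once.expression.to_numpy(), twice.expression.to_numpy(), atol=1e-12
        )

    def test_tiny_source_errors(self):
        b = make_bundle([[1.0, 2.0, 3.0]], sources=["A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            mean_center_within_source(b)


class TestZTransform:
    def test_hand_example_sample_sd(self):
        """{1,2,3} standardises to {-1,0,1} under the n-1 SD convention."""
        b = make_bundle([[1.0, 2.0, 3.0]])
        out = z_transform_within_source(b)
        np.testing.assert_allclose(out.expression.iloc[0], [-1, 0, 1])

    def test_constant_feature_flagged_zeroed(self):
        b = make_bundle([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        out = z_transform_within_source(b)
        np.testing.assert_allclose(out.expression.iloc[0], [0, 0, 0])
        rec = out.transforms[-1]
        assert "g0" in rec.params["zero_variance_features"]["A"]

    def test_each_source_standardised_independently(self):
        b = make_bundle(
            [[1.0, 2.0, 3.0, 10.0, 20.0, 30.0]],
            sources=["A"] * 3 + ["B"] * 3,
        )
        out = z_transform_within_source(b)
        for src in ("A", "B"):
            cols = out.source_mask(src)
            vals = out.expression[cols].iloc[0]
            assert vals.mean() == pytest.approx(0, abs=1e-9)
            assert vals.std(ddof=1) == pytest.approx(1, abs=1e-9)


class TestVarianceFilter:
    def test_threshold_semantics_kept(self):
        """10 of 100 samples beyond the twofold bound keeps the feature."""
        x = np.zeros(100)
        x[:10] = 1.2
        b = make_bundle(x.reshape(1, -1) - x.mean())
        # deviations: 10 samples at |1.2 - mean| > 1.0
        _, kept = variance_filter(b)
        assert kept == ["g0"]

    def test_boundary_nine_of_hundred_removed(self):
        x = np.zeros(100)
        x[:9] = 5.0
        b = make_bundle(x.reshape(1, -1))
        _, kept = variance_filter(b)
        assert kept == []

    def test_constant_feature_removed(self):
        b = make_bundle(np.ones((1, 20)))
        _, kept = variance_filter(b)
        assert kept == []

    def test_strict_inequality_on_deviation(self):
        """Deviation exactly equal to the bound does not count."""
        x = np.r_[np.full(5, 1.0), np.full(5, -1.0)]  # all |dev| == 1.0
        b = make_bundle(x.reshape(1, -1))
        _, kept = variance_filter(b, min_fraction=0.1, log2_fold=1.0)
        assert kept == []

    @settings(deadline=None, max_examples=25)
    @given(frac=st.floats(0.05, 0.95), frac2=st.floats(0.05, 0.95))
    def test_monotone_in_min_fraction(self, frac, frac2):
        rng = np.random.default_rng(7)
        b = make_bundle(rng.normal(0, 1.2, size=(30, 40)))
        lo, hi = sorted([frac, frac2])
        _, kept_lo = variance_filter(b, min_fraction=lo)
        _, kept_hi = variance_filter(b, min_fraction=hi)
        assert set(kept_hi) <= set(kept_lo)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            variance_filter(make_bundle(np.empty((0, 5)).reshape(0, 5)))


class TestCollapseProbes:
    def test_multi_probe_average(self):
        b = make_bundle(
            [[0.4, 0.8], [0.6, 0.2], [1.0, 2.0]],
            feature_ids=["p1", "p2", "p3"],
            feature_map={"p1": "GENE1", "p2": "GENE1", "p3": "GENE2"},
        )
        out = collapse_probes(b)
        np.testing.assert_allclose(out.expression.loc["GENE1"], [0.5, 0.5])
        np.testing.assert_allclose(out.expression.loc["GENE2"], [1.0, 2.0])

    def test_single_probe_identity(self):
        b = make_bundle([[1.0, 2.0]], feature_ids=["p1"], feature_map={"p1": "G"})
        out = collapse_probes(b)
        np.testing.assert_allclose(out.expression.loc["G"], [1.0, 2.0])

    def test_unmapped_probe_dropped_and_counted(self):
        b = make_bundle(
            [[1.0, 2.0], [3.0, 4.0]],
            feature_ids=["p1", "px"],
            feature_map={"p1": "G"},
        )
        out = collapse_probes(b)
        assert list(out.expression.index) == ["G"]
        assert out.transforms[-1].params["n_unmapped_dropped"] == 1

    def test_commutes_with_sample_subsetting(self, rng):
        b = make_bundle(
            rng.normal(size=(6, 8)),
            feature_ids=[f"p{i}" for i in range(6)],
            feature_map={f"p{i}": f"G{i % 3}" for i in range(6)},
        )
        sub_then = collapse_probes(b.subset_samples(["s0", "s2", "s5"]))
        then_sub = collapse_probes(b).subset_samples(["s0", "s2", "s5"])
        pd.testing.assert_frame_equal(sub_then.expression, then_sub.expression)

    def test_missing_map_errors(self):
        with pytest.raises(ValueError):
            collapse_probes(make_bundle([[1.0, 2.0]]))


class TestHer2Assignment:
    def test_hand_example(self):
        """ERBB2 {1,2,9} centres to {-3,-2,5}: one positive call."""
        b = make_bundle([[1.0, 2.0, 9.0]], feature_ids=["ERBB2"])
        out = assign_her2_status(b, "ERBB2")
        assert list(out.clinical["her2_status"]) == ["neg", "neg", "pos"]

    def test_boundary_value_is_negative(self):
        b = make_bundle([[2.0, 2.0, 2.0]], feature_ids=["ERBB2"])
        out = assign_her2_status(b, "ERBB2")
        assert (out.clinical["her2_status"] == "neg").all()

    def test_tneg_count_when_all_her2_negative(self):
        b = make_bundle([[2.0, 2.0, 2.0]], feature_ids=["ERBB2"])
        out = assign_her2_status(b, "ERBB2")
        assert out.clinical["tneg"].sum() == 3

    def test_unknown_pr_does_not_block_tneg(self):
        b = make_bundle([[2.0, 2.0, 2.0]], feature_ids=["ERBB2"])
        clin = b.clinical.copy()
        clin["pr_status"] = "unknown"
        out = assign_her2_status(b.with_clinical(clin), "ERBB2")
        assert out.clinical["tneg"].all()

    def test_missing_feature_errors(self):
        with pytest.raises(ValueError):
            assign_her2_status(make_bundle([[1.0, 2.0]]), "ERBB2")


class TestMerge:
    def _shifted_pair(self, rng, delta=3.0):
        base = rng.normal(size=(20, 15))
        a = make_bundle(base)
        b = make_bundle(base + delta)
        bclin = b.clinical.copy()
        bclin["source"] = "B"
        b = b.with_clinical(bclin)
        b.expression.columns = [f"t{i}" for i in range(15)]
        b.clinical.index = b.expression.columns
        return a, b

    @pytest.mark.parametrize("strategy", ["center", "dwd_lite"])
    def test_mean_shift_removed(self, rng, strategy):
        a, b = self._shifted_pair(rng)
        merged = merge_cohorts([a, b], strategy=strategy)
        src = merged.clinical["source"]
        ma = merged.expression.loc[:, src[src == "A"].index].mean(axis=1)
        mb = merged.expression.loc[:, src[src == "B"].index].mean(axis=1)
        np.testing.assert_allclose(ma.to_numpy(), mb.to_numpy(), atol=1e-6)

    def test_dwd_lite_preserves_within_source_geometry(self, rng):
        a, b = self._shifted_pair(rng)
        merged = merge_cohorts([a, b], strategy="dwd_lite")
        src = merged.clinical["source"]
        before = b.expression.to_numpy()
        after = merged.expression.loc[:, src[src == "B"].index].to_numpy()
        d_before = np.linalg.norm(before[:, :1] - before, axis=0)
        d_after = np.linalg.norm(after[:, :1] - after, axis=0)
        np.testing.assert_allclose(d_before, d_after, atol=1e-9)

    def test_single_bundle_identity(self, rng):
        a = make_bundle(rng.normal(size=(5, 6)))
        assert merge_cohorts([a]) is a

    def test_feature_intersection(self, rng):
        frames = []
        for ids, cols in (
            (["A", "B", "C"], "u"),
            (["B", "C", "D"], "v"),
            (["B", "C"], "w"),
        ):
            bb = make_bundle(rng.normal(size=(len(ids), 4)), feature_ids=ids)
            bb.expression.columns = [f"{cols}{i}" for i in range(4)]
            bb.clinical.index = bb.expression.columns
            frames.append(bb)
        merged = merge_cohorts(frames, strategy="center")
        assert sorted(merged.expression.index) == ["B", "C"]

    def test_empty_intersection_errors(self, rng):
        a = make_bundle(rng.normal(size=(2, 4)), feature_ids=["A", "B"])
        b = make_bundle(rng.normal(size=(2, 4)), feature_ids=["C", "D"])
        b.expression.columns = [f"t{i}" for i in range(4)]
        b.clinical.index = b.expression.columns
        with pytest.raises(ValueError, match="intersection"):
            merge_cohorts([a, b])

    def test_center_merge_after_z_is_noop(self, small_cohort):
        b, _ = small_cohort
        parts = [
            z_transform_within_source(b.subset_samples(b.source_mask(s)))
            for s in b.sources
        ]
        merged = merge_cohorts(parts, strategy="center")
        recombined = pd.concat([p.expression for p in parts], axis=1)
        np.testing.assert_allclose(
            merged.expression.to_numpy(),
            recombined[merged.expression.columns].to_numpy(),
            atol=1e-9,
        )


class TestOrderInvariance:
    def test_permuting_samples_permutes_output(self, rng):
        b = make_bundle(rng.normal(size=(10, 12)))
        perm = list(rng.permutation(list(b.expression.columns)))
        out = z_transform_within_source(b)
        out_perm = z_transform_within_source(b.subset_samples(perm))
        pd.testing.assert_frame_equal(
            out.expression[out_perm.expression.columns], out_perm.expression
        )
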