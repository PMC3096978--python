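"""Screening stages: PAM scoring, MC-CV Cox screen, consistency and
holdout filters, candidate bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from tnegsig import (
    MCCVConfig,
    SimulationParams,
    cox_consistency_filter,
    holdout_confirm,
    mccv_screen,
    pam_intersect,
    pam_screen,
    simulate_cohort,
)
from tnegsig.discovery import _blank_records
from tnegsig.prep import (
    mean_center_within_source,
    merge_cohorts,
    z_transform_within_source,
)
from conftest import make_bundle


def _labels(bundle):
    return bundle.clinical["dmfs_event"]


def _z_merged(bundle):
    parts = [
        z_transform_within_source(bundle.subset_samples(bundle.source_mask(s)))
        for s in bundle.sources
    ]
    return merge_cohorts(parts, strategy="center") if len(parts) > 1 else parts[0]


class TestPamScreen:
    def test_identical_class_means_score_zero(self, rng):
        n = 40
        vals = np.vstack([np.r_[np.zeros(20), np.zeros(20)], rng.normal(size=n)])
        b = make_bundle(vals, events=[0] * 20 + [1] * 20,
                        times=np.full(n, 50.0), feature_ids=["flat", "noise"])
        res = pam_screen(b, _labels(b), top_k=1)
        assert res["A"].loc["flat", "score"] == pytest.approx(0.0, abs=1e-12)
        assert not res["A"].loc["flat", "selected"]

    def test_topk_all_features_selects_everything(self, rng):
        b = make_bundle(rng.normal(size=(10, 30)),
                        events=[0] * 15 + [1] * 15, times=np.full(30, 50.0))
        res = pam_screen(b, _labels(b), top_k=10)
        assert res["A"]["selected"].all()

    def test_shifted_feature_ranks_first(self, rng):
        """One feature shifted +2 SD in the event class ranks first in
        every source in >=48/50 replicates."""
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            n_per = 100
            vals = r.normal(size=(1000, 2 * n_per))
            events = np.r_[np.zeros(n_per, int), np.ones(n_per, int)]
            order = r.permutation(2 * n_per)
            vals, events = vals[:, order], events[order]
            vals[0, events == 1] += 2.0
            sources = np.where(np.arange(2 * n_per) < n_per, "A", "B")
            # ensure both classes in both sources via random order
            b = make_bundle(vals, events=list(events),
                            times=np.full(2 * n_per, 60.0), sources=list(sources))
            res = pam_screen(b, _labels(b), top_k=10)
            rank_first = all(
                df["score"].abs().idxmax() == "g0" for df in res.values()
            )
            hits += rank_first
        assert hits >= 48

    def test_missing_class_errors(self, rng):
        b = make_bundle(rng.normal(size=(5, 10)), events=[0] * 10,
                        times=np.full(10, 50.0))
        with pytest.raises(ValueError, match="class"):
            pam_screen(b, _labels(b))


class TestPamIntersect:
    def _frame(self, scores, selected):
        return pd.DataFrame(
            {"score": scores, "raw_score": scores, "selected": selected},
            index=["g0", "g1", "g2"],
        )

    def test_same_sign_kept_opposite_dropped(self):
        a = self._frame([1.0, 1.0, 1.0], [True, True, False])
        b = self._frame([2.0, -1.0, 1.0], [True, True, True])
        assert pam_intersect({"A": a, "B": b}) == ["g0"]

    def test_selected_in_one_source_only_dropped(self):
        a = self._frame([1.0, 0.5, 0.0], [True, False, False])
        b = self._frame([1.0, 0.5, 0.0], [False, True, False])
        assert pam_intersect({"A": a, "B": b}) == []

    def test_requires_two_sources(self):
        with pytest.raises(ValueError):
            pam_intersect({"A": self._frame([1.0, 1, 1], [True] * 3)})


class TestMCCV:
    def test_constant_feature_never_selected(self, rng):
        n = 80
        vals = np.vstack([np.zeros(n), rng.normal(size=n)])
        b = make_bundle(vals, times=rng.exponential(40, n),
                        events=(rng.random(n) < 0.5).astype(int),
                        feature_ids=["const", "noise"])
        res = mccv_screen(b, MCCVConfig(n_iterations=10, seed=0))
        assert not res.loc["const", "mccv_selected"]

    def test_deterministic_and_sample_order_invariant(self, rng):
        n = 60
        b = make_bundle(rng.normal(size=(30, n)), times=rng.exponential(40, n),
                        events=(rng.random(n) < 0.5).astype(int))
        cfg = MCCVConfig(n_iterations=15, seed=7)
        res1 = mccv_screen(b, cfg)
        perm = list(np.random.default_rng(1).permutation(list(b.expression.columns)))
        res2 = mccv_screen(b.subset_samples(perm), cfg)
        pd.testing.assert_frame_equal(res1, res2)

    def test_strong_gene_selected_with_full_consistency(self):
        """A beta=-1 gene at n=200 (~35% events) is selected with
        consistency 1.0."""
        p = SimulationParams(
            n_genes=50, n_prognostic=1, effect_sizes=[-1.0],
            baseline_hazard_rate=0.00465, n_sources=2,
            samples_per_source=[100, 100], seed=4,
        )
        b, _ = simulate_cohort(p)
        res = mccv_screen(_z_merged(b), MCCVConfig(seed=4))
        row = res.loc["G00001"]
        assert row["mccv_selected"] and row["mccv_consistency"] == 1.0

    def test_selection_monotone_in_effect_size(self):
        """P(selected) is non-decreasing in |beta| (checked on a grid)."""
        rates = []
        for beta in (0.0, 0.25, 0.5, 1.0):
            sel = 0
            for seed in range(15):
                p = SimulationParams(
                    n_genes=30, n_prognostic=1, effect_sizes=[-beta] if beta else None,
                    baseline_hazard_rate=0.0046, n_sources=2,
                    samples_per_source=[100, 100], seed=seed,
                )
                if beta == 0.0:
                    p = SimulationParams(
                        n_genes=30, n_prognostic=0, baseline_hazard_rate=0.0046,
                        n_sources=2, samples_per_source=[100, 100], seed=seed,
                    )
                b, _ = simulate_cohort(p)
                res = mccv_screen(_z_merged(b), MCCVConfig(n_iterations=40, seed=seed))
                sel += bool(res.loc["G00001", "mccv_selected"])
            rates.append(sel / 15)
        assert all(b >= a - 0.15 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]

    def test_selected_subset_of_mean_p_threshold(self, rng):
        n = 100
        b = make_bundle(rng.normal(size=(50, n)), times=rng.exponential(40, n),
                        events=(rng.random(n) < 0.4).astype(int))
        cfg = MCCVConfig(n_iterations=20, seed=3)
        res = mccv_screen(b, cfg)
        sel = res[res["mccv_selected"]]
        assert (sel["mccv_mean_p"] < cfg.p_threshold).all()

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            MCCVConfig(p_threshold=1.5)


class TestConsistencyAndHoldout:
    def _records_for(self, bundle, candidates):
        rec = _blank_records(bundle.expression.index, None)
        rec["candidate"] = rec.index.isin(candidates)
        return rec

    def test_single_candidate_always_kept(self, rng):
        n = 120
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.01 * np.exp(-0.8 * x)))
        b = make_bundle(x[None, :], times=np.minimum(T, 80),
                        events=(T <= 80).astype(int), feature_ids=["gA"])
        rec = cox_consistency_filter(self._records_for(b, ["gA"]), b)
        assert rec.loc["gA", "candidate"]
        assert rec.loc["gA", "cox_consistent"]

    def test_collinear_duplicates_trigger_ridge_and_survive(self, rng):
        n = 150
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.01 * np.exp(-0.8 * x)))
        b = make_bundle(np.vstack([x, x]), times=np.minimum(T, 80),
                        events=(T <= 80).astype(int), feature_ids=["gA", "gB"])
        rec = cox_consistency_filter(self._records_for(b, ["gA", "gB"]), b)
        assert rec.loc["gA", "candidate"] and rec.loc["gB", "candidate"]

    def test_confounded_sign_flip_dropped(self, rng):
        """A covariate whose multivariate sign flips (classic
        confounding) is removed."""
        n = 400
        driver = rng.standard_normal(n)
        shadow = 0.9 * driver + 0.45 * rng.standard_normal(n)
        # hazard depends on driver positively and shadow negatively with
        # a weak coefficient: marginally shadow looks hazard-increasing
        T = rng.exponential(1 / (0.01 * np.exp(1.2 * driver - 0.55 * shadow)))
        b = make_bundle(np.vstack([driver, shadow]), times=np.minimum(T, 100),
                        events=(T <= 100).astype(int),
                        feature_ids=["driver", "shadow"])
        rec = cox_consistency_filter(self._records_for(b, ["driver", "shadow"]), b)
        assert rec.loc["driver", "candidate"]
        assert not rec.loc["shadow", "candidate"]

    def test_holdout_sign_flip_rejected(self, rng):
        n = 100
        x = rng.standard_normal(n)
        disc = make_bundle(x[None, :], times=rng.exponential(40, n),
                           events=(rng.random(n) < 0.5).astype(int),
                           feature_ids=["gA"])
        rec = self._records_for(disc, ["gA"])
        rec.loc["gA", "uni_coef"] = -0.5
        y = rng.standard_normal(n)
        T = rng.exponential(1 / (0.01 * np.exp(1.0 * y)))  # positive in holdout
        hold = make_bundle(y[None, :], times=np.minimum(T, 80),
                           events=(T <= 80).astype(int), feature_ids=["gA"])
        out = holdout_confirm(rec, hold)
        assert not out.loc["gA", "final_selected"]

    def test_holdout_confirms_true_gene(self):
        """beta=-1 gene confirmed in >=90% of replicates at holdout n=64."""
        hits = 0
        for seed in range(20):
            p = SimulationParams(
                n_genes=10, n_prognostic=1, effect_sizes=[-1.0],
                baseline_hazard_rate=0.00465, n_sources=2,
                samples_per_source=[135, 64], seed=seed,
            )
            b, _ = simulate_cohort(p)
            disc = b.subset_samples(b.source_mask("S1"))
            hold = mean_center_within_source(b.subset_samples(b.source_mask("S2")))
            rec = self._records_for(disc, ["G00001"])
            rec = cox_consistency_filter(rec, disc)
            out = holdout_confirm(rec, hold)
            hits += bool(out.loc["G00001", "final_selected"])
        assert hits >= 18

    def test_missing_holdout_feature_dropped_with_warning(self, rng):
        n = 60
        disc = make_bundle(rng.normal(size=(1, n)), times=rng.exponential(40, n),
                           events=(rng.random(n) < 0.5).astype(int),
                           feature_ids=["gA"])
        rec = self._records_for(disc, ["gA"])
        rec.loc["gA", "uni_coef"] = -0.5
        hold = make_bundle(rng.normal(size=(1, n)), times=rng.exponential(40, n),
                           events=(rng.random(n) < 0.5).astype(int),
                           feature_ids=["gOther"])
        with pytest.warns(UserWarning, match="absent"):
            out = holdout_confirm(rec, hold)
        assert not out.loc["gA", "final_selected"]

    def test_empty_candidate_list_passthrough(self, rng):
        n = 40
        b = make_bundle(rng.normal(size=(3, n)), times=rng.exponential(40, n),
                        events=(rng.random(n) < 0.5).astype(int))
        rec = self._records_for(b, [])
        out = holdout_confirm(cox_consistency_filter(rec, b), b)
        assert not out["final_selected"].any()


class TestUnionBookkeeping:
    def test_union_sizes(self):
        """Candidate lists of 11 and 7 sharing 4 genes combine to 14."""
        hr = {f"H{i}" for i in range(7)} | {"X1", "X2", "X3", "X4"}
        tn = {f"T{i}" for i in range(3)} | {"X1", "X2", "X3", "X4"}
        assert len(hr) == 11 and len(tn) == 7
        assert len(hr | tn) == 14

    def test_disjoint_and_identical(self):
        assert len({"a", "b", "c"} | {"d", "e"}) == 5
        assert {"a", "b"} | {"a", "b"} == {"a", "b"}
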