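import dataclasses

import numpy as np
import pandas as pd
import pytest

from dualscreen import bayes, fusion, screen, synthdata
from dualscreen.compounds import PhyschemProfile
from dualscreen.screen import FilterPolicy, LibraryEntry, apply_cascade, select_hits


def make_model(weights, threshold, mu_a=5.0, mu_i=0.0, sd=1.0, prior=0.5):
    return bayes.BayesModel(
        n_total=10,
        n_active=5,
        prior=prior,
        feature_stats={},
        weights=weights,
        mu_active=mu_a,
        sigma_active=sd,
        mu_inactive=mu_i,
        sigma_inactive=sd,
        class_threshold=threshold,
    )


GOOD_PROFILE = PhyschemProfile(mw=480, hba=8, hbd=3, rotb=6, psa=120, alogp=3.2)
# both models call feature-1 compounds active; model A's EstPGood at score 5 ≈ 1
MODEL_A = make_model({1: 5.0}, threshold=2.5)
MODEL_B = make_model({1: 4.0, 2: 4.0}, threshold=2.0)


def entry(id="c1", fp=frozenset({1}), profile=GOOD_PROFILE):
    return LibraryEntry(id=id, fingerprint=fp, profile=profile)


class TestCascade:
    def test_compliant_dual_active_passes(self):
        res = apply_cascade([entry()], MODEL_A, MODEL_B)
        assert res.table.loc[0, "survivor"]
        assert res.stage_counts == {
            "input": 1,
            "dual_active": 1,
            "est_p_good": 1,
            "physchem": 1,
        }

    @pytest.mark.parametrize(
        "profile,field",
        [
            (dataclasses.replace(GOOD_PROFILE, mw=520), "mw"),
            (dataclasses.replace(GOOD_PROFILE, hba=11), "hba"),
            (dataclasses.replace(GOOD_PROFILE, hbd=6), "hbd"),
            (dataclasses.replace(GOOD_PROFILE, rotb=11), "rotb"),
            (dataclasses.replace(GOOD_PROFILE, psa=260), "psa"),
            (dataclasses.replace(GOOD_PROFILE, alogp=5.5), "alogp"),
        ],
    )
    def test_property_caps_fail_at_property_stage(self, profile, field):
        res = apply_cascade([entry(profile=profile)], MODEL_A, MODEL_B)
        row = res.table.iloc[0]
        assert row["dual_active"] and row["prob_pass"] and not row["survivor"]

    def test_low_est_p_good_fails_at_probability_stage(self):
        # dual-active by threshold, but score far below model A's active mean
        model_a = make_model({1: 1.0}, threshold=0.5, mu_a=10.0, mu_i=0.0)
        res = apply_cascade([entry()], model_a, MODEL_B)
        row = res.table.iloc[0]
        assert row["dual_active"] and not row["prob_pass"] and not row["survivor"]
        assert row["est_p_good_a"] < 0.05

    def test_single_model_active_fails_dual_stage(self):
        res = apply_cascade([entry(fp=frozenset({2}))], MODEL_A, MODEL_B)
        row = res.table.iloc[0]
        assert not row["active_a"] and row["active_b"] and not row["survivor"]

    def test_missing_profile_fails_closed(self):
        res = apply_cascade([entry(profile=None)], MODEL_A, MODEL_B)
        row = res.table.iloc[0]
        assert row["prob_pass"] and not row["physchem_pass"] and not row["survivor"]

    def test_stage_counts_monotone_non_increasing(self, default_cfg):
        scenario = synthdata.gen_screen_scenario(default_cfg, seed=2)
        ma, mb = bayes.train(scenario.training_a), bayes.train(scenario.training_b)
        res = apply_cascade(scenario.library, ma, mb)
        counts = list(res.stage_counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_relaxing_a_threshold_never_shrinks_survivors(self, default_cfg):
        scenario = synthdata.gen_screen_scenario(default_cfg, seed=2)
        ma, mb = bayes.train(scenario.training_a), bayes.train(scenario.training_b)
        base = apply_cascade(scenario.library, ma, mb).stage_counts["physchem"]
        for relaxed in (
            FilterPolicy(est_p_good_min=0.0),
            FilterPolicy(mw_max=600),
            FilterPolicy(alogp_max=10),
            FilterPolicy(require_dual_active=False),
        ):
            n = apply_cascade(scenario.library, ma, mb, relaxed).stage_counts["physchem"]
            assert n >= base

    def test_merge_results_unions_survivors(self):
        strict = FilterPolicy(mw_max=400)
        relaxed = FilterPolicy(est_p_good_min=0.0, mw_max=600)
        lib = [entry("a", profile=dataclasses.replace(GOOD_PROFILE, mw=550)), entry("b")]
        r1 = apply_cascade(lib, MODEL_A, MODEL_B, strict)
        r2 = apply_cascade(lib, MODEL_A, MODEL_B, relaxed)
        merged = screen.merge_results(r1, r2)
        assert merged.table["survivor"].tolist() == [True, True]


class TestSelectHits:
    def make_result(self, ids):
        table = pd.DataFrame(
            {
                "id": ids,
                "active_a": True,
                "active_b": True,
                "dual_active": True,
                "est_p_good_a": 1.0,
                "est_p_good_b": 1.0,
                "prob_pass": True,
                "physchem_pass": True,
                "survivor": True,
            }
        )
        return screen.ScreenResult(table=table, stage_counts={"input": len(ids)})

    def test_threshold_is_mean_minus_k_sd(self):
        ids = [f"c{i}" for i in range(100)]
        # 99 scores at ~-5 (sd 1) plus one deep outlier
        rng = np.random.default_rng(0)
        scores = dict(zip(ids, np.concatenate([rng.normal(-5, 1, 99), [-12.0]])))
        result = self.make_result(ids)
        hits = select_hits(result, scores, sd_cutoff=3.0)
        assert "c99" in set(hits["id"])
        thr = fusion.score_thresholds(list(scores.values()), [3.0])[3.0]
        assert all(s <= thr for s in hits["fused_score"])

    def test_max_hits_zero_is_empty(self):
        result = self.make_result(["a", "b", "c"])
        hits = select_hits(result, {"a": -9.0, "b": -5.0, "c": -1.0}, max_hits=0)
        assert hits.empty

    def test_empty_survivors_warns_and_returns_empty(self, caplog):
        result = self.make_result(["a"])
        result.table["survivor"] = False
        with caplog.at_level("WARNING"):
            hits = select_hits(result, {"a": -9.0})
        assert hits.empty and "empty survivor set" in caplog.text

    def test_allow_list_restricts_selection(self):
        result = self.make_result(["a", "b", "c", "d"])
        scores = {"a": -9.0, "b": -8.9, "c": -1.0, "d": -1.1}
        hits = select_hits(result, scores, sd_cutoff=0.5, allow_list=["b"])
        assert hits["id"].tolist() == ["b"]

    def test_diversity_pruning_keeps_one_per_cluster(self):
        result = self.make_result(["a", "b", "c", "d"])
        scores = {"a": -9.0, "b": -8.9, "c": -8.8, "d": 0.0}
        fps = {
            "a": frozenset({1, 2, 3}),
            "b": frozenset({1, 2, 3}),
            "c": frozenset({9}),
            "d": frozenset({10}),
        }
        hits = select_hits(
            result, scores, sd_cutoff=0.2, diversity_cutoff=0.6, fingerprints=fps
        )
        assert hits["id"].tolist() == ["a", "c"]


class TestEndToEnd:
    def test_planted_dual_actives_recovered(self, default_cfg):
        scenario = synthdata.gen_screen_scenario(default_cfg, seed=1)
        ma, mb = bayes.train(scenario.training_a), bayes.train(scenario.training_b)
        res = apply_cascade(scenario.library, ma, mb)
        fused = fusion.fuse(scenario.docking_table, fusion.get_scheme("Top1_Top_Top1"))
        hits = select_hits(res, fused, sd_cutoff=2.0)
        recovered = set(hits["id"]) & scenario.dual_active_ids
        assert len(recovered) / len(scenario.dual_active_ids) >= 0.8


class TestLibraryIO:
    def test_roundtrip(self, tmp_path):
        entries = [entry("x"), LibraryEntry("y", frozenset({5, 7}), None)]
        path = tmp_path / "lib.tsv"
        screen.write_library(entries, path)
        back = screen.read_library(path)
        assert [e.id for e in back] == ["x", "y"]
        assert back[0].fingerprint == frozenset({1})
        assert back[0].profile.hba == 8
        assert back[1].profile is None
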