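import numpy as np
import pandas as pd
import pytest

from mobint import (
    ClassifyConfig,
    TrackSet,
    apply_confined_jump_filter,
    apply_duration_filter,
    classify_alpha,
    detect_butterfly_splits,
    downsample_tracks,
    run_classification,
    segment_butterfly,
)

from conftest import make_track


def features_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "parent_id",
            "duration",
            "alpha",
            "r_conf_um",
            "mean_jump_um",
            "motion_class",
            "fit_ok",
        ],
    )


class TestAlphaBands:
    @pytest.mark.parametrize(
        "alpha,expected",
        [
            (0.70, "Confined"),  # boundary inclusive
            (0.3, "Confined"),
            (0.85, "Brownian"),
            (0.999, "Brownian"),
            (1.0, "Directed"),
            (1.8, "Directed"),
        ],
    )
    def test_published_boundaries(self, alpha, expected):
        assert classify_alpha(alpha) == expected

    def test_non_finite_alpha_refused(self):
        with pytest.raises(ValueError):
            classify_alpha(float("nan"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifyConfig(alpha_confined_max=1.2, alpha_directed_min=1.0)


class TestButterflyDetection:
    def test_uniform_steps_no_splits(self):
        t = make_track([(0.05 * k, 0) for k in range(21)])
        assert detect_butterfly_splits(t) == []

    def test_single_outlier_jump_detected(self):
        # 20 steps of 0.05 um plus one 0.5 um jump: mean jump ~0.071,
        # relative cutoff 2.5x mean ~0.18 -> only the big step splits
        pts = [(0.05 * k, 0.0) for k in range(11)]
        x = pts[-1][0] + 0.5
        pts += [(x + 0.05 * k, 0.0) for k in range(10)]
        t = make_track(pts)
        assert detect_butterfly_splits(t) == [10]

    def test_absolute_rule_with_high_threshold_silent(self):
        pts = [(0.05 * k, 0.0) for k in range(11)]
        x = pts[-1][0] + 0.5
        pts += [(x + 0.05 * k, 0.0) for k in range(10)]
        t = make_track(pts)
        cfg = ClassifyConfig(butterfly_rule="absolute", butterfly_threshold=1.0)
        assert detect_butterfly_splits(t, cfg) == []

    def test_additive_sd_rule(self):
        pts = [(0.05 * k, 0.0) for k in range(11)]
        x = pts[-1][0] + 0.5
        pts += [(x + 0.05 * k, 0.0) for k in range(10)]
        t = make_track(pts)
        cfg = ClassifyConfig(butterfly_rule="additive_sd", butterfly_threshold=1.5)
        assert 10 in detect_butterfly_splits(t, cfg)

    def test_short_track_yields_no_splits(self):
        t = make_track([(0, 0), (5, 0), (5.1, 0)])
        assert detect_butterfly_splits(t) == []


class TestSegmentation:
    def test_one_split_partitions_21_points(self):
        t = make_track([(0.01 * k, 0) for k in range(21)])
        segs = segment_butterfly(t, [10])
        assert [s.duration for s in segs] == [11, 10]
        assert segs[0].localizations[-1].frame == 10
        assert segs[1].localizations[0].frame == 11

    def test_no_splits_identity(self):
        t = make_track([(0.01 * k, 0) for k in range(6)])
        assert segment_butterfly(t, []) == [t]

    def test_short_segment_discarded_by_min_duration(self):
        t = make_track([(0.01 * k, 0) for k in range(10)])
        segs = segment_butterfly(t, [2], min_duration=5)
        assert [s.duration for s in segs] == [7]

    def test_invalid_split_rejected(self):
        t = make_track([(0.01 * k, 0) for k in range(5)])
        with pytest.raises(ValueError):
            segment_butterfly(t, [10])


class TestFilters:
    def test_duration_filter_keeps_five_and_longer(self):
        tracks = tuple(
            make_track([(0.01 * k, 0) for k in range(n)], track_id=f"d{n}")
            for n in range(1, 21)
        )
        out = apply_duration_filter(TrackSet(tracks=tracks))
        durations = sorted(t.duration for t in out)
        assert len(out) == 16
        assert durations[0] == 5

    def test_duration_filter_empty_and_idempotent(self):
        empty = apply_duration_filter(TrackSet(tracks=()))
        assert len(empty) == 0
        tracks = (make_track([(0, 0)] * 7, "a"),)
        once = apply_duration_filter(TrackSet(tracks=tracks))
        twice = apply_duration_filter(once)
        assert once.tracks == twice.tracks

    def test_confined_jump_filter_scope(self):
        table = features_table(
            [
                ("a", "", 10, 0.5, 0.05, 0.12, "Confined", True),
                ("b", "", 10, 0.9, 0.30, 0.12, "Brownian", True),
                ("c", "", 10, 0.4, 0.04, 0.05, "Confined", True),
            ]
        )
        out = apply_confined_jump_filter(table)
        assert list(out["track_id"]) == ["b", "c"]
        again = apply_confined_jump_filter(out)
        assert out.equals(again)


class TestDownsampling:
    def test_small_pool_returned_whole(self):
        table = features_table(
            [(f"t{i}", "", 10, 1.0, 0.1, 0.1, "Brownian", True) for i in range(10)]
        )
        reps = downsample_tracks(table, n=20_000, reps=3, seed=1)
        assert all(len(r) == 10 for r in reps)

    def test_budget_exact_when_pool_larger(self):
        table = features_table(
            [(f"t{i}", "", 10, 1.0, 0.1, 0.1, "Brownian", True) for i in range(500)]
        )
        reps = downsample_tracks(table, n=200, reps=3, seed=1)
        assert [len(r) for r in reps] == [200, 200, 200]
        for r in reps:
            assert set(r["track_id"]).issubset(set(table["track_id"]))

    def test_seed_reproducible(self):
        table = features_table(
            [(f"t{i}", "", 10, 1.0, 0.1, 0.1, "Brownian", True) for i in range(100)]
        )
        a = downsample_tracks(table, n=30, reps=3, seed=9)
        b = downsample_tracks(table, n=30, reps=3, seed=9)
        for ra, rb in zip(a, b):
            assert ra.equals(rb)


class TestRunClassification:
    def test_empty_trackset_gives_empty_outputs(self):
        res = run_classification(TrackSet(tracks=()))
        assert res.features.empty
        assert res.stage_log["input_tracks"] == 0

    def test_all_short_tracks_removed_at_stage_one(self):
        tracks = tuple(
            make_track([(0.01 * k, 0) for k in range(3)], f"t{i}") for i in range(4)
        )
        res = run_classification(TrackSet(tracks=tracks))
        assert res.stage_log["after_duration_filter"] == 0
        assert res.features.empty

    def test_pipeline_invariants_on_mixture(self, mixture_run):
        ts, _ = mixture_run
        cfg = ClassifyConfig(downsample_n=150, seed=2)
        res = run_classification(ts, cfg)
        table = res.features
        # classes partition the classified rows
        assert set(table["motion_class"]) <= {"Confined", "Brownian", "Directed"}
        assert (table["duration"] >= 5).all()
        confined = table[table["motion_class"] == "Confined"]
        assert (confined["mean_jump_um"] <= 0.1).all()
        # replicates are size-exact subsets of the classified table
        for rep in res.replicates:
            assert len(rep) == min(150, len(table))
            assert set(rep["track_id"]).issubset(set(table["track_id"]))

    def test_butterfly_parents_excluded_segments_present(self, mixture_run):
        ts, truth = mixture_run
        res = run_classification(ts, ClassifyConfig(downsample_n=50))
        parents = set(res.butterfly_parents)
        assert parents  # the mixture contains switching tracks
        assert not (res.features["track_id"].isin(parents)).any()
        seg_parents = set(res.features.loc[res.features["parent_id"] != "", "parent_id"])
        assert seg_parents <= parents
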