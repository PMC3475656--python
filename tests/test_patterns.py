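"""Clustering, cluster-count selection, event detection and merging."""

import numpy as np
import pandas as pd
import pytest

import spikebifurc as sb
from spikebifurc.ensemble import SpikeTrainEnsemble
from spikebifurc.metrics import DistanceMatrix
from spikebifurc.patterns import (
    Event,
    event_statistics,
    find_events,
    interval_events,
    roc_merge,
)


def block_distance_matrix(sizes, within=0.3, between=6.0, noise=0.1, seed=0):
    """Distance matrix with block structure: tight within, far between."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(len(sizes)), sizes)
    n = g.size
    d = np.where(g[:, None] == g[None, :], within, between) + rng.normal(
        0, noise, (n, n)
    )
    d = np.abs((d + d.T) / 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, q=1.0, trial_ids=np.arange(n))


class TestFCM:
    def test_two_block_recovery(self):
        D = block_distance_matrix([15, 15])
        a = sb.fcm_cluster(D, 2, seed=0)
        labels = a.labels
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[15]
        assert a.memberships.max(axis=1).min() > 0.95

    def test_single_cluster_degenerate(self):
        D = block_distance_matrix([10])
        a = sb.fcm_cluster(D, 1, seed=0)
        assert np.all(a.labels == 0)
        assert np.allclose(a.memberships, 1.0)

    def test_membership_rows_sum_to_one(self):
        D = block_distance_matrix([8, 8, 8], seed=3)
        a = sb.fcm_cluster(D, 3, seed=1)
        assert np.allclose(a.memberships.sum(axis=1), 1.0)
        assert np.array_equal(a.labels, np.argmax(a.memberships, axis=1))

    def test_invalid_cluster_count(self):
        D = block_distance_matrix([4])
        with pytest.raises(ValueError):
            sb.fcm_cluster(D, 5, seed=0)


class TestSelectNClusters:
    def test_three_blobs(self):
        hits = 0
        for seed in range(20):
            D = block_distance_matrix([20, 20, 20], seed=seed)
            hits += sb.select_n_clusters(D, k_max=6, seed=seed) == 3
        assert hits >= 18

    def test_single_gaussian_blob(self):
        # feature columns drawn as one isotropic blob: no cluster structure
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(5.0, 1.0, size=(40, 12))  # trials x features
            D = DistanceMatrix(d=X.T, q=1.0, trial_ids=np.arange(40))
            hits += sb.select_n_clusters(D, k_max=5, seed=seed) == 1
        assert hits >= 8

    def test_identical_trials_degenerate(self):
        d = np.zeros((12, 12))
        D = DistanceMatrix(d=d, q=1.0, trial_ids=np.arange(12))
        assert sb.select_n_clusters(D, k_max=4, seed=0) == 1


class TestIntervalEvents:
    def test_gap_splitting_oracle(self):
        spikes = [(0, 1.0), (1, 1.5), (0, 2.0), (1, 10.0), (0, 10.5)]
        evs = interval_events(spikes, t_isi=3.0)
        assert len(evs) == 2
        assert np.allclose(evs[0].times, [1.0, 1.5, 2.0])
        assert np.allclose(evs[1].times, [10.0, 10.5])

    def test_single_spike_single_event(self):
        evs = interval_events([(0, 5.0)], t_isi=3.0)
        assert len(evs) == 1 and evs[0].times.tolist() == [5.0]

    def test_no_gaps_one_event(self):
        spikes = [(i % 3, float(i)) for i in range(10)]
        evs = interval_events(spikes, t_isi=3.0)
        assert len(evs) == 1 and len(evs[0].spikes) == 10

    def test_gap_exactly_t_isi_does_not_split(self):
        evs = interval_events([(0, 1.0), (1, 4.0)], t_isi=3.0)
        assert len(evs) == 1

    def test_brute_force_gap_scan(self):
        rng = np.random.default_rng(8)
        times = np.sort(rng.uniform(0, 200, 40))
        spikes = [(int(i % 5), float(t)) for i, t in enumerate(times)]
        t_isi = 4.0
        evs = interval_events(spikes, t_isi=t_isi)
        n_expected = 1 + int(np.sum(np.diff(times) > t_isi))
        assert len(evs) == n_expected


class TestROCMerge:
    def test_identical_samples_merged(self):
        a = Event(spikes=[(0, 10.0), (1, 11.0), (2, 12.0)])
        b = Event(spikes=[(3, 10.0), (4, 11.0), (5, 12.0)])
        merged = roc_merge({0: [a], 1: [b]}, t_roc=0.5)
        assert len(merged) == 1
        assert len(merged[0].spikes) == 6
        assert merged[0].patterns == {0, 1}

    def test_disjoint_supports_not_merged(self):
        a = Event(spikes=[(0, 1.0), (1, 2.0), (2, 3.0)])
        b = Event(spikes=[(3, 10.0), (4, 11.0), (5, 12.0)])
        merged = roc_merge({0: [a], 1: [b]}, t_roc=0.5)
        assert len(merged) == 2

    def test_merge_idempotence(self, three_pattern_specs):
        ens, _ = sb.generate_pattern_ensemble(
            three_pattern_specs, 60, duration=400.0, seed=9
        )
        D = sb.vp_distance_matrix(ens, 0.5)
        assign = sb.fcm_cluster(D, 3, seed=0)
        es = find_events(ens, assign, t_isi=3.0, t_roc=0.5)
        again = roc_merge({i: [e] for i, e in enumerate(es.events)}, t_roc=0.5)
        # events already merged: re-merging within distinct "patterns" only
        # merges pairs that are indistinguishable, i.e. nothing changes
        assert len(again) == len(es.events)

    def test_singleton_vs_sample_defined(self):
        a = Event(spikes=[(0, 10.0)])
        b = Event(spikes=[(1, 9.5), (2, 10.5)])
        merged = roc_merge({0: [a], 1: [b]}, t_roc=0.5)
        assert len(merged) == 1  # AUC 0.5 -> d = 0 -> merge


class TestEventStatistics:
    def test_reliability_definition(self):
        e = Event(spikes=[(t, 10.0) for t in range(45)])
        es = sb.EventSet(events=[e], noise_spikes=[], n_trials=50)
        stats = event_statistics(es)
        assert stats.loc[0, "reliability"] == pytest.approx(0.9)

    def test_jitter_and_precision_hand_values(self):
        e = Event(spikes=[(0, 9.0), (1, 10.0), (2, 11.0)])
        es = sb.EventSet(events=[e], noise_spikes=[], n_trials=3)
        stats = event_statistics(es)
        assert stats.loc[0, "jitter"] == pytest.approx(1.0)
        assert stats.loc[0, "precision"] == pytest.approx(1.0)

    def test_single_spike_event_precision_missing(self):
        e1 = Event(spikes=[(0, 9.0), (1, 10.0), (2, 11.0)])
        e2 = Event(spikes=[(0, 50.0)])
        es = sb.EventSet(events=[e1, e2], noise_spikes=[], n_trials=3)
        stats = event_statistics(es)
        assert np.isnan(stats.loc[1, "precision"])
        assert stats.loc[1, "jitter"] == 0.0
        from spikebifurc.patterns import condition_event_averages

        avg = condition_event_averages(stats)
        assert avg["precision"] == pytest.approx(1.0)  # NaN excluded

    def test_empty_event_set_rejected(self):
        es = sb.EventSet(events=[], noise_spikes=[], n_trials=3)
        with pytest.raises(ValueError):
            event_statistics(es)


class TestPatternOccupation:
    def test_single_pattern(self):
        occ = sb.pattern_occupation(np.zeros(10, dtype=int), n_patterns=3)
        row = occ.iloc[0]
        assert row["pattern_0"] == 1.0
        assert row["pattern_1"] == 0.0 and row["pattern_2"] == 0.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 4, size=120)
        conds = np.repeat(np.arange(6), 20)
        occ = sb.pattern_occupation(labels, conds, n_patterns=4)
        sums = occ[[f"pattern_{p}" for p in range(4)]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_designed_occupation_recovered(self):
        specs = [
            sb.PatternSpec([50.0], [1.0], [0.0], occupation=0.6),
            sb.PatternSpec([150.0], [1.0], [0.0], occupation=0.4),
        ]
        n = 100
        _, truth = sb.generate_pattern_ensemble(specs, n, duration=300.0, seed=11)
        occ = sb.pattern_occupation(truth.pattern_labels, n_patterns=2)
        assert abs(occ.iloc[0]["pattern_0"] - 0.6) < 2.576 * np.sqrt(0.24 / n)


class TestSegmentation:
    def test_boundary_placed_in_silent_gap(self):
        rng = np.random.default_rng(12)
        trains = []
        for _ in range(20):
            first = rng.uniform(0, 490, 25)
            second = rng.uniform(530, 1000, 25)
            trains.append(np.sort(np.concatenate([first, second])))
        ens = SpikeTrainEnsemble(trains, duration=1000.0)
        segs = sb.segment_trials(ens, target_len_ms=500.0)
        assert len(segs) == 2
        boundary = segs[0][1]
        assert 490.0 < boundary < 530.0

    def test_uniform_firing_fixed_length_fallback(self):
        rng = np.random.default_rng(13)
        trains = [np.sort(rng.uniform(0, 1000, 60)) for _ in range(20)]
        ens = SpikeTrainEnsemble(trains, duration=1000.0)
        with pytest.warns(UserWarning):
            segs = sb.segment_trials(ens, target_len_ms=500.0)
        assert len(segs) == 2
        assert segs[0][1] == pytest.approx(500.0)

    def test_segments_cover_trial(self):
        rng = np.random.default_rng(14)
        trains = [np.sort(rng.uniform(0, 2000, 30)) for _ in range(10)]
        ens = SpikeTrainEnsemble(trains, duration=2000.0)
        try:
            segs = sb.segment_trials(ens, target_len_ms=500.0)
        except UserWarning:
            pass
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segs = sb.segment_trials(ens, target_len_ms=500.0)
        assert segs[0][0] == 0.0 and segs[-1][1] == 2000.0
        for (a, b), (c, d) in zip(segs, segs[1:]):
            assert b == c


class TestLabelPermutationInvariance:
    def test_occupation_and_events_invariant(self, three_pattern_specs):
        ens, _ = sb.generate_pattern_ensemble(
            three_pattern_specs, 30, duration=400.0, seed=15
        )
        D = sb.vp_distance_matrix(ens, 0.5)
        assign = sb.fcm_cluster(D, 3, seed=0)
        es = find_events(ens, assign, t_isi=3.0, t_roc=0.5)

        perm = np.random.default_rng(16).permutation(ens.n_trials)
        ens_p = ens.subset(perm)
        D_p = sb.vp_distance_matrix(ens_p, 0.5)
        assign_p = sb.fcm_cluster(D_p, 3, seed=0)
        es_p = find_events(ens_p, assign_p, t_isi=3.0, t_roc=0.5)

        assert sorted(np.round(es.mean_times(), 6)) == sorted(
            np.round(es_p.mean_times(), 6)
        )
        occ = np.sort(np.bincount(assign.labels, minlength=3))
        occ_p = np.sort(np.bincount(assign_p.labels, minlength=3))
        assert np.array_equal(occ, occ_p)
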