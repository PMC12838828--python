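"""Microstate segmentation: GFP, clustering, GEV, backfitting, parameters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from somnirl.microstates import (GFPSeries, LabelSequence, backfit,
                                 fit_microstates, gev, gfp, gfp_peaks,
                                 select_n_states, temporal_parameters,
                                 transition_matrix)
from somnirl.synth import StateSpec, make_topographies, simulate_recording


def orthogonal_prototypes(k=4, c=8, seed=0):
    """k mutually orthogonal, zero-mean (average-referenced) unit maps.

    Random vectors are centered *before* orthogonalization so the result
    stays inside the zero-sum subspace and exactly orthogonal."""
    x = np.random.default_rng(seed).standard_normal((c, k))
    x -= x.mean(axis=0, keepdims=True)
    q = np.linalg.qr(x)[0]
    return q.T


def maps_from_prototypes(protos, n=200, seed=1):
    rng = np.random.default_rng(seed)
    ks = rng.integers(len(protos), size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    scales = rng.uniform(0.5, 2.0, size=n)
    return protos[ks] * (signs * scales)[:, None], ks


class TestGFP:
    def test_identical_channels_give_zero(self):
        assert np.allclose(gfp(np.ones((4, 10))).values, 0)

    def test_two_channel_hand_case(self):
        series = gfp(np.array([[1.0], [-1.0]]))
        assert series.values[0] == pytest.approx(1.0)

    @given(st.floats(-10, 10).filter(lambda c: abs(c) > 1e-6))
    def test_absolute_homogeneity(self, c):
        x = np.random.default_rng(3).standard_normal((5, 20))
        assert np.allclose(gfp(c * x).values, abs(c) * gfp(x).values)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(np.ones((1, 10)))


class TestGFPPeaks:
    def test_monotone_series_has_no_peaks(self):
        series = GFPSeries(np.arange(10.0), fs=100.0)
        assert gfp_peaks(series).size == 0

    def test_alternating_series(self):
        series = GFPSeries(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), fs=100.0)
        assert list(gfp_peaks(series)) == [1, 3]

    def test_close_peaks_thinned_keeping_larger(self):
        v = np.zeros(200)
        v[100], v[105] = 1.0, 2.0  # 5 ms apart at 1 kHz
        series = GFPSeries(v, fs=1000.0)
        assert list(gfp_peaks(series, min_separation_ms=10.0)) == [105]


class TestModifiedKMeans:
    def test_perfect_fit_on_orthogonal_prototypes(self):
        protos = orthogonal_prototypes()
        maps, _ = maps_from_prototypes(protos)
        model = fit_microstates(maps, 4, seed=0)
        assert model.gev == pytest.approx(1.0, abs=1e-9)
        corr = np.abs(model.prototypes @ protos.T)
        assert np.all(np.sort(corr.max(axis=1)) > 0.999)
        # one recovered prototype per true prototype
        assert sorted(corr.argmax(axis=1)) == [0, 1, 2, 3]

    def test_polarity_invariance(self):
        protos = orthogonal_prototypes()
        maps, _ = maps_from_prototypes(protos)
        a = fit_microstates(maps, 4, seed=0)
        b = fit_microstates(-maps, 4, seed=0)
        assert a.gev == pytest.approx(b.gev, abs=1e-12)
        assert np.allclose(np.abs(a.prototypes @ b.prototypes.T).max(axis=1),
                           1.0, atol=1e-9)

    def test_one_map_per_cluster_explains_everything(self, rng):
        maps = rng.standard_normal((5, 8))
        model = fit_microstates(maps, 5, seed=0)
        assert model.gev == pytest.approx(1.0, abs=1e-9)


class TestGEV:
    def test_perfect_assignment(self):
        protos = orthogonal_prototypes()
        maps, _ = maps_from_prototypes(protos)
        model = fit_microstates(maps, 4, seed=0)
        g = np.abs(np.random.default_rng(0).standard_normal(len(maps))) + 0.1
        assert gev(model, maps, g) == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_loop(self, rng):
        maps = rng.standard_normal((40, 8))
        g = np.abs(rng.standard_normal(40)) + 0.1
        model = fit_microstates(maps, 3, seed=1)
        # independent brute-force evaluation
        total = 0.0
        protos = model.prototypes
        for i in range(len(maps)):
            m = maps[i] - maps[i].mean()
            m = m / np.linalg.norm(m)
            best = max((m @ p) ** 2 for p in protos)
            total += g[i] ** 2 * best
        expected = total / np.sum(g**2)
        assert gev(model, maps, g) == pytest.approx(expected, abs=1e-12)

    def test_zero_gfp_rejected(self, rng):
        maps = rng.standard_normal((10, 8))
        model = fit_microstates(maps, 2, seed=0)
        with pytest.raises(ValueError, match="GFP"):
            gev(model, maps, np.zeros(10))


class TestSelectNStates:
    def test_single_k_equals_direct_fit(self, rng):
        maps = rng.standard_normal((60, 8))
        direct = fit_microstates(maps, 4, seed=2)
        selected = select_n_states(maps, k_range=[4], seed=2)
        assert selected.gev == pytest.approx(direct.gev)

    def test_four_prototype_data_reaches_gev_099_at_k4(self):
        protos = orthogonal_prototypes()
        maps, _ = maps_from_prototypes(protos, n=300)
        maps += 0.01 * np.random.default_rng(5).standard_normal(maps.shape)
        model = select_n_states(maps, k_range=[4], seed=0)
        assert model.gev >= 0.99

    def test_selected_model_maximizes_gev_over_range(self, rng):
        maps = rng.standard_normal((80, 8))
        model = select_n_states(maps, k_range=[2, 3, 4], seed=1)
        assert model.gev == max(model.gev_table.values())
        assert set(model.gev_table) == {2, 3, 4}

    def test_invalid_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_n_states(rng.standard_normal((8, 6)), k_range=[12])


class TestBackfit:
    def test_pure_prototype_columns(self):
        protos = orthogonal_prototypes()
        maps, _ = maps_from_prototypes(protos)
        model = fit_microstates(maps, 4, seed=0)
        k = 2
        epoch = np.outer(model.prototypes[k], np.array([1.0, -2.0, 0.5, -1.0]))
        labels = backfit(model, epoch, fs=100.0, min_duration_ms=0.0)
        assert np.all(labels.labels == k)

    def test_zero_min_duration_is_pure_argmax(self, rng):
        protos = orthogonal_prototypes()
        maps, _ = maps_from_prototypes(protos)
        model = fit_microstates(maps, 4, seed=0)
        epoch = rng.standard_normal((8, 50))
        labels = backfit(model, epoch, fs=100.0, min_duration_ms=0.0)
        x = epoch - epoch.mean(axis=0)
        x = x / np.linalg.norm(x, axis=0)
        expected = np.argmax((x.T @ model.prototypes.T) ** 2, axis=1)
        assert np.array_equal(labels.labels, expected)

    def test_short_segment_absorbed(self):
        protos = orthogonal_prototypes()
        maps, _ = maps_from_prototypes(protos)
        model = fit_microstates(maps, 4, seed=0)
        fs = 1000.0
        a, b = model.prototypes[0], model.prototypes[1]
        epoch = np.concatenate([np.tile(a, (50, 1)), np.tile(b, (4, 1)),
                                np.tile(a, (50, 1))]).T
        labels = backfit(model, epoch, fs=fs, min_duration_ms=10.0)
        assert np.all(labels.labels == labels.labels[0])


class TestTemporalParameters:
    def test_worked_example(self):
        labels = LabelSequence(np.array([0, 0, 1, 1, 1, 0]), fs=100.0,
                               n_states=2)
        series = GFPSeries(np.ones(6), fs=100.0)
        feats = temporal_parameters(labels, series)
        assert feats.coverage == pytest.approx([0.5, 0.5])
        assert feats.duration_ms == pytest.approx([15.0, 30.0])
        assert feats.occurrence_per_s[0] == pytest.approx(2 / 0.06)
        assert feats.occurrence_per_s[1] == pytest.approx(1 / 0.06)

    def test_single_state_sequence(self):
        labels = LabelSequence(np.zeros(100, dtype=int), fs=100.0, n_states=1)
        series = GFPSeries(np.full(100, 2.0), fs=100.0)
        feats = temporal_parameters(labels, series)
        assert feats.coverage[0] == pytest.approx(1.0)
        assert feats.duration_ms[0] == pytest.approx(1000.0)
        assert feats.occurrence_per_s[0] == pytest.approx(1.0)
        assert feats.mean_gfp[0] == pytest.approx(2.0)

    @given(st.integers(0, 2**31 - 1))
    def test_coverage_partitions_and_rows_stochastic(self, seed):
        r = np.random.default_rng(seed)
        labels = LabelSequence(r.integers(3, size=60), fs=100.0, n_states=3)
        series = GFPSeries(np.abs(r.standard_normal(60)), fs=100.0)
        feats = temporal_parameters(labels, series)
        assert feats.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        present = [k for k in range(3) if k not in feats.absent_states]
        rows = feats.transition.sum(axis=1)
        for k in present:
            if feats.transition[k].sum() > 0:
                assert rows[k] == pytest.approx(1.0, abs=1e-9)

    def test_absent_state_zeroed_not_error(self):
        labels = LabelSequence(np.zeros(10, dtype=int), fs=100.0, n_states=3)
        series = GFPSeries(np.ones(10), fs=100.0)
        feats = temporal_parameters(labels, series)
        assert feats.absent_states == (1, 2)
        assert feats.coverage[1] == 0.0


class TestTransitionMatrix:
    def test_alternating_sequence(self):
        T = transition_matrix(np.array([0, 0, 1, 0, 0, 1, 1]), n_states=2)
        assert T[0, 1] == pytest.approx(1.0)
        assert T[1, 0] == pytest.approx(1.0)

    def test_matches_bruteforce_bigrams(self, rng):
        labels = rng.integers(4, size=200)
        T = transition_matrix(labels, n_states=4)
        # independent bigram counting over deduplicated runs
        runs = [labels[0]]
        for v in labels[1:]:
            if v != runs[-1]:
                runs.append(v)
        counts = np.zeros((4, 4))
        for a, b in zip(runs[:-1], runs[1:]):
            counts[a, b] += 1
        expected = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1)
        assert np.allclose(T, expected)
        assert np.all(np.diag(T) == 0)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="segments"):
            transition_matrix(np.zeros(10, dtype=int), n_states=2)


class TestEndToEndInvariance:
    def test_sign_flip_leaves_everything_unchanged(self, topo4):
        spec = StateSpec("EC", {"delta": 2.0, "alpha": 1.0}, noise_sd=0.05,
                         complexity_knob=0.2)
        rec = simulate_recording(topo4, spec, 6.0, 250.0, seed=2)
        series = gfp(rec.data, rec.fs)
        peaks = gfp_peaks(series, 10.0)
        pos = fit_microstates(rec.data[:, peaks].T, 4, seed=0,
                              gfp_at_maps=series.values[peaks])
        neg = fit_microstates(-rec.data[:, peaks].T, 4, seed=0,
                              gfp_at_maps=series.values[peaks])
        assert pos.gev == pytest.approx(neg.gev, abs=1e-12)
        lab_pos = backfit(pos, rec.data, rec.fs)
        lab_neg = backfit(neg, -rec.data, rec.fs)
        assert np.array_equal(lab_pos.labels, lab_neg.labels)
        fp = temporal_parameters(lab_pos, series)
        fn = temporal_parameters(lab_neg, series)
        assert np.allclose(fp.duration_ms, fn.duration_ms)
        assert np.allclose(fp.transition, fn.transition)

    def test_parameter_recovery_on_low_noise_data(self, topo4):
        spec = StateSpec("EC", {"delta": 2.0, "alpha": 1.0}, noise_sd=0.02,
                         complexity_knob=0.2)
        rec = simulate_recording(topo4, spec, 30.0, 250.0, seed=3)
        series = gfp(rec.data, rec.fs)
        peaks = gfp_peaks(series, 10.0)
        model = fit_microstates(rec.data[:, peaks].T, 4, seed=0,
                                gfp_at_maps=series.values[peaks])
        labels = backfit(model, rec.data, rec.fs, min_duration_ms=30.0)
        perm = np.argmax(np.abs(model.prototypes @ topo4.maps.T), axis=1)
        match = (perm[labels.labels] == rec.true_label_sequence).mean()
        assert match >= 0.95
        feats = temporal_parameters(labels, series)
        mean_duration = feats.duration_ms.mean()
        assert abs(mean_duration - 90.0) / 90.0 < 0.15
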