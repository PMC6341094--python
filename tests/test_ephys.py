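"""Spike detection, metric extraction, refractory-constrained sorting,
waveform typing and rank statistics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_score

from raphemap import ephys
from raphemap.ephys import (EphysError, SpikeCluster, SpikeEvents,
                            classify_waveform_types, compute_spike_metrics,
                            detect_spikes, dunn_posthoc, kruskal_dunn,
                            sort_spikes)
from raphemap.synthgen import GroundTruth, simulate_probe
from raphemap.synthgen.probe import ProbeTruth, UnitSpec, make_template

FS = 25_000.0


def _trace_with_templates(times_s, template, n_samples, noise_sd, rng):
    x = rng.normal(0.0, noise_sd, n_samples) if noise_sd else np.zeros(n_samples)
    trough_offset = int(np.argmin(template))
    for t in times_s:
        i = int(round(t * FS)) - trough_offset
        x[i:i + template.size] += template
    return x


class TestDetectSpikes:
    def test_flat_trace_yields_no_events(self):
        assert len(detect_spikes(np.zeros(int(FS)), FS)) == 0

    def test_injected_templates_recovered_within_one_sample(self, rng):
        template = make_template(FS, trough_uv=100.0)
        true = np.arange(0.05, 10.0, 0.1)           # 100 spikes
        x = _trace_with_templates(true, template, int(10 * FS), 2.0, rng)
        events = detect_spikes(x, FS, k_sd=5.0)
        assert len(events) == true.size
        np.testing.assert_allclose(events.times, true, atol=1.5 / FS)

    def test_false_positive_rate_matches_gaussian_exceedance(self, rng):
        n = int(60 * FS)
        x = rng.normal(0.0, 1.0, n)
        events = detect_spikes(x, FS, k_sd=5.0, noise_estimator="std")
        p = stats.norm.cdf(-5.0)
        expected = (n - 1) * p * (1 - p)
        assert abs(len(events) - expected) <= 3 * np.sqrt(expected) + 1e-9

    def test_count_monotone_in_threshold(self, rng):
        template = make_template(FS, trough_uv=30.0)
        x = _trace_with_templates(np.arange(0.05, 5.0, 0.05), template,
                                  int(5 * FS), 3.0, rng)
        counts = [len(detect_spikes(x, FS, k_sd=k)) for k in (3, 4, 5, 6, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_short_trace_rejected(self):
        with pytest.raises(EphysError, match="shorter"):
            detect_spikes(np.zeros(10), FS)


def _two_population_events(rng, n_per=150):
    """Events drawn from two distinct waveform templates plus noise."""
    t_a = make_template(FS, trough_uv=100.0, tp_delay_ms=0.4, peak_frac=0.3)
    t_b = make_template(FS, trough_uv=60.0, tp_delay_ms=0.9, peak_frac=0.7)
    snippets, labels = [], []
    for lab, tmpl in enumerate((t_a, t_b)):
        for _ in range(n_per):
            snippets.append(tmpl + rng.normal(0, 1.5, tmpl.size))
            labels.append(lab)
    order = rng.permutation(len(snippets))
    snippets = np.asarray(snippets)[order]
    labels = np.asarray(labels)[order]
    events = SpikeEvents(times=np.sort(rng.uniform(0, 300, len(labels))),
                         snippets=snippets, fs=FS, pre=10)
    return events, labels


class TestSpikeMetrics:
    def test_zscore_contract(self, rng):
        events, _ = _two_population_events(rng)
        z = compute_spike_metrics(events)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-9)

    def test_two_populations_separate_in_metric_space(self, rng):
        events, labels = _two_population_events(rng)
        z = compute_spike_metrics(events)
        assert silhouette_score(z.to_numpy(), labels) > 0.5

    def test_constant_metric_dropped_with_warning(self, caplog):
        # identical snippets except trough depth: width metrics constant
        base = make_template(FS, trough_uv=50.0)
        snippets = np.stack([base * (1 + 0.3 * k) for k in range(20)])
        events = SpikeEvents(times=np.linspace(0, 1, 20), snippets=snippets,
                             fs=FS, pre=10)
        with caplog.at_level("WARNING", logger="raphemap.ephys"):
            z = compute_spike_metrics(events)
        assert "dropping constant spike metric" in caplog.text
        assert "peak_trough_ratio" not in z.columns   # scale-invariant metric
        assert "trough_amp" in z.columns

    def test_too_few_events_rejected(self):
        ev = SpikeEvents(times=np.array([0.1]), snippets=np.zeros((1, 40)),
                         fs=FS, pre=10)
        with pytest.raises(EphysError, match="at least 2"):
            compute_spike_metrics(ev)


def _poisson_train(rng, rate, duration, refractory=0.003):
    times = np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def _two_unit_metrics(rng, n_a=200, n_b=200, separation=6.0, spread=0.5):
    za = rng.normal(0.0, spread, size=(n_a, 3))
    zb = rng.normal(0.0, spread, size=(n_b, 3)) + separation / np.sqrt(3)
    ta = _poisson_train(rng, 5.0, 60.0)[:n_a]
    tb = _poisson_train(rng, 5.0, 60.0)[:n_b] + 0.0007  # interleaved
    metrics = np.vstack([za[:ta.size], zb[:tb.size]])
    times = np.concatenate([ta, tb])
    labels = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])
    return metrics, times, labels


class TestSortSpikes:
    def test_two_separated_units_fully_recovered(self, rng):
        metrics, times, labels = _two_unit_metrics(rng)
        clusters = sort_spikes(metrics, times, seed=0)
        included = [c for c in clusters if c.included]
        assert len(included) == 2
        for cl in included:
            true = labels[cl.member_ids]
            assert np.all(true == true[0])          # zero cross-assignments

    def test_overclustered_single_unit_merges_to_one(self, rng):
        metrics = rng.normal(0.0, 0.4, size=(300, 3))   # all within d_merge
        times = np.sort(rng.uniform(0, 600, 300))        # sparse: no ISI < 2 ms
        while np.any(np.diff(times) < 0.002):
            times = np.sort(rng.uniform(0, 600, 300))
        clusters = sort_spikes(metrics, times, seed=0)
        assert len(clusters) == 1
        assert clusters[0].n_spikes == 300

    def test_refractory_violations_block_merge(self, rng):
        # two metric-identical units firing 0.5 ms apart: merging would
        # put ~half of all ISIs below 2 ms
        n = 200
        ta = np.arange(n) * 0.05
        tb = ta + 0.0005
        metrics = np.vstack([rng.normal(0, 0.3, (n, 3)),
                             rng.normal(0, 0.3, (n, 3))])
        times = np.concatenate([ta, tb])
        clusters = sort_spikes(metrics, times, seed=0, overcluster_k=2)
        assert len(clusters) == 2

    def test_no_returned_cluster_exceeds_violation_ceiling(self, rng):
        for seed in range(5):
            metrics, times, _ = _two_unit_metrics(
                np.random.default_rng(seed))
            clusters = sort_spikes(metrics, times, seed=seed)
            for cl in clusters:
                if cl.included:
                    assert cl.violation_fraction(2.0) <= 0.005

    def test_inclusion_threshold_is_strict(self, rng):
        metrics = rng.normal(0, 0.3, size=(50, 3))
        times = np.sort(rng.uniform(0, 100, 50))
        clusters = sort_spikes(metrics, times, seed=0, overcluster_k=1)
        assert len(clusters) == 1 and not clusters[0].included  # 50 is not > 50

    def test_empty_input_and_bad_dmerge(self):
        assert sort_spikes(np.empty((0, 3)), np.empty(0)) == []
        with pytest.raises(EphysError, match="d_merge"):
            sort_spikes(np.zeros((5, 3)), np.zeros(5), d_merge=0.0)


class TestWaveformTypes:
    def _clusters(self, centroids):
        return [SpikeCluster(member_ids=np.arange(3), times=np.arange(3.0),
                             centroid=np.asarray(c, dtype=float), stereo=False,
                             included=True)
                for c in centroids]

    def test_single_type_contains_everything(self):
        clusters = self._clusters([[0, 0], [1, 1], [2, 2]])
        types = classify_waveform_types(clusters, k_types=1)
        assert len(types) == 1
        assert sorted(types[0].cluster_indices) == [0, 1, 2]

    def test_three_families_recovered(self, rng):
        families = np.repeat(np.arange(3), 5)
        centroids = [rng.normal(0, 0.2, 2) + [0, 10 * f] for f in families]
        types = classify_waveform_types(self._clusters(centroids), k_types=3,
                                        seed=0)
        labels = np.empty(len(families), dtype=int)
        for t in types:
            for i in t.cluster_indices:
                labels[i] = t.label
        assert adjusted_rand_score(families, labels) == 1.0

    def test_deterministic_given_seed(self, rng):
        centroids = rng.normal(size=(6, 2))
        clusters = self._clusters(centroids)
        a = classify_waveform_types(clusters, 2, seed=3)
        b = classify_waveform_types(clusters, 2, seed=3)
        assert [t.cluster_indices for t in a] == [t.cluster_indices for t in b]

    def test_bad_k_rejected(self):
        clusters = self._clusters([[0, 0], [1, 1]])
        with pytest.raises(EphysError):
            classify_waveform_types(clusters, 0)
        with pytest.raises(EphysError):
            classify_waveform_types(clusters, 3)


class TestRankStatistics:
    def test_kruskal_wallis_hand_example(self):
        """Three groups with no ties: H = 7.2 by direct rank-sum
        computation (rank sums 6, 15, 24 over N = 9)."""
        out = kruskal_dunn([np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
                            np.array([7.0, 8, 9])])
        assert out["H"] == pytest.approx(7.2, abs=1e-12)

    def test_identical_groups_give_h_zero(self, mini_protocol):
        clusters = [SpikeCluster(member_ids=np.arange(1),
                                 times=np.array([100.0]),
                                 centroid=np.full(2, float(i)),
                                 stereo=False, included=True)
                    for i in range(6)]
        types = classify_waveform_types(clusters, 2, seed=0)
        out = ephys.spike_response_stats(types, clusters, mini_protocol)
        assert out["H"] == 0.0 and out["p"] == 1.0

    def test_dunn_adjusted_never_below_raw(self, rng):
        groups = [rng.normal(loc, 1, 15) for loc in (0, 0.5, 2.0)]
        table = dunn_posthoc(groups)
        assert (table["p_adj"] >= table["p"] - 1e-12).all()

    def test_shifted_group_detected_in_power_simulation(self):
        detected = 0
        n_sims = 200
        for s in range(n_sims):
            r = np.random.default_rng(s)
            groups = [r.normal(0, 1, 20), r.normal(0, 1, 20),
                      r.normal(3, 1, 20)]
            if kruskal_dunn(groups)["p"] < 0.01:
                detected += 1
        assert detected / n_sims >= 0.95

    def test_empty_group_rejected(self):
        with pytest.raises(EphysError, match="empty"):
            kruskal_dunn([np.array([1.0]), np.array([])])


class TestEndToEnd:
    def test_train_locked_unit_rate_increases_during_stim(self, mini_protocol):
        """A unit driven at the stimulation blocks produces an included
        cluster whose stimulation-epoch rate exceeds baseline."""
        probe = ProbeTruth(units=(
            UnitSpec(rate_hz=3.0, stim_gain=4.0, trough_uv=120.0,
                     channels=(0, 1)),),
            delta_amp_uv=30.0, noise_uv=6.0)
        truth = GroundTruth(block_amplitudes=(2.0,) * 3, burst_rate_hz=0.05)
        rec = simulate_probe(mini_protocol, truth, seed=2, probe=probe,
                             n_channels=2, duration=mini_protocol.duration)
        clusters, _ = ephys.sort_recording(rec, seed=0)
        included = [c for c in clusters if c.included]
        assert included
        big = max(included, key=lambda c: c.n_spikes)
        stim = mini_protocol.stim_mask(big.times)
        base = mini_protocol.baseline_mask(big.times)
        stim_t = 3 * mini_protocol.block_duration
        base_t = mini_protocol.duration - stim_t
        assert stim.sum() / stim_t > base.sum() / base_t
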