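"""Extracellular spike detection, sorting and waveform typing.

The sorting procedure follows a refractory-constrained agglomeration
scheme: spikes are detected as threshold crossings at ``k`` standard
deviations of the noise (robust MAD estimator, since the raw standard
deviation is inflated by the spikes themselves), per-event waveform
metrics are z-scored, events are deliberately over-clustered with
k-means and clusters are then progressively merged while the
intercluster (centroid) distance stays below 2.5 in z-space *and* the
merged train's refractory-period (2 ms) violation fraction stays below
a small ceiling.  Stereotrode events (seen on two adjacent channels)
are sorted first, residual single-channel events second.  Clusters with
more than 50 spikes are flagged as included for downstream analysis.

Stimulus-locked spiking differences across waveform types are tested
with a Kruskal-Wallis test followed by Dunn's post-hoc comparisons
(Holm-adjusted).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .protocol import StimProtocol

logger = logging.getLogger(__name__)

#: snippet window in samples (1.6 ms at 25 kHz); also the detection dead time
DEFAULT_WINDOW = 40
#: default per-event metric set
DEFAULT_METRICS = ("trough_amp", "peak_amp", "trough_to_peak_ms",
                   "half_width_ms", "peak_trough_ratio")
#: stereotrode coincidence window for two-channel association, ms
STEREO_WINDOW_MS = 0.4


class EphysError(ValueError):
    """Raised for invalid electrophysiology-analysis configurations."""


# ---------------------------------------------------------------------------
# detection


@dataclass
class SpikeEvents:
    """Detected spike events with aligned waveform snippets.

    ``snippets`` is ``n_events x window`` with the trough at sample
    ``pre``.  ``channels`` holds, per event, the tuple of channels the
    event was observed on (length 2 for stereotrode events).
    """

    times: np.ndarray
    snippets: np.ndarray
    fs: float
    pre: int
    channels: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channels:
            self.channels = [(0,)] * len(self.times)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def stereo(self) -> np.ndarray:
        return np.asarray([len(c) == 2 for c in self.channels])


def noise_sd(trace: np.ndarray, estimator: str = "mad") -> float:
    """Noise standard deviation: robust ``median(|x|)/0.6745`` by default
    (spikes inflate the raw standard deviation), or plain ``std``."""
    x = np.asarray(trace, dtype=float)
    if estimator == "mad":
        return float(np.median(np.abs(x)) / 0.6745)
    if estimator == "std":
        return float(x.std())
    raise EphysError(f"unknown noise estimator {estimator!r}")


def detect_spikes(trace: np.ndarray, fs: float, k_sd: float = 5.0,
                  noise_estimator: str = "mad",
                  window: int = DEFAULT_WINDOW,
                  channel: int = 0) -> SpikeEvents:
    """Detect negative-going threshold crossings with dead time.

    One event is produced per crossing of ``-k_sd * sigma``; after each
    detection the following snippet window is dead to prevent
    double-counting multiphasic waveforms.  Snippets are aligned on the
    trough; events whose snippet would cross the trace edge are
    dropped.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise EphysError("detect_spikes expects a single-channel trace")
    if x.size < window:
        raise EphysError("trace shorter than one snippet window")
    if fs <= 0:
        raise EphysError("fs must be positive")
    thr = k_sd * noise_sd(x, noise_estimator)
    crossings = np.flatnonzero((x[1:] < -thr) & (x[:-1] >= -thr)) + 1
    pre = window // 4
    post = window - pre
    # trough alignment on a lightly smoothed copy to suppress one-sample
    # jitter from noise riding on the waveform
    smooth = np.convolve(x, np.ones(3) / 3.0, mode="same") if x.size >= 3 else x
    times, snippets = [], []
    last = -window
    for idx in crossings:
        if idx < last + window:
            continue
        seg_end = min(idx + post, x.size)
        trough = idx + int(np.argmin(smooth[idx:seg_end]))
        last = trough
        if trough - pre < 0 or trough + post > x.size:
            continue
        times.append(trough / fs)
        snippets.append(x[trough - pre:trough + post])
    snippets = np.asarray(snippets) if snippets else np.empty((0, window))
    return SpikeEvents(times=np.asarray(times), snippets=snippets, fs=fs,
                       pre=pre, channels=[(channel,)] * len(times))


def associate_stereo(per_channel: list[SpikeEvents],
                     coincidence_ms: float = STEREO_WINDOW_MS) -> SpikeEvents:
    """Merge per-channel detections; coincident events on adjacent
    channels become single two-channel (stereotrode) events.

    The snippet of a stereo event is taken from the channel with the
    deeper trough.
    """
    if not per_channel:
        raise EphysError("no channels given")
    fs = per_channel[0].fs
    pre = per_channel[0].pre
    records = []  # (time, channel, snippet)
    for ev in per_channel:
        for i in range(len(ev)):
            records.append((ev.times[i], ev.channels[i][0], ev.snippets[i]))
    records.sort(key=lambda r: r[0])
    tol = coincidence_ms / 1e3
    times, snippets, channels = [], [], []
    used = [False] * len(records)
    for i, (t, c, s) in enumerate(records):
        if used[i]:
            continue
        partner = None
        for j in range(i + 1, len(records)):
            tj, cj, sj = records[j]
            if tj - t > tol:
                break
            if not used[j] and abs(cj - c) == 1:
                partner = j
                break
        if partner is not None:
            tj, cj, sj = records[partner]
            used[partner] = True
            deeper = s if s[pre] <= sj[pre] else sj
            times.append(min(t, tj))
            snippets.append(deeper)
            channels.append(tuple(sorted((c, cj))))
        else:
            times.append(t)
            snippets.append(s)
            channels.append((c,))
        used[i] = True
    snippets = np.asarray(snippets) if snippets else np.empty((0, pre * 4))
    return SpikeEvents(times=np.asarray(times), snippets=snippets, fs=fs,
                       pre=pre, channels=channels)


# ---------------------------------------------------------------------------
# metrics


def _event_metrics(snippet: np.ndarray, pre: int, fs: float) -> dict[str, float]:
    trough_amp = -snippet[pre]
    post = snippet[pre:]
    peak_idx = int(np.argmax(post))
    peak_amp = float(post[peak_idx])
    below = snippet < -trough_amp / 2
    i = pre
    while i > 0 and below[i - 1]:
        i -= 1
    j = pre
    while j < snippet.size - 1 and below[j + 1]:
        j += 1
    half_width = (j - i + 1) / fs * 1e3
    return {
        "trough_amp": float(trough_amp),
        "peak_amp": peak_amp,
        "trough_to_peak_ms": peak_idx / fs * 1e3,
        "half_width_ms": half_width,
        "peak_trough_ratio": peak_amp / trough_amp if trough_amp else np.nan,
    }


def compute_spike_metrics(events: SpikeEvents,
                          metrics: tuple[str, ...] = DEFAULT_METRICS
                          ) -> pd.DataFrame:
    """Per-event waveform metrics, z-scored per column.

    Columns with zero variance are dropped with a logged warning (their
    z-score is undefined).
    """
    if len(events) < 2:
        raise EphysError("need at least 2 events to z-score metrics")
    rows = [_event_metrics(events.snippets[i], events.pre, events.fs)
            for i in range(len(events))]
    frame = pd.DataFrame(rows)[list(metrics)]
    out = {}
    for col in frame.columns:
        sd = frame[col].std(ddof=0)
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(frame[col].mean())):
            logger.warning("dropping constant spike metric %r (z undefined)", col)
            continue
        out[col] = (frame[col] - frame[col].mean()) / sd
    if not out:
        raise EphysError("all spike metrics are constant")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# sorting


@dataclass
class SpikeCluster:
    """A sorted cluster of spike events."""

    member_ids: np.ndarray          # indices into the event table
    times: np.ndarray               # sorted spike times, s
    centroid: np.ndarray            # mean z-scored metrics
    stereo: bool
    included: bool = False
    mean_waveform: np.ndarray | None = None

    @property
    def n_spikes(self) -> int:
        return len(self.member_ids)

    @property
    def isi(self) -> np.ndarray:
        """Inter-spike intervals, sorted ascending."""
        return np.sort(np.diff(self.times))

    def violation_fraction(self, refractory_ms: float = 2.0) -> float:
        if self.times.size < 2:
            return 0.0
        return float(np.mean(np.diff(self.times) < refractory_ms / 1e3))


def _merged_violations(t1: np.ndarray, t2: np.ndarray,
                       refractory_ms: float) -> float:
    merged = np.sort(np.concatenate([t1, t2]))
    if merged.size < 2:
        return 0.0
    return float(np.mean(np.diff(merged) < refractory_ms / 1e3))


def _sort_partition(metrics: np.ndarray, times: np.ndarray, ids: np.ndarray,
                    stereo: bool, d_merge: float, refractory_ms: float,
                    violation_ceiling: float, seed: int,
                    overcluster_k: int | None) -> list[SpikeCluster]:
    n = len(ids)
    if n == 0:
        return []
    k = overcluster_k if overcluster_k is not None else min(20, max(1, n // 50))
    k = min(k, n)
    if k > 1:
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(metrics)
    else:
        labels = np.zeros(n, dtype=int)
    clusters: dict[int, dict] = {}
    for c in range(k):
        sel = labels == c
        if sel.any():
            clusters[c] = {"ids": ids[sel], "times": np.sort(times[sel]),
                           "metrics": metrics[sel]}
    next_id = k
    blocked: set[frozenset] = set()
    while len(clusters) > 1:
        keys = list(clusters)
        cents = {c: clusters[c]["metrics"].mean(axis=0) for c in keys}
        pairs = sorted(
            ((np.linalg.norm(cents[a] - cents[b]), a, b)
             for a, b in itertools.combinations(keys, 2)
             if frozenset((a, b)) not in blocked),
            key=lambda p: p[0])
        merged = False
        for dist, a, b in pairs:
            if dist >= d_merge:
                break
            if _merged_violations(clusters[a]["times"], clusters[b]["times"],
                                  refractory_ms) <= violation_ceiling:
                clusters[next_id] = {
                    "ids": np.concatenate([clusters[a]["ids"], clusters[b]["ids"]]),
                    "times": np.sort(np.concatenate([clusters[a]["times"],
                                                     clusters[b]["times"]])),
                    "metrics": np.vstack([clusters[a]["metrics"],
                                          clusters[b]["metrics"]]),
                }
                del clusters[a], clusters[b]
                blocked = {p for p in blocked if not p & {a, b}}
                next_id += 1
                merged = True
                break
            blocked.add(frozenset((a, b)))
        if not merged:
            break
    return [SpikeCluster(member_ids=c["ids"], times=c["times"],
                         centroid=c["metrics"].mean(axis=0), stereo=stereo)
            for c in clusters.values()]


def sort_spikes(metrics: pd.DataFrame | np.ndarray, times: np.ndarray,
                stereo_mask: np.ndarray | None = None, d_merge: float = 2.5,
                refractory_ms: float = 2.0, min_spikes: int = 50,
                violation_ceiling: float = 0.005, seed: int = 0,
                snippets: np.ndarray | None = None,
                overcluster_k: int | None = None) -> list[SpikeCluster]:
    """Over-cluster and agglomerate spikes under the refractory constraint.

    Stereotrode events are sorted first, residual single-channel events
    second.  The closest centroid pair is merged while its distance is
    below ``d_merge`` and the merged inter-spike-interval violation
    fraction (ISIs shorter than ``refractory_ms``) does not exceed
    ``violation_ceiling``.  Clusters with strictly more than
    ``min_spikes`` events are flagged ``included``.
    """
    if d_merge <= 0:
        raise EphysError("d_merge must be positive")
    X = metrics.to_numpy() if isinstance(metrics, pd.DataFrame) else np.asarray(metrics)
    times = np.asarray(times, dtype=float)
    if X.shape[0] == 0:
        return []
    if X.shape[0] != times.size:
        raise EphysError("metrics and times disagree on the number of events")
    if stereo_mask is None:
        stereo_mask = np.zeros(times.size, dtype=bool)
    stereo_mask = np.asarray(stereo_mask, dtype=bool)
    ids = np.arange(times.size)
    clusters: list[SpikeCluster] = []
    for stereo in (True, False):
        sel = stereo_mask == stereo
        clusters.extend(_sort_partition(
            X[sel], times[sel], ids[sel], stereo, d_merge, refractory_ms,
            violation_ceiling, seed, overcluster_k))
    for cl in clusters:
        cl.included = cl.n_spikes > min_spikes
        if snippets is not None:
            cl.mean_waveform = snippets[cl.member_ids].mean(axis=0)
    return clusters


# ---------------------------------------------------------------------------
# waveform typing and response statistics


@dataclass
class WaveformType:
    label: int
    cluster_indices: list[int]
    mean_metrics: np.ndarray


def classify_waveform_types(clusters: list[SpikeCluster], k_types: int,
                            seed: int = 0, n_init: int = 10
                            ) -> list[WaveformType]:
    """Group clusters into waveform types by k-means on cluster-mean
    metrics; deterministic given the seed."""
    if k_types < 1 or k_types > len(clusters):
        raise EphysError(f"k_types must be in [1, {len(clusters)}]")
    cents = np.vstack([c.centroid for c in clusters])
    if k_types == 1:
        labels = np.zeros(len(clusters), dtype=int)
    else:
        labels = KMeans(n_clusters=k_types, random_state=seed,
                        n_init=n_init).fit_predict(cents)
    return [WaveformType(label=t,
                         cluster_indices=[i for i, l in enumerate(labels) if l == t],
                         mean_metrics=cents[labels == t].mean(axis=0))
            for t in range(k_types)]


def dunn_posthoc(groups: list[np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values, multiplicity-adjusted across pairs.
    """
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))
    offsets = np.cumsum([0] + [g.size for g in groups])
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean()
                  for i in range(len(groups))]
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append({"group_a": i, "group_b": j, "z": z,
                     "p": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method=adjust)[1]
    return out


def spiking_probabilities(clusters: list[SpikeCluster], protocol: StimProtocol,
                          mode: str = "train",
                          window_ms: float = 10.0) -> np.ndarray:
    """Spikes-per-pulse probability per cluster within post-pulse windows."""
    pulses = protocol.pulse_times(mode)
    w = window_ms / 1e3
    probs = []
    for cl in clusters:
        idx_lo = np.searchsorted(cl.times, pulses)
        idx_hi = np.searchsorted(cl.times, pulses + w)
        probs.append((idx_hi - idx_lo).sum() / pulses.size)
    return np.asarray(probs)


def spike_response_stats(types: list[WaveformType],
                         clusters: list[SpikeCluster],
                         protocol: StimProtocol, mode: str = "train",
                         window_ms: float = 10.0) -> dict:
    """Kruskal-Wallis H (tie-corrected) across waveform types on
    per-cluster spiking probabilities, with Dunn's post-hoc table."""
    if len(types) < 2:
        raise EphysError("need at least 2 waveform types")
    probs = spiking_probabilities(clusters, protocol, mode, window_ms)
    groups = [probs[t.cluster_indices] for t in types]
    if any(g.size == 0 for g in groups):
        raise EphysError("every waveform type must contain at least one cluster")
    if np.ptp(np.concatenate(groups)) == 0:
        # identical values everywhere: H = 0 by definition, p = 1
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    return {"H": float(h), "p": float(p), "dunn": dunn_posthoc(groups)}


def kruskal_dunn(groups: list[np.ndarray]) -> dict:
    """Kruskal-Wallis plus Dunn's post-hoc on raw per-group samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise EphysError("empty group")
    h, p = stats.kruskal(*groups)
    return {"H": float(h), "p": float(p), "dunn": dunn_posthoc(groups)}


# ---------------------------------------------------------------------------
# high-level pipeline over a recording


def sort_recording(rec, k_sd: float = 5.0, d_merge: float = 2.5,
                   refractory_ms: float = 2.0, min_spikes: int = 50,
                   seed: int = 0) -> tuple[list[SpikeCluster], SpikeEvents]:
    """Detect, associate and sort spikes across all channels of a
    synthetic or loaded probe recording."""
    from .lfp import preprocess_traces

    per_channel = []
    for c in range(rec.traces.shape[0]):
        mua = preprocess_traces(rec.traces[c], rec.fs).mua
        per_channel.append(detect_spikes(mua, rec.fs, k_sd=k_sd, channel=c))
    events = associate_stereo(per_channel)
    if len(events) < 2:
        return [], events
    metrics = compute_spike_metrics(events)
    clusters = sort_spikes(metrics, events.times, stereo_mask=events.stereo,
                           d_merge=d_merge, refractory_ms=refractory_ms,
                           min_spikes=min_spikes, seed=seed,
                           snippets=events.snippets)
    return clusters, events
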