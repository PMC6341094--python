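"""Synthetic multichannel extracellular recordings.

Emulates the phenomenology the electrophysiology stages analyse: spike
trains from template units inserted into band-limited noise, a
delta-band oscillation whose amplitude is suppressed during (lagged)
stimulation epochs, inhomogeneous-Poisson network bursts with a reduced
rate in the same epochs, and an optional gamma component.  Ground-truth
spike, unit and burst times are returned alongside the raw traces.

A lightweight LFP-rate generator (:func:`simulate_site_lfp`) produces
the same delta phenomenology directly at the down-sampled LFP rate for
the electro-vascular coupling presets, where the 25 kHz raw trace is
not needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ..protocol import StimProtocol
from .cohort import GeneratorError, GroundTruth


def make_template(fs: float, trough_uv: float = 80.0,
                  trough_width_ms: float = 0.3,
                  peak_frac: float = 0.4,
                  peak_width_ms: float = 0.6,
                  tp_delay_ms: float = 0.5) -> np.ndarray:
    """Biphasic extracellular spike template (negative trough, later
    positive peak), sampled at ``fs``; ~1.6 ms support."""
    t = (np.arange(int(round(1.6e-3 * fs))) - int(round(0.4e-3 * fs))) / fs * 1e3
    trough = -trough_uv * np.exp(-0.5 * (t / trough_width_ms) ** 2)
    peak = peak_frac * trough_uv * np.exp(-0.5 * ((t - tp_delay_ms) / peak_width_ms) ** 2)
    return trough + peak


@dataclass(frozen=True)
class UnitSpec:
    """One ground-truth unit: firing statistics and waveform shape."""

    rate_hz: float = 4.0
    stim_gain: float = 1.0          # multiplicative rate factor during stimulation
    trough_uv: float = 80.0
    tp_delay_ms: float = 0.5
    peak_frac: float = 0.4
    channels: tuple[int, ...] = (0,)  # 2 channels -> stereotrode unit


@dataclass(frozen=True)
class ProbeTruth:
    """Waveform/oscillation layer of the ground truth (epoch factors and
    the power lag live on :class:`GroundTruth`)."""

    units: tuple[UnitSpec, ...] = (
        UnitSpec(rate_hz=4.0, trough_uv=90.0, tp_delay_ms=0.45, peak_frac=0.35,
                 channels=(0, 1)),
        UnitSpec(rate_hz=3.0, trough_uv=70.0, tp_delay_ms=0.8, peak_frac=0.55,
                 channels=(2,)),
    )
    delta_amp_uv: float = 100.0
    delta_freq_hz: float = 2.0
    gamma_amp_uv: float = 10.0
    gamma_freq_hz: float = 40.0
    noise_uv: float = 8.0
    refractory_ms: float = 2.5


@dataclass
class ProbeRecording:
    """Raw traces plus complete ground truth for one recording site."""

    traces: np.ndarray              # channels x samples, microvolts
    fs: float
    site: str
    unit_times: dict[str, np.ndarray]
    unit_channels: dict[str, tuple[int, ...]]
    templates: dict[str, np.ndarray]
    burst_times: np.ndarray
    protocol: StimProtocol

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.fs


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration: float,
                   stim_windows: list[tuple[float, float]],
                   stim_factor: float, refractory_s: float = 0.0) -> np.ndarray:
    """Inhomogeneous Poisson times by thinning a homogeneous process."""
    peak = rate_hz * max(1.0, stim_factor)
    if peak <= 0:
        return np.empty(0)
    n = rng.poisson(peak * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    in_stim = np.zeros(times.size, dtype=bool)
    for a, b in stim_windows:
        in_stim |= (times >= a) & (times < b)
    local = np.where(in_stim, rate_hz * stim_factor, rate_hz)
    keep = rng.uniform(0.0, peak, size=times.size) < local
    times = times[keep]
    if refractory_s > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory_s:
                kept.append(t)
        times = np.asarray(kept)
    return times


def simulate_spike_times(protocol: StimProtocol, truth: GroundTruth,
                         probe: ProbeTruth, rng: np.random.Generator,
                         duration: float) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Ground-truth unit spike times and network-burst times.

    Unit rates are modulated during the (unshifted) stimulation epochs
    by each unit's ``stim_gain``; burst rates are reduced by the burst
    suppression factor during epochs shifted by the LFP power lag.
    """
    stim = [(on, on + protocol.block_duration)
            for on in protocol.block_onsets if on < duration]
    unit_times = {}
    for i, unit in enumerate(probe.units):
        unit_times[f"unit{i + 1}"] = _poisson_times(
            rng, unit.rate_hz, duration, stim, unit.stim_gain,
            refractory_s=probe.refractory_ms / 1e3)
    if not 0.0 < truth.burst_suppression <= 1.0:
        raise GeneratorError("burst suppression factor must be in (0, 1]")
    lagged = [(a + truth.lfp_power_lag_s, b + truth.lfp_power_lag_s) for a, b in stim]
    # no refractory on bursts: dead-time thinning would prune the denser
    # baseline epochs harder and distort the epoch rate ratio
    burst_times = _poisson_times(rng, truth.burst_rate_hz, duration, lagged,
                                 truth.burst_suppression)
    return unit_times, burst_times


def _delta_envelope(t: np.ndarray, protocol: StimProtocol,
                    truth: GroundTruth) -> np.ndarray:
    """Suppression envelope: drops to the suppression factor during
    stimulation epochs shifted by the configured power lag."""
    env = np.ones(t.size)
    lag = truth.lfp_power_lag_s
    for onset in protocol.block_onsets:
        env[(t >= onset + lag) & (t < onset + protocol.block_duration + lag)] = \
            truth.delta_suppression
    return env


def simulate_probe(protocol: StimProtocol, truth: GroundTruth, seed: int,
                   probe: ProbeTruth | None = None, n_channels: int = 4,
                   fs_raw: float = 25_000.0, duration: float | None = None,
                   site: str = "S1") -> ProbeRecording:
    """Generate a multichannel raw recording with ground truth.

    ``duration`` defaults to the protocol's scan length; shorter values
    are convenient for tests (blocks beyond the duration are dropped).
    """
    probe = probe or ProbeTruth()
    if not 0.0 < truth.delta_suppression <= 1.0:
        raise GeneratorError("delta suppression factor must be in (0, 1]")
    highest = max(probe.gamma_freq_hz, probe.delta_freq_hz, 3000.0)
    if fs_raw <= 2 * highest:
        raise GeneratorError(f"fs_raw must exceed twice the highest synthesised "
                             f"frequency ({highest:g} Hz)")
    if duration is None:
        duration = protocol.duration
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(duration * fs_raw))
    t = np.arange(n) / fs_raw

    traces = rng.normal(0.0, probe.noise_uv, size=(n_channels, n))

    # common delta oscillation, amplitude-suppressed with lag during stim
    env = _delta_envelope(t, protocol, truth)
    phase = rng.uniform(0, 2 * np.pi)
    delta = probe.delta_amp_uv * env * np.sin(2 * np.pi * probe.delta_freq_hz * t + phase)
    gamma = probe.gamma_amp_uv * np.sin(2 * np.pi * probe.gamma_freq_hz * t
                                        + rng.uniform(0, 2 * np.pi))
    traces += delta + gamma

    unit_times, burst_times = simulate_spike_times(protocol, truth, probe, rng,
                                                   duration)
    templates = {}
    unit_channels = {}
    for i, unit in enumerate(probe.units):
        name = f"unit{i + 1}"
        tmpl = make_template(fs_raw, trough_uv=unit.trough_uv,
                             tp_delay_ms=unit.tp_delay_ms,
                             peak_frac=unit.peak_frac)
        templates[name] = tmpl
        chans = tuple(c for c in unit.channels if c < n_channels)
        unit_channels[name] = chans
        for st in unit_times[name]:
            idx = int(round(st * fs_raw))
            stop = min(idx + tmpl.size, n)
            for c in chans:
                traces[c, idx:stop] += tmpl[: stop - idx]

    # network bursts: brief volleys of unit spikes on every channel
    for bt in burst_times:
        n_spk = rng.poisson(4) + 2
        jitter = rng.uniform(0.0, 0.08, size=n_spk)
        for dt_j in jitter:
            idx = int(round((bt + dt_j) * fs_raw))
            tmpl = templates["unit1"]
            stop = min(idx + tmpl.size, n)
            if idx < n:
                ch = rng.integers(0, n_channels)
                traces[ch, idx:stop] += 0.8 * tmpl[: stop - idx]

    unit_times = {k: v[v < duration] for k, v in unit_times.items()}
    return ProbeRecording(traces=traces.astype(np.float32), fs=fs_raw, site=site,
                          unit_times=unit_times, unit_channels=unit_channels,
                          templates=templates, burst_times=burst_times,
                          protocol=protocol)


def simulate_site_lfp(protocol: StimProtocol, truth: GroundTruth,
                      rng: np.random.Generator, fs: float = 3125.0,
                      delta_freq_hz: float = 2.0, delta_amp_uv: float = 100.0,
                      noise_uv: float = 20.0, am_depth: float = 0.2):
    """Delta-dominated LFP directly at the down-sampled rate.

    Adds a slow (~0.1 Hz low-passed) random amplitude modulation on top
    of the stimulation-locked suppression envelope so that the band
    power carries trial-to-trial variability.  Returns an
    :class:`raphemap.lfp.LfpTrace`.
    """
    from ..lfp import LfpTrace

    n = int(round(protocol.duration * fs))
    t = np.arange(n) / fs
    env = _delta_envelope(t, protocol, truth)
    if am_depth > 0:
        slow = rng.normal(0.0, 1.0, size=n)
        sos = sps.butter(2, 0.1, btype="low", fs=fs, output="sos")
        slow = sps.sosfiltfilt(sos, slow)
        slow /= max(np.abs(slow).max(), 1e-12)
        env = env * (1.0 + am_depth * slow)
    osc = delta_amp_uv * env * np.sin(2 * np.pi * delta_freq_hz * t
                                      + rng.uniform(0, 2 * np.pi))
    samples = osc + rng.normal(0.0, noise_uv, size=n)
    return LfpTrace(samples=samples, fs=fs, channel=0,
                    provenance=["synthetic delta-band site LFP"])
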