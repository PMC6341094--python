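"""Synthetic CBV/BOLD cohort generator.

Generates raw ROI-by-time hemodynamic signals with known ground truth,
mimicking an intravascular-contrast (iron oxide) acquisition: a CBV
*increase* produces a raw signal *decrease*, and the contrast agent
clears slowly, producing a multiplicative drift.  The preprocessing
stage's detrend / percent-change / sign-inversion chain is therefore
exercised rather than bypassed.

Raw model per ROI::

    raw(t) = B * (1 + drift * t) * (1 - r(t)) + noise(t)

where ``r(t)`` is the signed fractional CBV response, built as a
per-block amplitude schedule applied to peak-normalised boxcar (x) HRF
regressors (the same regressors the GLM fits), ``drift`` encodes
contrast-agent clearance and the noise is Gaussian per volume (AR(1)
optionally).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..hrf import GammaHRF, block_regressors
from ..protocol import StimProtocol
from . import atlas


class GeneratorError(ValueError):
    """Raised for inconsistent generator configurations."""


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side ground truth for one experimental configuration.

    Parameters
    ----------
    block_amplitudes
        Response magnitude per stimulation block, percent CBV change.
        Length must equal the protocol's number of blocks.
    roi_signs
        CBV response direction per ROI: ``+1`` for DRN-like ROIs (CBV
        increase) and ``-1`` for projection-like ROIs (CBV decrease).
    roi_gains
        Per-ROI multiplicative gain on the amplitude schedule.
    hrf
        The hemodynamic kernel shared with the fitting stage.
    drift_pct_per_min
        Contrast-agent clearance slope, percent of baseline per minute.
    noise_sd_pct
        Per-volume Gaussian noise standard deviation, percent of baseline.
    ar1
        Optional AR(1) coefficient of the noise (0 = white).
    coupling_targets
        Target Pearson r between HRF-convolved electrophysiological
        regressors and CBV, keyed by signal kind (delta/gamma/mua).
    r2_targets
        Structure-function variance-explained targets per atlas map.
    lfp_power_lag_s
        Latency of LFP power changes relative to stimulation onsets.
    delta_suppression
        Multiplicative delta-oscillation amplitude factor during
        (lagged) stimulation epochs, in (0, 1].
    burst_rate_hz / burst_suppression
        Baseline network-burst rate and its multiplicative factor
        during (lagged) stimulation epochs.
    """

    block_amplitudes: tuple[float, ...] = (2.0,) * 6
    roi_signs: dict[str, int] = field(default_factory=dict)
    roi_gains: dict[str, float] = field(default_factory=dict)
    hrf: GammaHRF = field(default_factory=GammaHRF)
    drift_pct_per_min: float = 0.5
    noise_sd_pct: float = 0.3
    ar1: float = 0.0
    coupling_targets: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.75, "gamma": 0.24, "mua": -0.1})
    r2_targets: dict[str, float] = field(
        default_factory=lambda: {"5-HT1F": 0.526, "5-HT2A": 0.212,
                                 "5-HT2C": 0.308, "5-HT1A": 0.0, "5-HT1B": 0.0})
    lfp_power_lag_s: float = 5.0
    delta_suppression: float = 0.5
    burst_rate_hz: float = 0.5
    burst_suppression: float = 0.5

    def __post_init__(self) -> None:
        for kind, r in self.coupling_targets.items():
            if abs(r) > 1:
                raise GeneratorError(f"coupling target |r| > 1 for {kind!r}")
        for name, r2 in self.r2_targets.items():
            if not 0.0 <= r2 <= 1.0:
                raise GeneratorError(f"r2 target outside [0, 1] for {name!r}")
        if not 0.0 < self.delta_suppression <= 1.0:
            raise GeneratorError("delta_suppression must be in (0, 1]")
        object.__setattr__(self, "block_amplitudes",
                           tuple(float(a) for a in self.block_amplitudes))

    def sign(self, roi: str) -> int:
        if roi in self.roi_signs:
            return self.roi_signs[roi]
        return +1 if roi == atlas.DRN else -1

    def gain(self, roi: str) -> float:
        return self.roi_gains.get(roi, 1.0)


@dataclass
class Scan:
    """One synthetic scan: raw ROI x time signals plus its ground truth."""

    raw: pd.DataFrame                       # volumes x ROIs, raw signal units
    protocol: StimProtocol
    amplitudes: pd.DataFrame                # blocks x ROIs, signed % CBV truth
    laser_on: bool = True


@dataclass
class Subject:
    subject_id: str
    sex: str
    condition: str
    scans: list[Scan]


@dataclass
class SyntheticCohort:
    """A cohort of subjects, each with one session of exactly 3 scans."""

    subjects: list[Subject]
    protocol: StimProtocol
    truth: GroundTruth

    def __post_init__(self) -> None:
        for sub in self.subjects:
            if len(sub.scans) != 3:
                raise GeneratorError("every session must contain exactly 3 scans")


_BASELINE_LEVEL = 1000.0  # arbitrary raw scanner units


def _scan_amplitude_scale(condition: str, scan_index: int, roi: str) -> float:
    """Condition-dependent amplitude scaling, per ROI and scan.

    ``restraint`` blunts every ROI in every scan by 0.5; ``fluoxetine``
    enhances the post-injection scans (indices 1 and 2) by 1.5 in
    prefrontal/cingulate, amygdala and striatal ROIs only.
    """
    if condition == "restraint":
        return 0.5
    if condition == "fluoxetine" and scan_index >= 1 and roi in atlas.FLUOXETINE_ROIS:
        return 1.5
    return 1.0


def simulate_scan(protocol: StimProtocol, truth: GroundTruth,
                  rng: np.random.Generator, rois: list[str],
                  condition: str = "control", scan_index: int = 0) -> Scan:
    """Generate one raw scan for the given ROIs."""
    if len(truth.block_amplitudes) != protocol.n_blocks:
        raise GeneratorError(
            f"amplitude schedule length {len(truth.block_amplitudes)} does not "
            f"match protocol with {protocol.n_blocks} blocks")
    regs = block_regressors(protocol, truth.hrf, per_block=True)  # vol x blocks
    t_min = protocol.frame_times / 60.0
    drift = 1.0 + truth.drift_pct_per_min / 100.0 * t_min

    raw = np.empty((protocol.n_volumes, len(rois)))
    amps = np.empty((protocol.n_blocks, len(rois)))
    base_sched = np.asarray(truth.block_amplitudes)
    for j, roi in enumerate(rois):
        scale = _scan_amplitude_scale(condition, scan_index, roi)
        sched = truth.sign(roi) * truth.gain(roi) * scale * base_sched
        amps[:, j] = sched
        response = regs @ (sched / 100.0)
        noise = rng.normal(0.0, truth.noise_sd_pct / 100.0 * _BASELINE_LEVEL,
                           size=protocol.n_volumes)
        if truth.ar1:
            for i in range(1, noise.size):
                noise[i] += truth.ar1 * noise[i - 1]
        raw[:, j] = _BASELINE_LEVEL * drift * (1.0 - response) + noise

    raw_df = pd.DataFrame(raw, columns=rois)
    amp_df = pd.DataFrame(amps, columns=rois,
                          index=[f"block{i + 1}" for i in range(protocol.n_blocks)])
    return Scan(raw=raw_df, protocol=protocol, amplitudes=amp_df)


def simulate_cbv_cohort(protocol: StimProtocol, truth: GroundTruth,
                        n_subjects: int, seed: int,
                        condition: str = "control",
                        rois: list[str] | None = None) -> SyntheticCohort:
    """Generate a cohort of ``n_subjects``, each with 3 scans.

    All randomness flows from a single :class:`numpy.random.SeedSequence`
    spawned per subject and scan; identical arguments give bit-identical
    output.
    """
    if condition not in ("control", "restraint", "fluoxetine"):
        raise GeneratorError(f"unknown condition {condition!r}")
    if rois is None:
        rois = atlas.default_atlas()
    root = np.random.SeedSequence(seed)
    subjects = []
    for s, sub_seq in enumerate(root.spawn(n_subjects)):
        scans = [
            simulate_scan(protocol, truth, np.random.default_rng(scan_seq),
                          rois, condition=condition, scan_index=k)
            for k, scan_seq in enumerate(sub_seq.spawn(3))
        ]
        subjects.append(Subject(
            subject_id=f"sub-{s + 1:02d}",
            sex="F" if s % 2 == 0 else "M",
            condition=condition,
            scans=scans,
        ))
    return SyntheticCohort(subjects=subjects, protocol=protocol, truth=truth)
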