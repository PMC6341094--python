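"""Photostimulation block design and the fMRI sampling grid.

A single :class:`StimProtocol` object is shared by every stage of the
pipeline: the synthetic-data generator uses it to place block responses,
the GLM builds its regressors from it, the LFP/ephys stages use it to
define stimulation versus baseline epochs.

Two standard protocols are provided.  The *short* protocol delivers six
20 s, 20 Hz light trains separated by 40 s OFF periods within a 12 min
scan sampled every 2 s (360 volumes); each 20 s block therefore spans
exactly 10 volumes.  The *long* protocol stretches the OFF period to
160 s within a 24 min scan (720 volumes).  Both include a 60 s lead-in
baseline before the first block so that percent-change normalisation has
at least 30 baseline volumes to work with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ProtocolError(ValueError):
    """Raised for invalid or unknown stimulation protocol configurations."""


@dataclass(frozen=True)
class StimProtocol:
    """Block-design photostimulation schedule on an fMRI sampling grid.

    Parameters
    ----------
    block_onsets
        Stimulation train onsets in seconds, strictly increasing.
    block_duration
        Duration of each ON block in seconds.  Must be an integer
        multiple of ``volume_interval``.
    inter_onset
        Onset-to-onset spacing in seconds (ON + OFF).
    pulse_rate
        Light-pulse rate within a block, Hz.
    pulse_width_ms
        Individual pulse width, milliseconds.
    volume_interval
        fMRI volume spacing (effective TR), seconds.
    n_volumes
        Number of volumes in the scan.
    """

    block_onsets: tuple[float, ...]
    block_duration: float
    inter_onset: float
    pulse_rate: float = 20.0
    pulse_width_ms: float = 5.0
    volume_interval: float = 2.0
    n_volumes: int = 360

    def __post_init__(self) -> None:
        onsets = np.asarray(self.block_onsets, dtype=float)
        if onsets.size == 0:
            raise ProtocolError("protocol must contain at least one block")
        if np.any(np.diff(onsets) <= 0):
            raise ProtocolError("block onsets must be strictly increasing")
        if self.block_duration <= 0 or self.volume_interval <= 0:
            raise ProtocolError("durations must be positive")
        ratio = self.block_duration / self.volume_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ProtocolError(
                "block_duration must be an integer number of volumes "
                f"(got {self.block_duration} s at {self.volume_interval} s/volume)"
            )
        if onsets[0] < 0 or onsets[-1] + self.block_duration > self.duration:
            raise ProtocolError("every block must lie inside the scan")
        object.__setattr__(self, "block_onsets", tuple(float(t) for t in onsets))

    # -- derived quantities -------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return len(self.block_onsets)

    @property
    def duration(self) -> float:
        """Total scan duration in seconds."""
        return self.n_volumes * self.volume_interval

    @property
    def volumes_per_block(self) -> int:
        return int(round(self.block_duration / self.volume_interval))

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each volume (start-of-volume convention)."""
        return np.arange(self.n_volumes) * self.volume_interval

    def boxcar(self, times: np.ndarray | None = None) -> np.ndarray:
        """0/1 stimulation indicator sampled at ``times`` (default: volumes)."""
        t = self.frame_times if times is None else np.asarray(times, dtype=float)
        out = np.zeros(t.shape, dtype=float)
        for onset in self.block_onsets:
            out[(t >= onset) & (t < onset + self.block_duration)] = 1.0
        return out

    def block_boxcar(self, index: int, times: np.ndarray | None = None) -> np.ndarray:
        """0/1 indicator for a single block (0-based ``index``)."""
        t = self.frame_times if times is None else np.asarray(times, dtype=float)
        onset = self.block_onsets[index]
        return ((t >= onset) & (t < onset + self.block_duration)).astype(float)

    def stim_mask(self, times: np.ndarray, lag: float = 0.0,
                  transition: float = 0.0) -> np.ndarray:
        """Boolean mask of stimulation epochs over arbitrary sample times.

        ``lag`` shifts every epoch (e.g. the ~5 s latency of LFP power
        changes); ``transition`` additionally excludes the first seconds
        of each shifted epoch.
        """
        t = np.asarray(times, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for onset in self.block_onsets:
            mask |= (t >= onset + lag + transition) & (t < onset + lag + self.block_duration)
        return mask

    def baseline_mask(self, times: np.ndarray, lag: float = 0.0,
                      transition: float = 0.0) -> np.ndarray:
        """Mask of baseline samples: outside every (shifted) stimulation
        epoch and outside the first ``transition`` seconds that follow
        each epoch's end."""
        t = np.asarray(times, dtype=float)
        mask = np.ones(t.shape, dtype=bool)
        for onset in self.block_onsets:
            mask &= ~((t >= onset + lag) & (t < onset + lag + self.block_duration + transition))
        return mask

    def pulse_times(self, mode: str = "train") -> np.ndarray:
        """Light-pulse onset times.

        ``train`` returns every pulse of every block at ``pulse_rate``;
        ``single_pulse`` returns one isolated pulse per block (the first),
        emulating low-frequency single-pulse probing.
        """
        if mode == "single_pulse":
            return np.asarray(self.block_onsets, dtype=float)
        if mode != "train":
            raise ProtocolError(f"unknown pulse mode {mode!r}")
        period = 1.0 / self.pulse_rate
        pulses = [onset + np.arange(int(round(self.block_duration * self.pulse_rate))) * period
                  for onset in self.block_onsets]
        return np.concatenate(pulses)


#: lead-in baseline before the first block (seconds); the acquisitions
#: include a pre-block baseline whose length we fix here.
LEAD_IN_S = 60.0


def make_protocol(kind: str) -> StimProtocol:
    """Build one of the two standard block protocols.

    ``short``: 6 blocks of 20 s ON / 40 s OFF, 2 s volumes, 360 volumes
    (12 min).  ``long``: 6 blocks of 20 s ON / 160 s OFF, 720 volumes
    (24 min).
    """
    if kind == "short":
        inter, n_vol = 60.0, 360
    elif kind == "long":
        inter, n_vol = 180.0, 720
    else:
        raise ProtocolError(f"unknown protocol kind {kind!r}; expected 'short' or 'long'")
    onsets = tuple(LEAD_IN_S + i * inter for i in range(6))
    return StimProtocol(
        block_onsets=onsets,
        block_duration=20.0,
        inter_onset=inter,
        pulse_rate=20.0,
        pulse_width_ms=5.0,
        volume_interval=2.0,
        n_volumes=n_vol,
    )
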