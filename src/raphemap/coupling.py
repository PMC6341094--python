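"""Electro-vascular coupling.

Relates electrophysiology to hemodynamics in two complementary ways:
(1) per-site correlation between an HRF-convolved band-power (or MUA
rate) regressor and the CBV time series — the analysis behind the
finding that convolved delta power, but not convolved MUA, mirrors the
CBV response; (2) across recording sites, correlation between a
regional fractional metric (delta-power or burst-frequency change) and
the site's COPE, with strict (animal, ROI) matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hrf import GammaHRF, convolve_resample

logger = logging.getLogger(__name__)


class CouplingError(ValueError):
    """Raised for invalid coupling-analysis inputs."""


def burn_in_volumes(hrf: GammaHRF, volume_interval: float) -> int:
    """Number of volumes covered by one HRF kernel length; excluded from
    correlations as convolution edge burn-in."""
    return int(np.ceil(hrf.duration / volume_interval))


def convolved_regressor(series: np.ndarray, series_fs: float, hrf: GammaHRF,
                        target_interval: float, n_out: int | None = None,
                        normalize: str = "peak") -> np.ndarray:
    """Convolve a band-power/MUA-rate series with the HRF and
    average-resample onto the fMRI volume grid.

    ``series_fs`` must be finer than the volume grid.  When ``n_out``
    is given, a duration mismatch beyond one volume is an error.
    """
    if series_fs <= 1.0 / target_interval:
        raise CouplingError("series sampling must be finer than the volume grid")
    dt_in = 1.0 / series_fs
    x = np.asarray(series, dtype=float)
    avail = int(x.size * dt_in / target_interval)
    if n_out is not None and abs(avail - n_out) > 1:
        raise CouplingError(
            f"series covers {avail} volumes but the CBV series has {n_out} "
            "(mismatch beyond 1 volume)")
    out = convolve_resample(x, dt_in, hrf, target_interval,
                            n_out=min(avail, n_out) if n_out else None,
                            normalize=normalize)
    if n_out is not None and out.size == n_out - 1:
        # final volume only partially covered: extend with the last value
        out = np.append(out, out[-1])
    return out


@dataclass
class CouplingRecord:
    """Per-site coupling between a convolved regressor and CBV."""

    site_id: str
    kind: str               # delta | gamma | mua
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise CouplingError("|r| cannot exceed 1")
        if self.n < 3:
            raise CouplingError("need at least 3 time points")


def site_coupling(regressor: np.ndarray, cbv: np.ndarray, site_id: str = "site",
                  kind: str = "delta", hrf: GammaHRF | None = None,
                  volume_interval: float = 2.0,
                  burn_in: int | None = None) -> CouplingRecord:
    """Pearson correlation between regressor and CBV series, excluding
    the kernel-length burn-in at the start."""
    x = np.asarray(regressor, dtype=float)
    y = np.asarray(cbv, dtype=float)
    if x.size != y.size:
        raise CouplingError("regressor and CBV series must have equal length")
    if burn_in is None:
        burn_in = burn_in_volumes(hrf or GammaHRF(), volume_interval)
    x, y = x[burn_in:], y[burn_in:]
    if x.size < 3:
        raise CouplingError("fewer than 3 samples after burn-in exclusion")
    r, p = stats.pearsonr(x - x.mean(), y - y.mean())
    return CouplingRecord(site_id=site_id, kind=kind, r=float(r), p=float(p),
                          n=x.size)


@dataclass
class RegionalCouplingResult:
    """Across-site correlation of a fractional metric with the COPE."""

    pairs: pd.DataFrame     # animal, roi, metric, cope
    r: float
    p: float
    n: int


def regional_coupling(metrics: pd.DataFrame,
                      copes: pd.DataFrame) -> RegionalCouplingResult:
    """Correlate per-site fractional metrics with (animal, ROI)-matched
    COPEs.

    Both inputs need columns ``animal, roi, value``; unmatched sites are
    dropped with a warning; fewer than 3 matched pairs is an error.
    """
    for name, df in (("metrics", metrics), ("copes", copes)):
        missing = {"animal", "roi", "value"} - set(df.columns)
        if missing:
            raise CouplingError(f"{name} table lacks columns {sorted(missing)}")
    merged = metrics.merge(copes, on=["animal", "roi"],
                           suffixes=("_metric", "_cope"))
    dropped = len(metrics) - len(merged)
    if dropped:
        logger.warning("dropped %d recording sites without a matched COPE",
                       dropped)
    if len(merged) < 3:
        raise CouplingError(f"only {len(merged)} matched (animal, ROI) pairs; "
                            "need at least 3")
    r, p = stats.pearsonr(merged["value_metric"], merged["value_cope"])
    pairs = merged.rename(columns={"value_metric": "metric",
                                   "value_cope": "cope"})
    return RegionalCouplingResult(pairs=pairs, r=float(r), p=float(p),
                                  n=len(merged))
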