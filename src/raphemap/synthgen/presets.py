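"""Calibrated generator presets.

Each preset fixes the study conditions for one synthetic experiment:
sample sizes, noise levels and the ground-truth effect the pipeline is
expected to recover.  The calibration constants are the study's
defining quantities — the 2.6% -> 1.7% block adaptation, the 0.75
convolved-delta/CBV coupling, the 0.69 / 0.78 site-level correlations
of delta power and burst frequency with regional COPEs, and the 52.6%
/ 21.2% / 30.8% variance explained by the 5-HT1F/2A/2C receptor maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..hrf import GammaHRF
from ..protocol import StimProtocol, make_protocol
from . import atlas
from .cohort import GroundTruth, SyntheticCohort, simulate_cbv_cohort
from .maps import AtlasMaps, _mixed_map, simulate_atlas_maps
from .probe import simulate_site_lfp

#: per-block response magnitudes (% CBV) declining linearly from the
#: first-block to the sixth-block amplitude of the adaptation effect
ADAPTATION_SCHEDULE: tuple[float, ...] = tuple(np.linspace(2.6, 1.7, 6))

#: calibration targets for the electro-vascular coupling presets
DELTA_COUPLING_R = 0.75
FIG3E_DELTA_R = 0.69
FIG3F_BURST_R = 0.78

#: variance-explained targets for the receptor-screen preset
RECEPTOR_R2 = {"5-HT1F": 0.526, "5-HT2A": 0.212, "5-HT2C": 0.308,
               "5-HT1A": 0.0, "5-HT1B": 0.0}


def adaptation_truth() -> GroundTruth:
    """Ground truth with the declining block-amplitude schedule."""
    return GroundTruth(block_amplitudes=ADAPTATION_SCHEDULE,
                       noise_sd_pct=0.3, drift_pct_per_min=0.0)


def adaptation_short(n_subjects: int = 10, seed: int = 1,
                     rois: list[str] | None = None) -> SyntheticCohort:
    """Short-protocol cohort with block-to-block adaptation in the
    projection areas (2.6% in block 1 declining to 1.7% in block 6)."""
    protocol = make_protocol("short")
    return simulate_cbv_cohort(protocol, adaptation_truth(), n_subjects, seed,
                               rois=rois)


def stress_cohorts(n_control: int = 4, n_restraint: int = 7,
                   seed: int = 0) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Control and restraint cohorts; restraint blunts every ROI's
    amplitude by a factor 0.5 without changing the response pattern."""
    protocol = make_protocol("short")
    truth = GroundTruth(noise_sd_pct=0.3)
    control = simulate_cbv_cohort(protocol, truth, n_control, seed,
                                  condition="control")
    restraint = simulate_cbv_cohort(protocol, truth, n_restraint, seed + 1,
                                    condition="restraint")
    return control, restraint


def fluoxetine_cohorts(n_control: int = 4, n_fluox: int = 9,
                       seed: int = 0) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Control and fluoxetine cohorts; the post-injection scans (2 and 3)
    carry enhanced amplitudes in prefrontal/cingulate, amygdala and
    striatal ROIs only."""
    protocol = make_protocol("short")
    truth = GroundTruth(noise_sd_pct=0.3)
    control = simulate_cbv_cohort(protocol, truth, n_control, seed,
                                  condition="control")
    fluox = simulate_cbv_cohort(protocol, truth, n_fluox, seed + 1,
                                condition="fluoxetine")
    return control, fluox


@dataclass
class CouplingSite:
    """One site-paired synthetic LFP / CBV recording."""

    site_id: str
    lfp: object                 # raphemap.lfp.LfpTrace
    cbv: np.ndarray             # preprocessed-style % change on the volume grid


def coupling_delta(seed: int = 7, n_sites: int = 8,
                   target_r: float = DELTA_COUPLING_R,
                   protocol: StimProtocol | None = None,
                   truth: GroundTruth | None = None) -> list[CouplingSite]:
    """Site-paired LFP/CBV recordings whose convolved-delta-power /
    CBV correlation equals ``target_r``.

    The delta-band LFP is simulated with lagged stimulus suppression,
    its 10 Hz power envelope is convolved with the shared HRF and
    resampled to the volume grid (exactly the coupling stage's own
    regressor path), and the CBV series is built by mixing that
    regressor with orthogonalised noise at the ratio that pins the
    sample correlation, over the burn-in-excluded range the coupling
    stage correlates.
    """
    from ..coupling import burn_in_volumes, convolved_regressor
    from ..lfp import band_power_envelope

    protocol = protocol or make_protocol("short")
    truth = truth or GroundTruth()
    root = np.random.SeedSequence(seed)
    sites = []
    for i, seq in enumerate(root.spawn(n_sites)):
        rng = np.random.default_rng(seq)
        lfp = simulate_site_lfp(protocol, truth, rng)
        power, env_fs = band_power_envelope(lfp.samples, lfp.fs, band=(1.0, 4.0))
        reg = convolved_regressor(power, env_fs, truth.hrf,
                                  protocol.volume_interval,
                                  n_out=protocol.n_volumes)
        burn = burn_in_volumes(truth.hrf, protocol.volume_interval)
        tail = reg[burn:]
        mixed = _mixed_map(tail, target_r, rng)
        # scale into %-change-like units; affine maps leave r untouched
        cbv = np.empty(protocol.n_volumes)
        scale = 1.5 / max(mixed.std(), 1e-12)
        cbv[burn:] = mixed * scale
        cbv[:burn] = rng.normal(0.0, cbv[burn:].std(), size=burn)
        sites.append(CouplingSite(site_id=f"site{i + 1:02d}", lfp=lfp, cbv=cbv))
    return sites


_CORTICAL_ROIS = ("mPFC", "ACC", "M1", "M2", "S1", "S2", "OFC", "RSC")


def matched_sites(seed: int, target_r: float, metric_mean: float,
                  metric_sd: float, n_sites: int = 15, n_animals: int = 7,
                  cope_mean: float = -2.2, cope_sd: float = 0.9,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(animal, ROI)-matched site table drawn from a bivariate normal.

    Returns ``(metrics, copes)`` data frames with columns
    ``animal, roi, value``.  The population correlation is the target
    inflated by the first-order small-sample bias term
    ``(1 - r^2) / (2 n)`` so that the *sample* Pearson r at ``n_sites``
    is centred on the target.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rho = min(target_r * (1.0 + (1.0 - target_r ** 2) / (2.0 * n_sites)),
              0.999)
    cov = np.array([[metric_sd ** 2, rho * metric_sd * cope_sd],
                    [rho * metric_sd * cope_sd, cope_sd ** 2]])
    draws = rng.multivariate_normal([metric_mean, cope_mean], cov, size=n_sites)
    animals = [f"m{i % n_animals + 1}" for i in range(n_sites)]
    rois = [_CORTICAL_ROIS[i % len(_CORTICAL_ROIS)] for i in range(n_sites)]
    metrics = pd.DataFrame({"animal": animals, "roi": rois, "value": draws[:, 0]})
    copes = pd.DataFrame({"animal": animals, "roi": rois, "value": draws[:, 1]})
    return metrics, copes


def fig3e(seed: int = 11, n_sites: int = 15) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractional delta-power change vs COPE across matched sites
    (population r = 0.69)."""
    return matched_sites(seed, FIG3E_DELTA_R, metric_mean=-0.4, metric_sd=0.15,
                         n_sites=n_sites)


def fig3f(seed: int = 13, n_sites: int = 15) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractional burst-frequency change vs COPE across matched sites
    (population r = 0.78)."""
    return matched_sites(seed, FIG3F_BURST_R, metric_mean=-0.5, metric_sd=0.2,
                         n_sites=n_sites)


def receptor_screen(seed: int = 0, n_rois: int = 38,
                    r2_targets: dict[str, float] | None = None,
                    ) -> tuple[pd.Series, AtlasMaps]:
    """COPE truth over a 38-ROI atlas plus receptor/projection maps with
    pinned variance-explained targets."""
    labels = atlas.projection_labels()[:n_rois]
    seq = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(seq[0])
    cope = pd.Series(rng.normal(-2.2, 0.9, size=len(labels)), index=labels,
                     name="cope")
    maps = simulate_atlas_maps(cope, r2_targets or dict(RECEPTOR_R2),
                               seed=int(seq[1].generate_state(1)[0] % (2 ** 31)))
    return cope, maps


#: discoverable preset registry (figure-named aliases included)
PRESETS = {
    "adaptation_short": adaptation_short,
    "fig2_shortblock": adaptation_short,
    "coupling_delta": coupling_delta,
    "fig3_coupling": coupling_delta,
    "fig3e": fig3e,
    "fig3f": fig3f,
    "fig4_restraint": stress_cohorts,
    "stress": stress_cohorts,
    "fig5_fluoxetine": fluoxetine_cohorts,
    "receptor_screen": receptor_screen,
}
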