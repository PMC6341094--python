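"""Experiment orchestration.

Ties the stages together into reproducible end-to-end synthetic
experiments mirroring the study's conditions: a control cohort, acute
restraint (globally blunted amplitudes), fluoxetine (post-injection
enhancement restricted to prefrontal/cingulate, amygdala and striatal
ROIs), the block-adaptation experiment, the electro-vascular coupling
sites and the receptor screen.  Every run is fully determined by its
:class:`RunConfig` (preset, overrides, seed) and writes result tables
plus a JSON manifest from which the run can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling, group, hemo, structfunc
from .protocol import make_protocol
from .synthgen import atlas, presets
from .synthgen.cohort import SyntheticCohort

logger = logging.getLogger(__name__)

#: documented defaults for every overridable module parameter
OVERRIDE_DEFAULTS: dict[str, float | int] = {
    "poly_order": 2,
    "forming_p": 0.01,
    "d_merge": 2.5,
    "refractory_ms": 2.0,
    "min_spikes": 50,
    "hrf_shape": 6.0,
    "hrf_scale": 0.6,
    "n_control": 4,
    "n_condition": None,   # preset default: 7 restraint / 9 fluoxetine
}

_PRESETS = ("control", "fig2_shortblock", "adaptation_short", "fig3_coupling",
            "coupling_delta", "fig4_restraint", "stress", "fig5_fluoxetine",
            "receptor_screen")


class ConfigError(ValueError):
    """Raised with an aggregated report of configuration violations."""


@dataclass
class RunConfig:
    """Serialisable configuration of one synthetic experiment."""

    preset: str = "fig4_restraint"
    protocol: str = "short"
    n_perm: int = 5000
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"
    overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return validate_config(d)


def validate_config(config: dict | RunConfig) -> RunConfig:
    """Resolve defaults, reject unknown keys and aggregate violations."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = []
    unknown = set(config) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    merged = {f.name: config.get(f.name, getattr(RunConfig, f.name, None))
              for f in dataclasses.fields(RunConfig)}
    if merged["overrides"] is None:
        merged["overrides"] = {}
    if merged["preset"] not in _PRESETS:
        errors.append(f"unknown preset {merged['preset']!r}; "
                      f"available: {list(_PRESETS)}")
    if merged["protocol"] not in ("short", "long"):
        errors.append(f"unknown protocol {merged['protocol']!r}")
    if not isinstance(merged["n_perm"], int) or merged["n_perm"] < 100:
        errors.append("n_perm must be an integer >= 100")
    unknown_over = set(merged["overrides"]) - set(OVERRIDE_DEFAULTS)
    if unknown_over:
        errors.append(f"unknown override keys: {sorted(unknown_over)}")
    resolved = dict(OVERRIDE_DEFAULTS)
    resolved.update(merged["overrides"])
    if resolved["d_merge"] <= 0:
        errors.append("d_merge must be positive")
    if resolved["poly_order"] < 0:
        errors.append("poly_order must be >= 0")
    if resolved["refractory_ms"] <= 0:
        errors.append("refractory_ms must be positive")
    if errors:
        raise ConfigError("; ".join(errors))
    merged["overrides"] = resolved
    return RunConfig(**merged)


# ---------------------------------------------------------------------------
# first- and second-level helpers


def first_level_copes(cohort: SyntheticCohort, poly_order: int = 2
                      ) -> tuple[list[list[pd.Series]], pd.DataFrame]:
    """Preprocess and fit every scan of a cohort; per-subject lists of
    per-scan COPE series plus the subject metadata table."""
    per_subject = []
    meta = []
    for sub in cohort.subjects:
        copes = []
        for scan in sub.scans:
            series = hemo.preprocess_cbv(scan.raw, scan.protocol, contrast="cbv")
            res = hemo.BlockDesignGLM.from_protocol(
                series, scan.protocol, hrf=cohort.truth.hrf,
                poly_order=poly_order).fit()
            copes.append(res.cope("pooled")["cope"])
        per_subject.append(copes)
        meta.append({"subject": sub.subject_id, "condition": sub.condition,
                     "sex": sub.sex})
    return per_subject, pd.DataFrame(meta).set_index("subject")


def session_copes(cohort: SyntheticCohort, mode: str,
                  poly_order: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject session-contrast COPE maps (subjects x ROIs)."""
    per_subject, meta = first_level_copes(cohort, poly_order)
    rows = [group.session_contrast(scans, mode) for scans in per_subject]
    return pd.DataFrame(rows, index=meta.index), meta


# ---------------------------------------------------------------------------
# calibrated recovery experiments (used by the preset runners below and
# by the validation tooling)


def adaptation_block_amplitudes(seed: int, n_subjects: int = 10,
                                poly_order: int = 2) -> pd.DataFrame:
    """Block-wise response-amplitude recovery on the adaptation preset.

    Generates the short-protocol adaptation cohort, preprocesses scan 1
    of every subject, fits the per-block GLM and averages the amplitude
    (magnitude in the known response direction) over projection ROIs.
    Returns a data frame with per-block ``mean`` and ``sem`` across
    subjects.
    """
    cohort = presets.adaptation_short(n_subjects=n_subjects, seed=seed)
    rows = []
    for sub in cohort.subjects:
        scan = sub.scans[0]
        series = hemo.preprocess_cbv(scan.raw, scan.protocol)
        amps = hemo.blockwise_amplitudes(series, scan.protocol,
                                         hrf=cohort.truth.hrf,
                                         poly_order=poly_order)
        proj = [r for r in amps.columns if r != atlas.DRN]
        signed = amps[proj].mul([cohort.truth.sign(r) for r in proj], axis=1)
        rows.append(signed.mean(axis=1))
    table = pd.DataFrame(rows, index=[s.subject_id for s in cohort.subjects])
    return pd.DataFrame({"mean": table.mean(), "sem": table.sem()})


def delta_coupling_records(seed: int, n_sites: int = 8) -> pd.DataFrame:
    """Per-site convolved-delta-power / CBV coupling on the calibrated
    preset: the regressor is recomputed from each synthetic LFP through
    the band-power + HRF-convolution path."""
    from .lfp import band_power_envelope

    sites = presets.coupling_delta(seed=seed, n_sites=n_sites)
    protocol = make_protocol("short")
    hrf_model = presets.GroundTruth().hrf
    records = []
    for site in sites:
        power, env_fs = band_power_envelope(site.lfp.samples, site.lfp.fs)
        reg = coupling.convolved_regressor(power, env_fs, hrf_model,
                                           protocol.volume_interval,
                                           n_out=protocol.n_volumes)
        rec = coupling.site_coupling(reg, site.cbv, site_id=site.site_id,
                                     kind="delta",
                                     volume_interval=protocol.volume_interval)
        records.append({"site": rec.site_id, "kind": rec.kind, "r": rec.r,
                        "p": rec.p, "n": rec.n})
    return pd.DataFrame(records)


def matched_site_mean_r(kind: str, base_seed: int, n_reps: int = 50) -> float:
    """Mean across replicate seeds of the site-level Pearson r between a
    fractional electrophysiological metric and matched COPEs
    (``kind``: 'delta' for delta power, 'burst' for burst frequency)."""
    preset_fn = {"delta": presets.fig3e, "burst": presets.fig3f}[kind]
    rs = []
    for rep in range(n_reps):
        metrics, copes = preset_fn(seed=base_seed + rep)
        rs.append(coupling.regional_coupling(metrics, copes).r)
    return float(np.mean(rs))


def receptor_variance_explained(base_seed: int,
                                n_seeds: int = 100) -> pd.Series:
    """Mean variance explained (r^2) per receptor map over replicate
    generator seeds, via the structure-function stage after white-matter
    masking."""
    acc: dict[str, list[float]] = {}
    for s in range(n_seeds):
        cope, maps = presets.receptor_screen(seed=base_seed + s)
        for name, m in maps.maps.items():
            masked, _ = structfunc.mask_white_matter(m, maps.wm_labels)
            out = structfunc.structure_function_corr(cope, masked,
                                                     map_id=name)
            acc.setdefault(name, []).append(out.r2)
    return pd.Series({k: float(np.mean(v)) for k, v in acc.items()},
                     name="r2")


# ---------------------------------------------------------------------------
# experiment runners


def _two_group_experiment(cfg: RunConfig, condition: str,
                          make_cohorts) -> dict:
    mode = "fluoxetine" if condition == "fluoxetine" else "restraint"
    n_cond = cfg.overrides["n_condition"] or (9 if condition == "fluoxetine" else 7)
    control, treated = make_cohorts(
        n_control=cfg.overrides["n_control"],
        **({"n_restraint": n_cond} if condition == "restraint"
           else {"n_fluox": n_cond}),
        seed=cfg.seed)
    copes_c, meta_c = session_copes(control, mode, cfg.overrides["poly_order"])
    copes_t, meta_t = session_copes(treated, mode, cfg.overrides["poly_order"])
    copes = pd.concat([copes_c, copes_t])
    meta = pd.concat([meta_c, meta_t])
    design, contrast = group.build_group_design(meta, condition)
    adjacency = atlas.roi_adjacency(list(copes.columns))
    result = group.GroupPermutation(copes, design, contrast,
                                    adjacency=adjacency,
                                    forming_p=cfg.overrides["forming_p"]
                                    ).fit(n_perm=cfg.n_perm, seed=cfg.seed)
    table = result.table.copy()
    table["q"] = group.fdr_correct(table["p"])
    logger.info("group test: forming |t| threshold %.3f, n_perm %d",
                result.forming_threshold, result.n_perm)

    tables = {"group_stats": table, "session_copes": copes}
    if mode == "restraint":
        # DRN-normalised connectivity per group (scale-invariant profile);
        # undefined for the drug contrast, whose DRN session COPE is null
        norm = {}
        for name, cop in (("control", copes_c), ("treated", copes_t)):
            mean_cope = cop.mean(axis=0)
            t = mean_cope / cop.sem(axis=0)
            tab = pd.DataFrame({"cope": mean_cope, "t": t})
            norm[name] = group.normalize_to_drn(tab)
        tables["connectivity"] = pd.DataFrame(norm)
    return {"tables": tables, "result": result, "meta": meta}


def _adaptation_experiment(cfg: RunConfig) -> dict:
    cohort = presets.adaptation_short(seed=cfg.seed)
    rows = []
    for sub in cohort.subjects:
        scan = sub.scans[0]
        series = hemo.preprocess_cbv(scan.raw, scan.protocol)
        amps = hemo.blockwise_amplitudes(series, scan.protocol,
                                         hrf=cohort.truth.hrf,
                                         poly_order=cfg.overrides["poly_order"])
        proj = [r for r in amps.columns if r != atlas.DRN]
        # amplitude magnitude in the known response direction
        signed = amps[proj].mul(
            [cohort.truth.sign(r) for r in proj], axis=1)
        rows.append(signed.mean(axis=1))
    block_table = pd.DataFrame(rows, index=[s.subject_id for s in cohort.subjects])
    summary = pd.DataFrame({"mean": block_table.mean(),
                            "sem": block_table.sem()})
    return {"tables": {"block_amplitudes": block_table,
                       "block_summary": summary}}


def _coupling_experiment(cfg: RunConfig) -> dict:
    table = delta_coupling_records(seed=cfg.seed or 7)
    return {"tables": {"site_coupling": table}}


def _receptor_experiment(cfg: RunConfig) -> dict:
    cope, maps = presets.receptor_screen(seed=cfg.seed)
    masked = {}
    for name, m in maps.maps.items():
        masked[name], _ = structfunc.mask_white_matter(m, maps.wm_labels)
    table = structfunc.receptor_screen(cope, masked)
    return {"tables": {"receptor_screen": table}}


def run_experiment(config: dict | RunConfig) -> dict:
    """Run one preset end to end; write tables and a manifest.

    Returns a dict with the result tables and the manifest.  Re-running
    with the same config produces byte-identical tables.
    """
    cfg = validate_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.preset in ("fig4_restraint", "stress"):
        out = _two_group_experiment(cfg, "restraint", presets.stress_cohorts)
    elif cfg.preset == "fig5_fluoxetine":
        out = _two_group_experiment(cfg, "fluoxetine", presets.fluoxetine_cohorts)
    elif cfg.preset in ("fig2_shortblock", "adaptation_short"):
        out = _adaptation_experiment(cfg)
    elif cfg.preset in ("fig3_coupling", "coupling_delta"):
        out = _coupling_experiment(cfg)
    elif cfg.preset == "receptor_screen":
        out = _receptor_experiment(cfg)
    elif cfg.preset == "control":
        cohort = presets.adaptation_short(n_subjects=cfg.overrides["n_control"],
                                          seed=cfg.seed)
        copes, meta = session_copes(cohort, "restraint",
                                    cfg.overrides["poly_order"])
        out = {"tables": {"session_copes": copes}}
    else:  # pragma: no cover - validate_config already rejects
        raise ConfigError(f"unknown preset {cfg.preset!r}")

    manifest = {"config": cfg.to_dict(),
                "tables": sorted(out["tables"])}
    for name, table in out["tables"].items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", float_format="%.6g")
        logger.info("wrote %s", path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    out["manifest"] = manifest
    return out
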