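"""On-disk formats for synthetic data.

ROI time series are tab-separated tables (one column per ROI, header
row of labels, one row per volume) with a JSON sidecar holding the
protocol, units and ground truth.  Probe recordings are little-endian
int16 binary, channel-interleaved, with a JSON sidecar (sampling rate,
channel map, ground truth spike/burst times, microvolt scale).  Cohorts
are laid out BIDS-style (``sub-XX/ses-01/func`` and ``ephys``) without
claiming BIDS validity.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..protocol import StimProtocol
from .cohort import Scan, SyntheticCohort
from .probe import ProbeRecording

_INT16_MAX = 32000


def _protocol_dict(protocol: StimProtocol) -> dict:
    return dataclasses.asdict(protocol)


def protocol_from_dict(d: dict) -> StimProtocol:
    d = dict(d)
    d["block_onsets"] = tuple(d["block_onsets"])
    return StimProtocol(**d)


def write_series(path: str | Path, series: pd.DataFrame,
                 protocol: StimProtocol, sidecar_extra: dict | None = None) -> Path:
    """Write an ROI x time table as TSV plus a ``.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"protocol": _protocol_dict(protocol), "units": "raw signal"}
    sidecar.update(sidecar_extra or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path: str | Path) -> tuple[pd.DataFrame, StimProtocol, dict]:
    path = Path(path)
    series = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return series, protocol_from_dict(sidecar["protocol"]), sidecar


def write_probe(path: str | Path, rec: ProbeRecording) -> Path:
    """Write raw traces as channel-interleaved little-endian int16 plus
    a JSON sidecar carrying the scale and ground truth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    peak = float(np.abs(rec.traces).max()) or 1.0
    scale = peak / _INT16_MAX  # microvolts per count
    ints = np.round(rec.traces / scale).astype("<i2")
    ints.T.reshape(-1).tofile(path)  # sample-major, channel-interleaved
    sidecar = {
        "fs": rec.fs,
        "n_channels": int(rec.traces.shape[0]),
        "site": rec.site,
        "uv_per_count": scale,
        "protocol": _protocol_dict(rec.protocol),
        "unit_times": {k: np.asarray(v).tolist() for k, v in rec.unit_times.items()},
        "unit_channels": {k: list(v) for k, v in rec.unit_channels.items()},
        "burst_times": np.asarray(rec.burst_times).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_probe(path: str | Path) -> ProbeRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raw = np.fromfile(path, dtype="<i2")
    n_ch = sidecar["n_channels"]
    traces = raw.reshape(-1, n_ch).T.astype(np.float32) * sidecar["uv_per_count"]
    return ProbeRecording(
        traces=traces, fs=sidecar["fs"], site=sidecar["site"],
        unit_times={k: np.asarray(v) for k, v in sidecar["unit_times"].items()},
        unit_channels={k: tuple(v) for k, v in sidecar["unit_channels"].items()},
        templates={},
        burst_times=np.asarray(sidecar["burst_times"]),
        protocol=protocol_from_dict(sidecar["protocol"]),
    )


def write_cohort(root: str | Path, cohort: SyntheticCohort) -> Path:
    """Write a cohort under a BIDS-inspired directory layout."""
    root = Path(root)
    for sub in cohort.subjects:
        for k, scan in enumerate(sub.scans):
            func = root / sub.subject_id / "ses-01" / "func"
            write_series(
                func / f"{sub.subject_id}_ses-01_run-{k + 1:02d}_roi.tsv",
                scan.raw, scan.protocol,
                sidecar_extra={
                    "condition": sub.condition,
                    "sex": sub.sex,
                    "truth_amplitudes": scan.amplitudes.to_dict(),
                })
    return root


def write_nifti(path: str | Path, volume: np.ndarray,
                voxel_size_mm: float = 0.2) -> Path:
    """Optional 4D NIfTI-1 export of a volumetric phantom."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), path)
    return path
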