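"""Synthetic atlas maps with controlled structure-function correlation.

Each map (projection density or receptor expression) is generated by
mixing the true response (COPE) map with an orthogonalised Gaussian
noise map at the analytically required ratio, so that the *sample*
correlation with the COPE truth equals ``+/- sqrt(r2_target)`` exactly.
Affine rescaling afterwards leaves the correlation untouched.  A
"projection" map with target 0 is always included, encoding the
finding that anatomical projection density does not predict the
hemodynamic response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import atlas
from .cohort import GeneratorError


@dataclass
class AtlasMaps:
    """Per-ROI atlas maps sharing one label set.

    ``maps`` holds one value series per source (projection density or a
    receptor subtype's expression); ``wm_labels`` lists entries that
    belong to white matter and should be masked before any
    structure-function comparison.
    """

    maps: dict[str, pd.Series]
    wm_labels: tuple[str, ...] = field(default_factory=tuple)
    provenance: dict[str, float] = field(default_factory=dict)

    def labels(self) -> list[str]:
        first = next(iter(self.maps.values()))
        return list(first.index)


def _mixed_map(cope: np.ndarray, r_target: float,
               rng: np.random.Generator) -> np.ndarray:
    """Vector whose sample Pearson correlation with ``cope`` is exactly
    ``r_target``, via orthogonalised noise mixing."""
    c = cope - cope.mean()
    nc = np.linalg.norm(c)
    if nc == 0:
        raise GeneratorError("COPE truth is constant; correlation undefined")
    u_c = c / nc
    for _ in range(16):
        z = rng.normal(size=cope.size)
        z = z - z.mean()
        z = z - (z @ u_c) * u_c
        nz = np.linalg.norm(z)
        if nz > 1e-10:
            break
    else:  # pragma: no cover - probability ~0
        raise GeneratorError("could not build an orthogonal noise map")
    u_n = z / nz
    return r_target * u_c + np.sqrt(max(0.0, 1.0 - r_target ** 2)) * u_n


def simulate_atlas_maps(cope_truth: pd.Series, r2_targets: dict[str, float],
                        seed: int, negative: set[str] | None = None,
                        include_wm: bool = True) -> AtlasMaps:
    """Generate atlas maps hitting per-map r-squared targets.

    Parameters
    ----------
    cope_truth
        Per-ROI true response amplitudes (the map the generated maps are
        calibrated against).
    r2_targets
        Target variance-explained per map name, each in [0, 1].  A
        ``projection`` entry with target 0 is appended if absent.
    negative
        Map names whose correlation sign should be negative
        (default: all positive).
    include_wm
        Append white-matter entries (random values) to every map so the
        masking step has work to do.
    """
    if cope_truth.size < 3:
        raise GeneratorError("need at least 3 ROIs for a correlation target")
    targets = dict(r2_targets)
    targets.setdefault("projection", 0.0)
    for name, r2 in targets.items():
        if not 0.0 <= r2 <= 1.0:
            raise GeneratorError(f"r2 target outside [0, 1] for {name!r}")
    negative = negative or set()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cope = cope_truth.to_numpy(dtype=float)
    maps: dict[str, pd.Series] = {}
    for name in sorted(targets):
        r = np.sqrt(targets[name]) * (-1.0 if name in negative else 1.0)
        m = _mixed_map(cope, r, rng)
        # arbitrary positive affine rescale into expression-like units
        m = 50.0 + 20.0 * m / max(np.abs(m).max(), 1e-12)
        series = pd.Series(m, index=cope_truth.index, name=name)
        if include_wm:
            wm_vals = pd.Series(rng.uniform(20.0, 90.0, size=len(atlas.WM_LABELS)),
                                index=list(atlas.WM_LABELS))
            series = pd.concat([series, wm_vals])
        maps[name] = series
    return AtlasMaps(maps=maps,
                     wm_labels=atlas.WM_LABELS if include_wm else (),
                     provenance=dict(targets))
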