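"""Structure-function comparison.

Correlates the functional response map (per-ROI COPEs) with anatomical
atlas maps: serotonergic projection density and receptor-subtype
expression.  White-matter entries are removed from anatomical maps
first, so the comparison concerns terminal fields rather than fibre
tracts.  A receptor screen correlates several expression maps against
the response map, applies BH-FDR across the screened set and ranks by
variance explained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .group import fdr_correct

logger = logging.getLogger(__name__)


class StructFuncError(ValueError):
    """Raised for invalid structure-function comparisons."""


def mask_white_matter(atlas_map: pd.Series,
                      wm_labels) -> tuple[pd.Series, int]:
    """Remove white-matter-labelled entries from an ROI map.

    Returns the masked map and the number of entries removed; removing
    everything is an error.
    """
    wm = {str(l).lower() for l in wm_labels}
    keep = [lab for lab in atlas_map.index if str(lab).lower() not in wm]
    removed = len(atlas_map) - len(keep)
    if not keep:
        raise StructFuncError("white-matter masking removed every entry")
    return atlas_map.loc[keep], removed


@dataclass
class StructureFunctionResult:
    """Correlation of one anatomical map with the response map."""

    map_id: str
    r: float
    r2: float
    p: float
    n: int
    significant: bool | None = None     # set after multiplicity correction
    q: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise StructFuncError("r2 must lie in [0, 1]")


def _harmonise(cope: pd.Series, atlas_map: pd.Series
               ) -> tuple[np.ndarray, np.ndarray, int]:
    """Case-insensitive inner join on ROI labels."""
    cope_idx = {str(l).lower(): l for l in cope.index}
    map_idx = {str(l).lower(): l for l in atlas_map.index}
    shared = sorted(set(cope_idx) & set(map_idx))
    dropped = (len(cope) - len(shared)) + (len(atlas_map) - len(shared))
    if dropped:
        logger.info("label harmonisation dropped %d unshared entries", dropped)
    x = np.array([cope[cope_idx[l]] for l in shared], dtype=float)
    y = np.array([atlas_map[map_idx[l]] for l in shared], dtype=float)
    return x, y, len(shared)


def structure_function_corr(cope: pd.Series, atlas_map: pd.Series,
                            map_id: str | None = None
                            ) -> StructureFunctionResult:
    """Pearson correlation between the COPE map and one anatomical map
    over their shared ROIs (at least 3 required)."""
    x, y, n = _harmonise(cope, atlas_map)
    if n < 3:
        raise StructFuncError(f"only {n} shared ROIs after harmonisation; "
                              "need at least 3")
    r, p = stats.pearsonr(x, y)
    return StructureFunctionResult(
        map_id=map_id or (atlas_map.name or "map"),
        r=float(r), r2=float(r) ** 2, p=float(p), n=n)


def receptor_screen(cope: pd.Series, maps: dict[str, pd.Series],
                    alpha: float = 0.05) -> pd.DataFrame:
    """Screen several maps against the response map.

    Per-map Pearson r / r-squared / p, BH-FDR corrected across the
    screened maps, sorted by variance explained (ties broken by map
    label for a stable order).
    """
    if not maps:
        raise StructFuncError("no maps to screen")
    results = [structure_function_corr(cope, m, map_id=name)
               for name, m in sorted(maps.items())]
    frame = pd.DataFrame({
        "map": [r.map_id for r in results],
        "r": [r.r for r in results],
        "r2": [r.r2 for r in results],
        "p": [r.p for r in results],
        "n": [r.n for r in results],
    })
    frame["q"] = fdr_correct(frame["p"].to_numpy())
    frame["significant"] = frame["q"] < alpha
    return (frame.sort_values(["r2", "map"], ascending=[False, True])
                 .reset_index(drop=True))
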