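"""Synthetic ROI atlas used by the generator and group stages.

The default atlas carries 39 labels: the DRN plus 38 grey-matter
projection regions grouped anatomically (isocortex, hippocampal
formation, amygdala/cortical subplate, striatum, thalamus,
hypothalamus).  A 38-ROI variant (projection regions only) is used for
the structure-function comparison, where the seed region itself is
excluded.  A small set of white-matter labels exists solely so that the
white-matter masking step has something to remove.

The ROI adjacency graph is a deliberately simple synthetic structure:
regions are chained within their anatomical group and the groups are
joined into one connected component.  It serves cluster-extent
correction on ROI-level statistic maps; it makes no claim to true mouse
neuroanatomical adjacency.
"""

from __future__ import annotations

import networkx as nx

DRN = "DRN"

#: anatomical groups of the synthetic atlas (order defines the label order)
ATLAS_GROUPS: dict[str, list[str]] = {
    "isocortex": [
        "mPFC", "PrL", "IL", "ACC", "OFC", "M1", "M2", "S1", "S2",
        "V1", "V2", "A1", "RSC", "PtA", "Ins", "TeA",
    ],
    "hippocampus": ["CA1", "CA3", "DG", "Sub", "Ent"],
    "amygdala": ["BLA", "CeA", "MeA", "Cla", "EP"],
    "striatum": ["CPu", "NAc", "OT", "LS", "GP"],
    "thalamus": ["VPM", "LD", "MD", "Po", "LGN"],
    "hypothalamus": ["LH", "PVN"],
}

#: white-matter labels (only present in atlas *maps*, never in the
#: functional ROI set); the masking stage removes them.
WM_LABELS: tuple[str, ...] = ("cc", "ac", "ic", "fx")

#: projection regions with enhanced responses under fluoxetine
#: (prefrontal/cingulate cortex, amygdala and striatum).
FLUOXETINE_ROIS: tuple[str, ...] = (
    "mPFC", "PrL", "IL", "ACC", "OFC", "BLA", "CeA", "CPu", "NAc",
)


def projection_labels() -> list[str]:
    """The 38 projection-region labels (no DRN), in atlas order."""
    out: list[str] = []
    for members in ATLAS_GROUPS.values():
        out.extend(members)
    return out


def default_atlas(include_drn: bool = True) -> list[str]:
    """Full atlas label list: 39 labels with the DRN, 38 without."""
    labels = projection_labels()
    return [DRN] + labels if include_drn else labels


def roi_adjacency(labels: list[str] | None = None) -> nx.Graph:
    """Adjacency graph over atlas ROIs (chained within groups, groups
    bridged head-to-head, DRN attached to the thalamus chain)."""
    graph = nx.Graph()
    if labels is None:
        labels = default_atlas()
    graph.add_nodes_from(labels)
    heads = []
    for members in ATLAS_GROUPS.values():
        present = [m for m in members if m in graph]
        for a, b in zip(present, present[1:]):
            graph.add_edge(a, b)
        if present:
            heads.append(present[0])
    for a, b in zip(heads, heads[1:]):
        graph.add_edge(a, b)
    if DRN in graph and "VPM" in graph:
        graph.add_edge(DRN, "VPM")
    return graph
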