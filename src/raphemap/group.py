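"""Second-level inference across subjects.

Session contrasts (drug: post-injection scans averaged minus the
pre-injection scan; restraint: all three scans averaged), non-parametric
permutation testing with a Freedman-Lane covariate-respecting scheme,
family-wise correction by the max-statistic and by cluster extent on an
ROI adjacency graph, Benjamini-Hochberg FDR across ROIs, and
DRN-normalised functional connectivity.

:class:`GroupPermutation` is the model object; ``fit(n_perm, seed)``
returns a :class:`PermutationResult` with per-ROI t statistics,
uncorrected and corrected p-values and the null-distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthgen import atlas


class GroupError(ValueError):
    """Raised for invalid group-level designs or inputs."""


# ---------------------------------------------------------------------------
# session contrasts


def session_contrast(scans: list[pd.Series], mode: str) -> pd.Series:
    """Collapse a session's three scans into one per-subject COPE map.

    ``fluoxetine``: mean of the two post-injection scans minus the
    pre-injection scan (within-session correction).  ``restraint``:
    plain mean of the three scans (no within-session reference exists).
    """
    if len(scans) != 3:
        raise GroupError(f"a session must contain exactly 3 scans, got {len(scans)}")
    s = [pd.Series(x) for x in scans]
    if mode == "fluoxetine":
        return (s[1] + s[2]) / 2.0 - s[0]
    if mode == "restraint":
        return (s[0] + s[1] + s[2]) / 3.0
    raise GroupError(f"unknown session contrast mode {mode!r}")


def build_group_design(subjects: pd.DataFrame, test_condition: str,
                       reference: str = "control") -> tuple[pd.DataFrame, np.ndarray]:
    """Two-sample design with sex covariate from a subject table.

    ``subjects`` needs columns ``condition`` and ``sex``.  Returns the
    design frame (intercept, group indicator, sex) and the contrast
    vector selecting the group effect (test - reference).
    """
    cond = subjects["condition"]
    if not set(cond) <= {test_condition, reference}:
        raise GroupError("subject table contains conditions outside the comparison")
    design = pd.DataFrame({
        "intercept": np.ones(len(subjects)),
        "group": (cond == test_condition).astype(float).to_numpy(),
        "sex": (subjects["sex"] == "M").astype(float).to_numpy(),
    }, index=subjects.index)
    contrast = np.array([0.0, 1.0, 0.0])
    return design, contrast


# ---------------------------------------------------------------------------
# permutation machinery


def _edges_from_adjacency(adjacency, labels: list[str]) -> list[tuple[int, int]]:
    if adjacency is None:
        return []
    if isinstance(adjacency, nx.Graph):
        index = {lab: i for i, lab in enumerate(labels)}
        return [(index[a], index[b]) for a, b in adjacency.edges
                if a in index and b in index]
    return [tuple(e) for e in adjacency]


def _component_extents(mask: np.ndarray, edges: list[tuple[int, int]]) -> list[list[int]]:
    """Connected components of the supra-threshold node set (union-find)."""
    nodes = np.flatnonzero(mask)
    if nodes.size == 0:
        return []
    parent = {int(i): int(i) for i in nodes}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        if mask[a] and mask[b]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for i in nodes:
        comps.setdefault(find(int(i)), []).append(int(i))
    return list(comps.values())


def max_cluster_extent(mask: np.ndarray, edges: list[tuple[int, int]]) -> int:
    comps = _component_extents(mask, edges)
    return max((len(c) for c in comps), default=0)


@dataclass
class PermutationResult:
    """Permutation-test output: per-ROI statistics and null summaries."""

    table: pd.DataFrame             # roi, t, p, p_fwe, cluster, p_cluster
    clusters: pd.DataFrame          # cluster id, extent, rois, p_corr
    n_perm: int
    seed: int | None
    forming_threshold: float
    null_max_t: np.ndarray
    null_max_extent: np.ndarray
    df_resid: int

    def summary(self) -> str:
        lines = [
            f"Permutation test ({self.n_perm} permutations, seed {self.seed})",
            f"  cluster-forming |t| threshold: {self.forming_threshold:.3f} "
            f"(df = {self.df_resid})",
            f"  null max|t|: median {np.median(self.null_max_t):.2f}, "
            f"95th pct {np.percentile(self.null_max_t, 95):.2f}",
            self.table.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        if len(self.clusters):
            lines.append("clusters:")
            lines.append(self.clusters.to_string())
        return "\n".join(lines)


class GroupPermutation:
    """Covariate-respecting permutation test over subject-level COPEs.

    The null is built Freedman-Lane style: nuisance covariates (the
    design columns with zero contrast weight) are fitted, their
    residuals permuted, the fitted nuisance added back and the full
    model refitted, giving the permutation distribution of the contrast
    t statistic.  Family-wise corrected p-values use the max-statistic
    and cluster-extent null distributions.
    """

    def __init__(self, copes: pd.DataFrame, design: pd.DataFrame,
                 contrast: np.ndarray, adjacency=None,
                 forming_p: float = 0.01):
        if len(copes) != len(design):
            raise GroupError("copes and design disagree on the number of subjects")
        contrast = np.asarray(contrast, dtype=float)
        if contrast.size != design.shape[1]:
            raise GroupError("contrast length must equal the design column count")
        if len(copes) <= design.shape[1]:
            raise GroupError("more design columns than subjects")
        # each level of a binary tested factor needs >= 2 members
        for j in np.flatnonzero(contrast):
            col = design.iloc[:, j]
            levels = col.unique()
            if len(levels) == 2 and min((col == l).sum() for l in levels) < 2:
                raise GroupError("need at least 2 subjects per group")
        self.copes = copes
        self.design = design
        self.contrast = contrast
        self.adjacency = adjacency
        self.forming_p = forming_p

    def _tstats(self, Y: np.ndarray, X: np.ndarray, xtx_inv: np.ndarray,
                cvar: float, df: int) -> np.ndarray:
        pinv = xtx_inv @ X.T
        if Y.ndim == 2:
            beta = pinv @ Y
            resid = Y - X @ beta
            sigma2 = (resid ** 2).sum(axis=0) / df
            return (self.contrast @ beta) / np.sqrt(sigma2 * cvar)
        beta = np.einsum("ij,cjk->cik", pinv, Y)
        resid = Y - np.einsum("ij,cjk->cik", X, beta)
        sigma2 = (resid ** 2).sum(axis=1) / df
        copes = np.einsum("i,cik->ck", self.contrast, beta)
        return copes / np.sqrt(sigma2 * cvar)

    def fit(self, n_perm: int = 5000, seed: int | None = None,
            chunk: int = 512) -> PermutationResult:
        if n_perm < 100:
            raise GroupError("n_perm must be at least 100")
        X = self.design.to_numpy(dtype=float)
        Y = self.copes.to_numpy(dtype=float)
        labels = list(self.copes.columns)
        n, p = X.shape
        df = n - p
        xtx_inv = np.linalg.inv(X.T @ X)
        cvar = float(self.contrast @ xtx_inv @ self.contrast)
        t_obs = self._tstats(Y, X, xtx_inv, cvar, df)

        nuisance = np.flatnonzero(self.contrast == 0)
        if nuisance.size:
            X0 = X[:, nuisance]
            fitted0 = X0 @ np.linalg.lstsq(X0, Y, rcond=None)[0]
        else:
            fitted0 = np.zeros_like(Y)
        R = Y - fitted0

        edges = _edges_from_adjacency(self.adjacency, labels)
        t_thr = float(stats.t.ppf(1.0 - self.forming_p / 2.0, df))

        rng = np.random.default_rng(seed)
        exceed = np.zeros(t_obs.size)
        null_max_t = np.empty(n_perm)
        null_max_ext = np.empty(n_perm, dtype=int)
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perms = np.stack([rng.permutation(n) for _ in range(m)])
            Yp = fitted0[None, :, :] + R[perms]
            t_null = self._tstats(Yp, X, xtx_inv, cvar, df)
            abs_null = np.abs(t_null)
            exceed += (abs_null >= np.abs(t_obs)[None, :]).sum(axis=0)
            null_max_t[done:done + m] = abs_null.max(axis=1)
            for i in range(m):
                null_max_ext[done + i] = max_cluster_extent(abs_null[i] > t_thr,
                                                            edges)
            done += m

        p_unc = (1.0 + exceed) / (n_perm + 1.0)
        p_fwe = (1.0 + (null_max_t[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) \
            / (n_perm + 1.0)
        p_fwe = np.maximum(p_fwe, p_unc)

        cluster_table = _cluster_table(t_obs, labels, edges, t_thr, null_max_ext)
        cluster_id = np.full(t_obs.size, -1)
        p_cluster = np.full(t_obs.size, np.nan)
        for _, row in cluster_table.iterrows():
            for roi in row["rois"]:
                idx = labels.index(roi)
                cluster_id[idx] = row["cluster"]
                p_cluster[idx] = row["p_corr"]

        table = pd.DataFrame({
            "t": t_obs, "p": p_unc, "p_fwe": p_fwe,
            "cluster": cluster_id, "p_cluster": p_cluster,
        }, index=pd.Index(labels, name="roi"))
        return PermutationResult(table=table, clusters=cluster_table,
                                 n_perm=n_perm, seed=seed,
                                 forming_threshold=t_thr,
                                 null_max_t=null_max_t,
                                 null_max_extent=null_max_ext, df_resid=df)


def _cluster_table(t_obs: np.ndarray, labels: list[str],
                   edges: list[tuple[int, int]], t_thr: float,
                   null_extents: np.ndarray) -> pd.DataFrame:
    comps = _component_extents(np.abs(t_obs) > t_thr, edges)
    rows = []
    for cid, comp in enumerate(sorted(comps, key=len, reverse=True)):
        extent = len(comp)
        p_corr = (1.0 + (null_extents >= extent).sum()) / (null_extents.size + 1.0)
        rows.append({"cluster": cid, "extent": extent,
                     "rois": [labels[i] for i in comp], "p_corr": p_corr})
    return pd.DataFrame(rows, columns=["cluster", "extent", "rois", "p_corr"])


def permutation_test(copes: pd.DataFrame, design: pd.DataFrame,
                     contrast: np.ndarray, n_perm: int = 5000,
                     seed: int | None = None, adjacency=None,
                     forming_p: float = 0.01) -> PermutationResult:
    """Convenience wrapper around :class:`GroupPermutation`."""
    return GroupPermutation(copes, design, contrast, adjacency=adjacency,
                            forming_p=forming_p).fit(n_perm=n_perm, seed=seed)


def cluster_extent_correct(stat: pd.Series, adjacency,
                           forming_threshold: float,
                           null_extents: np.ndarray) -> pd.DataFrame:
    """Cluster table with corrected p from a supplied null-extent
    distribution (empty table, not an error, when nothing survives the
    forming threshold)."""
    labels = list(stat.index)
    edges = _edges_from_adjacency(adjacency, labels)
    return _cluster_table(stat.to_numpy(dtype=float), labels, edges,
                          forming_threshold, np.asarray(null_extents))


def fwe_calibration(n_datasets: int = 500, n_perm: int = 500,
                    alpha: float = 0.05, seed: int = 0, n_rois: int = 10,
                    n1: int = 7, n2: int = 4) -> float:
    """Empirical family-wise error rate of the max-statistic permutation
    test under the global null.

    Simulates ``n_datasets`` two-sample datasets (group sizes matching
    the restraint comparison by default) with no true effect and
    returns the fraction in which any ROI survives family-wise
    correction at ``alpha``.
    """
    root = np.random.SeedSequence(seed)
    false_positives = 0
    for i, seq in enumerate(root.spawn(n_datasets)):
        rng = np.random.default_rng(seq)
        copes = pd.DataFrame(rng.normal(size=(n1 + n2, n_rois)),
                             columns=[f"r{j}" for j in range(n_rois)])
        design = pd.DataFrame({"intercept": np.ones(n1 + n2),
                               "group": [1.0] * n1 + [0.0] * n2})
        res = GroupPermutation(copes, design, [0.0, 1.0]).fit(
            n_perm=n_perm, seed=int(seq.generate_state(1)[0] % (2 ** 31)))
        if (res.table["p_fwe"] < alpha).any():
            false_positives += 1
    return false_positives / n_datasets


# ---------------------------------------------------------------------------
# FDR and DRN normalisation


def fdr_correct(pvalues: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values."""
    arr = np.asarray(pvalues, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise GroupError("p-values must lie in [0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q")
    return q


def normalize_to_drn(cope_table: pd.DataFrame, drn_label: str = atlas.DRN,
                     t_floor: float = 2.0) -> pd.Series:
    """Normalise projection-area COPEs to the DRN COPE.

    Functional connectivity expressed this way is invariant to global
    rescaling of the response; a DRN response without a reliable effect
    (|t| below ``t_floor``) makes the ratio unstable and is refused.
    """
    if drn_label not in cope_table.index:
        raise GroupError(f"DRN ROI {drn_label!r} not present in the COPE table")
    drn = cope_table.loc[drn_label]
    if "t" in cope_table.columns and abs(drn["t"]) < t_floor:
        raise GroupError(f"|t| of the DRN COPE ({drn['t']:.2f}) is below the "
                         f"stability floor {t_floor}")
    drn_cope = drn["cope"] if "cope" in cope_table.columns else float(drn)
    if drn_cope == 0:
        raise GroupError("DRN COPE is zero; normalisation undefined")
    copes = cope_table["cope"] if "cope" in cope_table.columns \
        else cope_table.iloc[:, 0]
    out = copes / drn_cope
    out.loc[drn_label] = 1.0
    return out.rename("normalized_cope")
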