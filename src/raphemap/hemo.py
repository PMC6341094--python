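"""First-level hemodynamic analysis.

Preprocessing of raw contrast-agent (CBV) signals — linear detrend for
nanoparticle clearance, percent change to the pre-first-block baseline,
sign inversion — followed by a block-design general linear model with
gamma-HRF activity regressors, their temporal derivatives and
polynomial drift terms.  The model/results pair mirrors the
statsmodels idiom: :class:`BlockDesignGLM` is built from data and
``fit()`` returns a :class:`BlockDesignGLMResults` carrying contrast
estimates (COPEs), standard errors, t statistics and residual
diagnostics, with a ``summary()`` table.

Because the activity regressors are peak-normalised, a regression
coefficient of *a* reads directly as a response amplitude of *a*
percent signal change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import ndimage

from .hrf import GammaHRF, block_regressors
from .protocol import StimProtocol


class HemoError(ValueError):
    """Raised for invalid hemodynamic-analysis inputs."""


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class RoiTimeSeriesSet:
    """ROI x time percent-change signals plus preprocessing provenance."""

    data: pd.DataFrame                  # volumes x ROIs, percent change
    volume_interval: float
    provenance: list[str] = field(default_factory=list)

    @property
    def rois(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.data)


def preprocess_cbv(raw: pd.DataFrame, protocol: StimProtocol,
                   contrast: str = "cbv",
                   response_tail_s: float = 25.0) -> RoiTimeSeriesSet:
    """Detrend, percent-change-normalise and (for CBV) sign-invert.

    In order: a linear trend fitted on non-stimulation volumes (the
    stimulation epochs plus a ``response_tail_s`` hemodynamic tail —
    the HRF kernel support — are excluded from the fit) is removed to
    account for contrast-agent clearance; the series is expressed as
    percent change relative to the mean of the volumes preceding the
    first block; the sign is inverted iff ``contrast='cbv'`` so that a
    CBV increase reads positive.
    """
    if contrast not in ("cbv", "bold"):
        raise HemoError(f"unknown contrast {contrast!r}")
    t = protocol.frame_times
    nonstim = np.ones(t.size, dtype=bool)
    for onset in protocol.block_onsets:
        nonstim &= ~((t >= onset)
                     & (t < onset + protocol.block_duration + response_tail_s))
    baseline = t < protocol.block_onsets[0]
    if not baseline.any():
        raise HemoError("no baseline volumes before the first block")

    # pivot the slope removal at the baseline window so the signal level
    # that the percent change divides by is the pre-stimulation level
    X = np.column_stack([np.ones(t.size), t - t[baseline].mean()])
    out = {}
    for roi in raw.columns:
        y = raw[roi].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X[nonstim], y[nonstim], rcond=None)
        detrended = y - coef[1] * X[:, 1]           # remove slope, keep level
        base_mean = detrended[baseline].mean()
        if base_mean <= 0:
            raise HemoError(f"non-positive baseline mean for ROI {roi!r}")
        pct = 100.0 * (detrended / base_mean - 1.0)
        out[roi] = -pct if contrast == "cbv" else pct
    prov = ["linear detrend (slope fit on non-stimulation volumes)",
            "percent change to pre-first-block baseline",
            "sign inverted (CBV convention)" if contrast == "cbv"
            else "no sign inversion (BOLD convention)"]
    return RoiTimeSeriesSet(data=pd.DataFrame(out),
                            volume_interval=protocol.volume_interval,
                            provenance=prov)


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """GLM design with labelled activity, derivative and drift columns."""

    frame: pd.DataFrame
    activity_columns: list[str]
    derivative_columns: list[str]
    drift_columns: list[str]

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def contrast_for(self, which: str | int = "pooled") -> np.ndarray:
        """Contrast vector selecting activity columns: ``'pooled'`` sums
        all activity columns; an integer selects one block (0-based)."""
        c = np.zeros(len(self.columns))
        if which == "pooled":
            for col in self.activity_columns:
                c[self.columns.index(col)] = 1.0 / len(self.activity_columns)
        else:
            c[self.columns.index(self.activity_columns[int(which)])] = 1.0
        return c


def build_design(protocol: StimProtocol, hrf: GammaHRF | None = None,
                 poly_order: int = 2, per_block: bool = False) -> DesignMatrix:
    """Boxcar (x) HRF activity regressors + temporal derivatives +
    Legendre drift columns up to ``poly_order``.

    Activity columns are peak-normalised; derivatives are the finite
    difference of their activity column; Legendre drift polynomials are
    orthogonal to the constant term by construction.
    """
    hrf = hrf or GammaHRF()
    acts = block_regressors(protocol, hrf, per_block=per_block)
    n = protocol.n_volumes
    cols, act_names, der_names, drift_names = {}, [], [], []
    for i in range(acts.shape[1]):
        name = f"block{i + 1}" if per_block else "stim"
        cols[name] = acts[:, i]
        act_names.append(name)
    for name in act_names:
        d = np.diff(cols[name], prepend=cols[name][0])
        cols[f"d_{name}"] = d
        der_names.append(f"d_{name}")
    x = np.linspace(-1.0, 1.0, n)
    for p in range(poly_order + 1):
        coefs = np.zeros(p + 1)
        coefs[p] = 1.0
        col = legendre.legval(x, coefs)
        if p > 0:
            col = col - col.mean()   # exact orthogonality on the sampled grid
        cols[f"poly{p}"] = col
        drift_names.append(f"poly{p}")
    frame = pd.DataFrame(cols)
    X = frame.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [frame.columns[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-8 * abs(r[0, 0])]
        raise HemoError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(frame=frame, activity_columns=act_names,
                        derivative_columns=der_names, drift_columns=drift_names)


# ---------------------------------------------------------------------------
# GLM model / results


class BlockDesignGLM:
    """Ordinary-least-squares block-design GLM over an ROI series set.

    Parameters
    ----------
    series
        Preprocessed percent-change signals (:class:`RoiTimeSeriesSet`
        or a plain volumes x ROIs data frame).
    design
        A :class:`DesignMatrix` whose rows match the series' volumes.
    """

    def __init__(self, series: RoiTimeSeriesSet | pd.DataFrame,
                 design: DesignMatrix):
        data = series.data if isinstance(series, RoiTimeSeriesSet) else series
        if len(data) != len(design.frame):
            raise HemoError(f"design rows ({len(design.frame)}) must equal "
                            f"series volumes ({len(data)})")
        self.data = data
        self.design = design

    @classmethod
    def from_protocol(cls, series, protocol: StimProtocol,
                      hrf: GammaHRF | None = None, poly_order: int = 2,
                      per_block: bool = False) -> "BlockDesignGLM":
        return cls(series, build_design(protocol, hrf, poly_order, per_block))

    def fit(self) -> "BlockDesignGLMResults":
        X = self.design.matrix
        Y = self.data.to_numpy(dtype=float)
        xtx = X.T @ X
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError as exc:
            raise HemoError("singular design matrix") from exc
        beta = xtx_inv @ X.T @ Y
        resid = Y - X @ beta
        df = X.shape[0] - X.shape[1]
        sigma2 = (resid ** 2).sum(axis=0) / df
        return BlockDesignGLMResults(model=self, params=beta, resid=resid,
                                     sigma2=sigma2, xtx_inv=xtx_inv, df_resid=df)


class BlockDesignGLMResults:
    """Fitted block-design GLM: coefficients, contrasts, diagnostics."""

    def __init__(self, model: BlockDesignGLM, params: np.ndarray,
                 resid: np.ndarray, sigma2: np.ndarray, xtx_inv: np.ndarray,
                 df_resid: int):
        self.model = model
        self._params = params
        self.resid = resid
        self.sigma2 = sigma2
        self.xtx_inv = xtx_inv
        self.df_resid = df_resid

    @property
    def rois(self) -> list[str]:
        return list(self.model.data.columns)

    @property
    def params(self) -> pd.DataFrame:
        return pd.DataFrame(self._params, index=self.model.design.columns,
                            columns=self.rois)

    def cope(self, contrast: np.ndarray | str | int = "pooled") -> pd.DataFrame:
        """Contrast-of-parameter-estimates table: cope, se, t per ROI."""
        c = (self.model.design.contrast_for(contrast)
             if isinstance(contrast, (str, int)) else np.asarray(contrast, float))
        if c.size != self._params.shape[0]:
            raise HemoError("contrast length must equal the design column count")
        cope = c @ self._params
        var = self.sigma2 * float(c @ self.xtx_inv @ c)
        se = np.sqrt(var)
        table = pd.DataFrame({"cope": cope, "se": se, "t": cope / se},
                             index=pd.Index(self.rois, name="roi"))
        table.attrs["contrast"] = np.array2string(c, precision=3)
        return table

    def blockwise_amplitudes(self) -> pd.DataFrame:
        """Per-block response amplitude estimates (% change), blocks x ROIs.

        Requires a per-block design.
        """
        acts = self.model.design.activity_columns
        if len(acts) < 2:
            raise HemoError("blockwise amplitudes need a per-block design")
        rows = [self.cope(i)["cope"] for i in range(len(acts))]
        return pd.DataFrame(rows, index=acts)

    def residual_diagnostics(self) -> pd.DataFrame:
        """Lag-1 residual autocorrelation and stimulus-locked residual
        variance fraction per ROI (a well-specified model leaves both
        near zero)."""
        r = self.resid
        lag1 = np.array([np.corrcoef(r[:-1, j], r[1:, j])[0, 1]
                         for j in range(r.shape[1])])
        act = self.model.design.frame[self.model.design.activity_columns].sum(axis=1)
        act = (act - act.mean()).to_numpy()
        denom = (r ** 2).sum(axis=0) * (act ** 2).sum()
        stim_locked = (r.T @ act) ** 2 / np.where(denom > 0, denom, np.inf)
        return pd.DataFrame({"lag1_autocorr": lag1,
                             "stim_locked_r2": stim_locked},
                            index=pd.Index(self.rois, name="roi"))

    def summary(self) -> str:
        table = self.cope("pooled")
        lines = ["Block-design GLM (OLS)",
                 f"  volumes: {len(self.model.data)}, "
                 f"design columns: {len(self.model.design.columns)}, "
                 f"df_resid: {self.df_resid}",
                 f"  contrast: pooled activity",
                 table.to_string(float_format=lambda v: f"{v: .4f}")]
        return "\n".join(lines)

    def plot_fit(self, roi: str, ax=None):
        """Observed vs fitted series for one ROI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.data[roi].to_numpy()
        j = self.rois.index(roi)
        fitted = self.model.design.matrix @ self._params[:, j]
        ax.plot(y, lw=0.8, label="observed")
        ax.plot(fitted, lw=1.2, label="fitted")
        ax.set_xlabel("volume")
        ax.set_ylabel("% change")
        ax.set_title(roi)
        ax.legend()
        return ax


def fit_glm(series, design: DesignMatrix,
            contrast: np.ndarray | str | int = "pooled") -> pd.DataFrame:
    """Convenience: fit the GLM and return the COPE table."""
    return BlockDesignGLM(series, design).fit().cope(contrast)


def blockwise_amplitudes(series, protocol: StimProtocol,
                         hrf: GammaHRF | None = None,
                         poly_order: int = 2) -> pd.DataFrame:
    """Per-block amplitude estimates from a per-block design."""
    model = BlockDesignGLM.from_protocol(series, protocol, hrf=hrf,
                                         poly_order=poly_order, per_block=True)
    return model.fit().blockwise_amplitudes()


# ---------------------------------------------------------------------------
# motion and smoothing


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm) then 3
    rotations (rad)."""

    params: np.ndarray      # volumes x 6

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise HemoError("motion parameters must be volumes x 6")


@dataclass
class FDResult:
    fd: np.ndarray
    mean: float
    sd: float


def framewise_displacement(motion: MotionTrace | np.ndarray,
                           rotation_radius_mm: float = 5.0) -> FDResult:
    """Frame-wise displacement: FD_t = sum|d translations| +
    radius * sum|d rotations| (rotations converted to arc length on a
    sphere of the given radius)."""
    if rotation_radius_mm <= 0:
        raise HemoError("rotation radius must be positive")
    params = motion.params if isinstance(motion, MotionTrace) \
        else MotionTrace(np.asarray(motion)).params
    if params.shape[0] < 2:
        raise HemoError("need at least 2 volumes for frame-wise displacement")
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return FDResult(fd=fd, mean=float(fd.mean()), sd=float(fd.std(ddof=1)))


def smooth_map(volume: np.ndarray, voxel_size_mm: float,
               fwhm_mm: float = 0.45) -> np.ndarray:
    """Gaussian-smooth a volumetric map to the target FWHM (mm).

    If the FWHM is below the voxel size the map is passed through
    unchanged with a warning.
    """
    if voxel_size_mm <= 0:
        raise HemoError("voxel size must be positive")
    if fwhm_mm < voxel_size_mm:
        warnings.warn("requested FWHM is below the voxel size; map passed "
                      "through unsmoothed", stacklevel=2)
        return np.array(volume, dtype=float, copy=True)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma)
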