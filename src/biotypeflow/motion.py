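"""Motion quality control and functional-connectivity construction.

Implements the scrubbing stage of the pipeline: frame-wise displacement
(FD) and DVARS computation from realignment parameters and BOLD series,
threshold-based frame censoring with neighbour expansion and
short-segment removal, temporal band-pass filtering, Pearson FC vectors
over uncensored frames, and linear covariate residualization fitted on
the training split only.

Conventions
-----------
* FD(t) is the sum of the six absolute frame-to-frame differences of the
  realignment parameters; rotations are converted from radians to an
  arc-length displacement on a sphere of radius 50 mm by default, so FD
  is in mm throughout and comparable to the 0.2 mm threshold.
* DVARS(t) is the root of the across-unit mean of squared frame-to-frame
  intensity differences, on whatever intensity scale the panel carries
  (% BOLD change in the intended use).
* Both series are defined as 0 at the first frame, where no backward
  difference exists.
* FC vectors enumerate the strict upper triangle of the ROI correlation
  matrix row-major (0,1), (0,2), ..., (R-2,R-1); for R ROIs the vector
  has R(R-1)/2 entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

DEFAULT_FD_THRESH = 0.2  # mm
DEFAULT_DVARS_THRESH = 75.0
ROTATION_RADIUS_MM = 50.0


class InsufficientFramesError(ValueError):
    """Raised when too few uncensored frames remain to compute FC."""


@dataclass(frozen=True)
class MotionTrace:
    """Six rigid-body realignment parameters per frame.

    Translations ``dx, dy, dz`` are in mm; rotations ``alpha, beta,
    gamma`` in radians.  ``tr`` is the frame period in seconds.
    """

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    tr: float = 0.72

    def __post_init__(self) -> None:
        arrays = [self.dx, self.dy, self.dz, self.alpha, self.beta, self.gamma]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("all six motion series must have equal length")
        if lengths.pop() < 2:
            raise ValueError("motion trace needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return len(self.dx)

    def as_matrix(self) -> np.ndarray:
        """Frames x 6 matrix in (dx, dy, dz, alpha, beta, gamma) order."""
        return np.column_stack(
            [self.dx, self.dy, self.dz, self.alpha, self.beta, self.gamma]
        )


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Frames x units BOLD intensities (% BOLD) with frame period ``tr``."""

    data: np.ndarray
    tr: float = 0.72

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("time-series panel must be 2-D (frames x units)")
        if data.shape[0] < 2:
            raise ValueError("time-series panel needs at least 2 frames")
        if not np.isfinite(data).all():
            raise ValueError("time-series panel contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class CensorMask:
    """Per-frame keep/censor flags; ``kept`` is True where a frame survives."""

    kept: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "kept", np.asarray(self.kept, dtype=bool))

    @property
    def n_frames(self) -> int:
        return len(self.kept)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def n_censored(self) -> int:
        """Count of censored frames — the head-motion covariate."""
        return self.n_frames - self.n_kept


def framewise_displacement(
    trace: MotionTrace, rotation_radius_mm: float | None = ROTATION_RADIUS_MM
) -> np.ndarray:
    """Frame-wise displacement in mm-equivalent units.

    FD(t) = |Δdx| + |Δdy| + |Δdz| + |Δα| + |Δβ| + |Δγ|, with the three
    rotational differences scaled by ``rotation_radius_mm`` (arc length
    on a 50 mm sphere by default, the convention of standard scrubbing).
    Pass ``rotation_radius_mm=None`` for the literal unscaled sum of
    angular differences.  FD(0) = 0 by definition.
    """
    mat = trace.as_matrix()
    diffs = np.abs(np.diff(mat, axis=0))
    radius = 1.0 if rotation_radius_mm is None else float(rotation_radius_mm)
    fd = diffs[:, :3].sum(axis=1) + radius * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def dvars(panel: TimeSeriesPanel) -> np.ndarray:
    """Root mean square (across units) of frame-to-frame intensity change.

    DVARS(t) = sqrt(mean_units (I(t) - I(t-1))^2), DVARS(0) = 0.
    """
    diffs = np.diff(panel.data, axis=0)
    out = np.sqrt(np.mean(diffs**2, axis=1))
    return np.concatenate([[0.0], out])


def censor_frames(
    fd: np.ndarray,
    dvars_series: np.ndarray,
    fd_thresh: float = DEFAULT_FD_THRESH,
    dvars_thresh: float = DEFAULT_DVARS_THRESH,
    n_before: int = 1,
    n_after: int = 2,
    min_segment: int = 5,
    censor_first: bool = False,
) -> CensorMask:
    """Build a censor mask from FD and DVARS series.

    A frame t is an outlier when FD(t) > ``fd_thresh`` or DVARS(t) >
    ``dvars_thresh``; each outlier censors frames [t - n_before,
    t + n_after] clipped to the run; surviving contiguous runs shorter
    than ``min_segment`` frames are then censored too.  The result is a
    fixed point of the rules (re-applying them changes nothing).
    """
    fd = np.asarray(fd, dtype=float)
    dvars_series = np.asarray(dvars_series, dtype=float)
    if fd.shape != dvars_series.shape:
        raise ValueError("FD and DVARS series must have the same length")
    n = len(fd)
    censored = np.zeros(n, dtype=bool)
    outliers = np.flatnonzero((fd > fd_thresh) | (dvars_series > dvars_thresh))
    for t in outliers:
        censored[max(0, t - n_before) : min(n, t + n_after + 1)] = True
    if censor_first and n > 0:
        censored[0] = True
    # short-segment rule: kept runs of < min_segment contiguous frames go too
    kept = ~censored
    boundaries = np.flatnonzero(np.diff(np.concatenate([[0], kept.view(np.int8), [0]])))
    for start, stop in zip(boundaries[::2], boundaries[1::2]):
        if stop - start < min_segment:
            censored[start:stop] = True
    return CensorMask(kept=~censored)


def bandpass(
    panel: TimeSeriesPanel,
    low: float = 0.009,
    high: float = 0.08,
    order: int = 4,
) -> TimeSeriesPanel:
    """Zero-phase Butterworth band-pass of every unit's time course.

    Retains fluctuations in (``low``, ``high``) Hz and removes the mean;
    applied forward-backward (``sosfiltfilt``) so no phase distortion is
    introduced.
    """
    nyquist = 0.5 / panel.tr
    if high >= nyquist:
        raise ValueError(
            f"band edge {high} Hz is not below the Nyquist frequency {nyquist:.4f} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / panel.tr, output="sos")
    demeaned = panel.data - panel.data.mean(axis=0, keepdims=True)
    filtered = signal.sosfiltfilt(sos, demeaned, axis=0)
    return TimeSeriesPanel(data=filtered, tr=panel.tr)


def fc_index_pairs(n_roi: int) -> tuple[np.ndarray, np.ndarray]:
    """ROI index pairs (i, j), i < j, in the row-major vectorization order."""
    return np.triu_indices(n_roi, k=1)


def n_fc_features(n_roi: int) -> int:
    """Length of the vectorized upper-triangular FC for ``n_roi`` regions."""
    return n_roi * (n_roi - 1) // 2


def fc_vector(
    panel: TimeSeriesPanel,
    mask: CensorMask | None = None,
    min_kept: int = 3,
) -> np.ndarray:
    """Pearson FC vector over uncensored frames.

    Correlates every ROI pair using only the kept frames of ``mask`` and
    returns the strict upper triangle row-major.  Subjects with fewer
    than ``min_kept`` surviving frames cannot yield a stable correlation
    and raise :class:`InsufficientFramesError` so callers can exclude
    them, mirroring image-quality exclusions in real cohorts.
    """
    data = panel.data
    if mask is not None:
        if mask.n_frames != panel.n_frames:
            raise ValueError("censor mask length does not match panel frames")
        data = data[mask.kept]
    if data.shape[0] < min_kept:
        raise InsufficientFramesError(
            f"only {data.shape[0]} uncensored frames (< {min_kept}); subject excluded"
        )
    if data.shape[1] < 2:
        raise ValueError("need at least 2 ROIs for FC")
    corr = np.corrcoef(data, rowvar=False)
    iu, ju = fc_index_pairs(data.shape[1])
    return np.clip(corr[iu, ju], -1.0, 1.0)


@dataclass
class ResidualModel:
    """Training-split linear model removing age, sex and head motion.

    For each FC feature an ordinary least-squares fit on the training
    subjects regresses the feature on the three covariates (centred at
    their training means), so the intercept equals the training feature
    mean.  Applying the model subtracts only the covariate part; the
    training mean is retained.  Validation and replication data are
    adjusted with the *training* coefficients, never refit.
    """

    covariate_names: tuple[str, ...] = ("age", "sex", "motion")
    coef_: np.ndarray | None = None  # n_covariates x n_features
    covariate_means_: np.ndarray | None = None
    feature_means_: np.ndarray | None = None
    _fitted: bool = field(default=False, repr=False)

    def fit(self, fc: np.ndarray, covariates: np.ndarray) -> "ResidualModel":
        fc = np.asarray(fc, dtype=float)
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim != 2 or cov.shape[1] != len(self.covariate_names):
            raise ValueError(
                f"covariates must be n_subjects x {len(self.covariate_names)}"
            )
        if cov.shape[0] != fc.shape[0]:
            raise ValueError("covariate rows must match FC rows")
        self.covariate_means_ = cov.mean(axis=0)
        self.feature_means_ = fc.mean(axis=0)
        centred = cov - self.covariate_means_
        design = np.column_stack([np.ones(len(centred)), centred])
        beta, *_ = np.linalg.lstsq(design, fc, rcond=None)
        self.coef_ = beta[1:]  # drop the intercept row (= feature means)
        self._fitted = True
        return self

    def transform(self, fc: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("ResidualModel must be fitted on the training split first")
        fc = np.asarray(fc, dtype=float)
        centred = np.asarray(covariates, dtype=float) - self.covariate_means_
        return fc - centred @ self.coef_

    def fit_transform(self, fc: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        return self.fit(fc, covariates).transform(fc, covariates)


def fit_residual_model(train_fc: np.ndarray, train_covariates: np.ndarray) -> ResidualModel:
    """Fit the covariate-removal model on the training split."""
    return ResidualModel().fit(train_fc, train_covariates)


def apply_residual_model(
    model: ResidualModel, fc: np.ndarray, covariates: np.ndarray
) -> np.ndarray:
    """Adjust any split's FC panel with training-split coefficients."""
    return model.transform(fc, covariates)
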