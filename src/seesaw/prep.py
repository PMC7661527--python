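"""Temporal preprocessing of resting-state BOLD data.

Implements the temporal half of a standard resting-state pipeline: discard of
initial non-equilibrium frames, linear detrending, ideal band-pass filtering
(0.01-0.08 Hz), construction of the Friston 24-parameter motion confound set,
and ordinary-least-squares nuisance regression (global / white-matter / CSF
signals, motion terms).  Spatial preprocessing (slice timing, realignment, MNI
normalisation) is assumed done upstream; an optional Gaussian smoother is
provided as a utility.

All operations accept either a plain 1-D timeseries or a :class:`VolumeSeries`
(4-D array + affine); voxelwise application commutes with timeseries
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeSeries",
    "MotionParams",
    "ConfoundMatrix",
    "discard_initial_frames",
    "linear_detrend",
    "bandpass_filter",
    "friston24",
    "regress_nuisance",
    "extract_mean_signal",
    "gaussian_smooth",
    "preprocess",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VolumeSeries:
    """A 4-D BOLD series: ``data[x, y, z, t]`` with a voxel->MNI-mm affine.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD signal, arbitrary units.
    affine : ndarray, shape (4, 4)
        Invertible voxel-index -> MNI-millimetre transform.
    tr : float
        Seconds per frame.
    brain_mask : ndarray of bool, shape (x, y, z), optional
        Restricts voxelwise operations when present.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float = 2.0
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries.data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("VolumeSeries needs at least 2 frames")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError("brain_mask shape does not match spatial dims")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MotionParams:
    """Rigid-body motion parameters: t x 6 (3 translations mm, 3 rotations rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 6:
            raise ValueError(
                f"motion parameters must have 6 columns, got {self.values.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_rp_file(cls, path) -> "MotionParams":
        """Read an SPM-style whitespace-delimited ``rp_*.txt`` file."""
        return cls(np.loadtxt(path, ndmin=2))


@dataclass
class ConfoundMatrix:
    """Named nuisance regressors, t x k."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.names:
            self.names = [f"confound_{i}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per confound column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("confound column names must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def hstack(self, other: "ConfoundMatrix") -> "ConfoundMatrix":
        if other.n_frames != self.n_frames:
            raise ValueError("confound row counts differ")
        return ConfoundMatrix(
            np.hstack([self.values, other.values]), self.names + other.names
        )

    def drop(self, name: str) -> "ConfoundMatrix":
        if name not in self.names:
            raise KeyError(name)
        keep = [i for i, n in enumerate(self.names) if n != name]
        return ConfoundMatrix(self.values[:, keep], [self.names[i] for i in keep])


def _frames_last(x):
    """Return (2-D array with time on axis -1, reshaper back to input shape)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], lambda a: a[0]
    flat = x.reshape(-1, x.shape[-1])
    return flat, lambda a: a.reshape(x.shape)


def discard_initial_frames(series, n_discard: int):
    """Drop the first ``n_discard`` frames (magnetisation equilibration).

    Accepts a :class:`VolumeSeries` or an array whose last axis is time and
    returns the same type, shortened.  Discarding all frames is an error.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if isinstance(series, VolumeSeries):
        if n_discard >= series.n_frames:
            raise ValueError(
                f"cannot discard {n_discard} of {series.n_frames} frames"
            )
        return replace(series, data=series.data[..., n_discard:])
    x = np.asarray(series, dtype=float)
    if n_discard >= x.shape[-1]:
        raise ValueError(f"cannot discard {n_discard} of {x.shape[-1]} frames")
    return x[..., n_discard:]


def linear_detrend(x):
    """OLS residual of each timeseries on [intercept, linear ramp]."""
    if isinstance(x, VolumeSeries):
        return replace(x, data=linear_detrend(x.data))
    flat, back = _frames_last(x)
    t = flat.shape[-1]
    if t < 3:
        raise ValueError("linear_detrend requires at least 3 frames")
    ramp = np.arange(t, dtype=float)
    design = np.column_stack([np.ones(t), ramp])
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    return back(flat - (design @ beta).T)


def bandpass_filter(x, tr: float, f_low: float = 0.01, f_high: float = 0.08):
    """Ideal (frequency-domain boxcar) band-pass filter.

    DFT components with frequency in ``[f_low, f_high]`` (inclusive band
    edges) are retained; everything else, including the 0-Hz mean, is zeroed.
    """
    if isinstance(x, VolumeSeries):
        return replace(x, data=bandpass_filter(x.data, x.tr, f_low, f_high))
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= f_low < f_high):
        raise ValueError("need 0 <= f_low < f_high")
    if f_high > nyquist + 1e-12:
        raise ValueError(f"f_high={f_high} exceeds Nyquist {nyquist}")
    flat, back = _frames_last(x)
    t = flat.shape[-1]
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= f_low - 1e-12) & (freqs <= f_high + 1e-12)
    spec = np.fft.rfft(flat, axis=-1)
    spec[..., ~keep] = 0.0
    return back(np.fft.irfft(spec, n=t, axis=-1))


def friston24(motion: MotionParams | np.ndarray) -> ConfoundMatrix:
    """Friston 24-parameter motion confound set.

    Column order: the 6 parameters R(t); their one-frame lag R(t-1) (first
    frame zero-padded); R(t)^2; R(t-1)^2.
    """
    if not isinstance(motion, MotionParams):
        motion = MotionParams(motion)
    r = motion.values
    lag = np.vstack([np.zeros((1, 6)), r[:-1]])
    values = np.hstack([r, lag, r**2, lag**2])
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = (
        base
        + [f"{n}_lag" for n in base]
        + [f"{n}_sq" for n in base]
        + [f"{n}_lag_sq" for n in base]
    )
    return ConfoundMatrix(values, names)


def _ols_residual(y: np.ndarray, design: np.ndarray, names: list[str]) -> np.ndarray:
    """Residual of y (n x m) on design (n x k); errors on rank deficiency."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns by greedy rank check
        bad = []
        cols: list[int] = []
        for j in range(design.shape[1]):
            trial = design[:, cols + [j]]
            if np.linalg.matrix_rank(trial) > len(cols):
                cols.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def regress_nuisance(x, confounds: ConfoundMatrix, include_global: bool = True):
    """OLS residual of each timeseries on the confound set plus an intercept.

    ``include_global=False`` drops the column named ``"global"`` (if present),
    realising the no-GSR replication stream.  The residual is numerically
    orthogonal to every retained confound column.
    """
    if isinstance(x, VolumeSeries):
        return replace(x, data=regress_nuisance(x.data, confounds, include_global))
    conf = confounds
    if not include_global and "global" in conf.names:
        conf = conf.drop("global")
    flat, back = _frames_last(x)
    t = flat.shape[-1]
    if conf.n_frames != t:
        raise ValueError(
            f"confound rows ({conf.n_frames}) != frame count ({t})"
        )
    design = np.column_stack([np.ones(t), conf.values])
    resid = _ols_residual(flat.T, design, ["intercept"] + conf.names).T
    return back(resid)


def extract_mean_signal(series: VolumeSeries, mask: np.ndarray) -> np.ndarray:
    """Per-frame arithmetic mean of the in-mask voxel timeseries."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.data.shape[:3]:
        raise ValueError("mask shape does not match volume spatial dims")
    if not mask.any():
        raise ValueError("empty mask")
    return series.data[mask].mean(axis=0)


def gaussian_smooth(series: VolumeSeries, fwhm_mm: float = 6.0) -> VolumeSeries:
    """Per-frame 3-D Gaussian smoothing, sigma = fwhm / (2 sqrt(2 ln 2)).

    Requires isotropic voxels (anisotropic grids are out of scope).  Returns
    the smoothed series together with the sigma actually used (mm) as the
    attribute ``sigma_mm`` on the returned object is not kept; use
    :func:`smoothing_sigma_mm` for the closed form.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    vox = series.voxel_size_mm()
    if not np.allclose(vox, vox[0], rtol=1e-6):
        raise ValueError(f"anisotropic voxels {vox} not supported")
    sigma_vox = smoothing_sigma_mm(fwhm_mm) / vox[0]
    out = np.empty_like(series.data)
    for t in range(series.n_frames):
        ndimage.gaussian_filter(
            series.data[..., t], sigma=sigma_vox, output=out[..., t], mode="nearest"
        )
    return replace(series, data=out)


def smoothing_sigma_mm(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given FWHM: fwhm / (2 sqrt(2 ln 2))."""
    return fwhm_mm * FWHM_TO_SIGMA


def preprocess(
    series,
    confounds: ConfoundMatrix | None = None,
    *,
    tr: float | None = None,
    n_discard: int = 10,
    f_low: float = 0.01,
    f_high: float = 0.08,
    include_global: bool = True,
):
    """Default temporal pipeline: discard -> detrend -> bandpass -> regress.

    Confound rows must already be aligned with the *retained* frames (the
    caller discards motion rows alongside frames, or passes full-length
    confounds which are truncated here from the front).
    """
    is_vol = isinstance(series, VolumeSeries)
    if tr is None:
        if not is_vol:
            raise ValueError("tr required for plain timeseries input")
        tr = series.tr
    out = discard_initial_frames(series, n_discard)
    out = linear_detrend(out)
    out = bandpass_filter(out, tr, f_low, f_high)
    if confounds is not None:
        n = out.n_frames if is_vol else np.asarray(out).shape[-1]
        conf = confounds
        if conf.n_frames == n + n_discard:
            conf = ConfoundMatrix(conf.values[n_discard:], conf.names)
        out = regress_nuisance(out, conf, include_global=include_global)
    return out
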