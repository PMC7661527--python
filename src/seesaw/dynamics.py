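"""Dominance-state dynamics of the DMN/TPN seesaw.

Per frame the brain is labelled DMN-dominant (1) when the DMN network-mean
BOLD signal strictly exceeds the TPN signal, else TPN-dominant (0).  From the
resulting binary indicator the package derives the study's per-subject
statistics: the dominance index (frame count of DMN dominance), the number of
state transitions (indicator changes, equivalently zero crossings of the
DMN-minus-TPN difference series), and the mean dwell time of each state (mean
run length before a switch, censored first/last runs included by default).

The module also implements the BOLD-variability analysis: per-voxel temporal
standard deviation, an MNI box mask for the right fronto-insular cortex
(RFIC), and an across-subject (partial) correlation of a dynamics metric with
voxelwise SD, family-wise corrected by a seeded max-|r| permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import NetworkPair, voxel_centers_mm
from .prep import VolumeSeries

__all__ = [
    "DominanceSummary",
    "BoxMaskSpec",
    "RFIC_BOX",
    "dominance_indicator",
    "dominance_index",
    "difference_vector",
    "count_transitions",
    "run_lengths",
    "mean_dwell_time",
    "average_deviation",
    "summarize_dominance",
    "voxel_sd_map",
    "box_mask",
    "variability_association",
    "VariabilityResult",
]


@dataclass
class DominanceSummary:
    """Per-subject dominance-dynamics statistics.

    ``mean_dwell_*`` are in frames (NaN, flagged, when the state never
    occurs); seconds are frames x TR.  ``ad_*`` are average deviations from
    zero (mean absolute value) of the DMN, TPN and difference series;
    ``anticorr`` is the Pearson correlation between the two series.
    """

    dominance_index: int
    n_transitions: int
    mean_dwell_dmn: float
    mean_dwell_tpn: float
    ad_dmn: float
    ad_tpn: float
    ad_diff: float
    anticorr: float
    n_frames: int
    tr: float
    dmn_absent: bool = False
    tpn_absent: bool = False

    @property
    def mean_dwell_dmn_seconds(self) -> float:
        return self.mean_dwell_dmn * self.tr

    @property
    def mean_dwell_tpn_seconds(self) -> float:
        return self.mean_dwell_tpn * self.tr

    def to_dict(self) -> dict:
        return {
            "dominance_index": self.dominance_index,
            "n_transitions": self.n_transitions,
            "mean_dwell_dmn": self.mean_dwell_dmn,
            "mean_dwell_tpn": self.mean_dwell_tpn,
            "mean_dwell_dmn_seconds": self.mean_dwell_dmn_seconds,
            "mean_dwell_tpn_seconds": self.mean_dwell_tpn_seconds,
            "ad_dmn": self.ad_dmn,
            "ad_tpn": self.ad_tpn,
            "ad_diff": self.ad_diff,
            "anticorr": self.anticorr,
            "n_frames": self.n_frames,
            "tr": self.tr,
        }


@dataclass(frozen=True)
class BoxMaskSpec:
    """Axis-aligned MNI-mm box with inclusive bounds."""

    x_range: tuple[float, float]
    y_range: tuple[float, float]
    z_range: tuple[float, float]

    def __post_init__(self):
        for lo, hi in (self.x_range, self.y_range, self.z_range):
            if lo > hi:
                raise ValueError("box bounds must satisfy min <= max")

    def contains(self, xyz_mm) -> bool:
        x, y, z = xyz_mm
        return (
            self.x_range[0] <= x <= self.x_range[1]
            and self.y_range[0] <= y <= self.y_range[1]
            and self.z_range[0] <= z <= self.z_range[1]
        )


#: Right fronto-insular cortex box (MNI mm).
RFIC_BOX = BoxMaskSpec((27, 48), (0, 28), (-19, 15))


def _as_pair_arrays(pair):
    if isinstance(pair, NetworkPair):
        return pair.dmn_ts, pair.tpn_ts
    dmn, tpn = pair
    dmn = np.asarray(dmn, dtype=float).ravel()
    tpn = np.asarray(tpn, dtype=float).ravel()
    if dmn.shape != tpn.shape:
        raise ValueError("DMN/TPN series lengths differ")
    return dmn, tpn


def dominance_indicator(pair) -> np.ndarray:
    """1 where DMN > TPN (strict; ties count as TPN dominance), else 0."""
    dmn, tpn = _as_pair_arrays(pair)
    return (dmn > tpn).astype(np.int8)


def dominance_index(indicator) -> int:
    """Number of DMN-dominant frames (sum of the indicator)."""
    ind = np.asarray(indicator)
    if not np.isin(ind, (0, 1)).all():
        raise ValueError("indicator must be binary")
    return int(ind.sum())


def difference_vector(pair) -> np.ndarray:
    """DMN series minus TPN series, elementwise."""
    dmn, tpn = _as_pair_arrays(pair)
    return dmn - tpn


def count_transitions(indicator) -> int:
    """Number of frame-to-frame changes of the dominance indicator."""
    ind = np.asarray(indicator)
    if ind.size < 1:
        raise ValueError("indicator must be non-empty")
    return int((ind[1:] != ind[:-1]).sum())


def run_lengths(indicator) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encoding: (state of each run, length of each run)."""
    ind = np.asarray(indicator)
    if ind.size == 0:
        raise ValueError("indicator must be non-empty")
    change = np.flatnonzero(ind[1:] != ind[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [ind.size]])
    return ind[starts], ends - starts


def mean_dwell_time(
    indicator, state: str = "DMN", tr: float = 2.0, include_censored: bool = True
) -> tuple[float, float]:
    """Mean run length of a state, in (frames, seconds).

    The first and last (censored) runs are included by default; set
    ``include_censored=False`` to drop them.  If the state never occurs the
    result is (nan, nan) — a flagged missing value, not an error.
    """
    want = 1 if state.upper() == "DMN" else 0
    states, lengths = run_lengths(indicator)
    if not include_censored and states.size > 2:
        states, lengths = states[1:-1], lengths[1:-1]
    sel = lengths[states == want]
    if sel.size == 0:
        return float("nan"), float("nan")
    frames = float(sel.mean())
    return frames, frames * tr


def average_deviation(x) -> float:
    """Mean absolute value (average deviation from zero)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty input")
    return float(np.abs(x).mean())


def summarize_dominance(pair, tr: float | None = None) -> DominanceSummary:
    """All per-subject dominance statistics for one DMN/TPN pair."""
    dmn, tpn = _as_pair_arrays(pair)
    if tr is None:
        tr = pair.tr if isinstance(pair, NetworkPair) else 2.0
    ind = dominance_indicator((dmn, tpn))
    diff = dmn - tpn
    dwell_dmn, _ = mean_dwell_time(ind, "DMN", tr)
    dwell_tpn, _ = mean_dwell_time(ind, "TPN", tr)
    if np.std(dmn) > 0 and np.std(tpn) > 0:
        anticorr = float(np.corrcoef(dmn, tpn)[0, 1])
    else:
        anticorr = float("nan")
    return DominanceSummary(
        dominance_index=dominance_index(ind),
        n_transitions=count_transitions(ind),
        mean_dwell_dmn=dwell_dmn,
        mean_dwell_tpn=dwell_tpn,
        ad_dmn=average_deviation(dmn),
        ad_tpn=average_deviation(tpn),
        ad_diff=average_deviation(diff),
        anticorr=anticorr,
        n_frames=int(ind.size),
        tr=float(tr),
        dmn_absent=not bool((ind == 1).any()),
        tpn_absent=not bool((ind == 0).any()),
    )


def voxel_sd_map(prep: VolumeSeries | np.ndarray) -> np.ndarray:
    """Per-voxel temporal standard deviation (sample, n-1 denominator)."""
    data = prep.data if isinstance(prep, VolumeSeries) else np.asarray(prep, float)
    if data.shape[-1] < 2:
        raise ValueError("need at least 2 frames")
    return data.std(axis=-1, ddof=1)


def box_mask(spec: BoxMaskSpec, affine: np.ndarray, dims) -> np.ndarray:
    """Voxels whose centre's mm coordinates lie inside the (inclusive) box."""
    centers = voxel_centers_mm(np.asarray(affine), tuple(dims))
    eps = 1e-9
    mask = (
        (centers[..., 0] >= spec.x_range[0] - eps)
        & (centers[..., 0] <= spec.x_range[1] + eps)
        & (centers[..., 1] >= spec.y_range[0] - eps)
        & (centers[..., 1] <= spec.y_range[1] + eps)
        & (centers[..., 2] >= spec.z_range[0] - eps)
        & (centers[..., 2] <= spec.z_range[1] + eps)
    )
    if not mask.any():
        raise ValueError("box does not intersect the grid")
    return mask


@dataclass
class VariabilityResult:
    """Across-subject metric-vs-SD correlation within a mask.

    ``r_map``/``p_corrected_map`` are 3-D with NaN outside the mask;
    ``peak_mm`` is the MNI coordinate of the max-|r| voxel.
    """

    r_map: np.ndarray
    p_corrected_map: np.ndarray
    peak_mm: tuple[float, float, float]
    peak_r: float
    peak_p_corrected: float
    n_subjects: int
    n_perm: int

    @property
    def any_significant(self) -> bool:
        return bool(np.nanmin(self.p_corrected_map) < 0.05)


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = y.shape[0]
    design = np.ones((n, 1))
    if covariates is not None:
        design = np.column_stack([design, covariates])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def variability_association(
    metric,
    sd_maps,
    mask: np.ndarray,
    affine: np.ndarray,
    covariates=None,
    n_perm: int = 5000,
    seed: int = 0,
) -> VariabilityResult:
    """Correlate a per-subject dynamics metric with voxelwise BOLD SD.

    Pearson correlation (partial, when covariates are given, by residualising
    both sides on [intercept, covariates]) is computed across subjects at
    every in-mask voxel.  Family-wise error within the mask is controlled by
    permuting the metric vector and recording the max-|r| null distribution
    (``n_perm`` permutations, seeded); corrected p uses the standard
    (1 + #null >= observed) / (n_perm + 1) estimator.
    """
    metric = np.asarray(metric, dtype=float).ravel()
    n = metric.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.std(metric) == 0:
        raise ValueError("constant metric")
    mask = np.asarray(mask, dtype=bool)
    maps = np.stack(
        [np.asarray(m, dtype=float)[mask] for m in sd_maps], axis=0
    )  # n_subjects x n_voxels
    if maps.shape[0] != n:
        raise ValueError("metric length and number of SD maps differ")
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
    m_res = _residualize(metric[:, None], cov)[:, 0]
    y_res = _residualize(maps, cov)
    m_c = m_res - m_res.mean()
    y_c = y_res - y_res.mean(axis=0)
    m_norm = np.linalg.norm(m_c)
    y_norm = np.linalg.norm(y_c, axis=0)
    y_norm[y_norm == 0] = np.inf  # constant voxels -> r = 0
    r = (y_c.T @ m_c) / (y_norm * m_norm)

    rng = np.random.default_rng(seed)
    null_max = _max_abs_r_null(y_c, m_c, y_norm, m_norm, n_perm, rng)

    abs_r = np.abs(r)
    p_corr = (1.0 + (null_max[None, :] >= abs_r[:, None]).sum(axis=1)) / (n_perm + 1.0)

    r_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    r_map[mask] = r
    p_map[mask] = p_corr
    peak_flat = int(np.argmax(abs_r))
    peak_idx = np.array(np.nonzero(mask)).T[peak_flat]
    peak_mm = tuple(
        float(v) for v in (np.asarray(affine) @ np.append(peak_idx, 1.0))[:3]
    )
    return VariabilityResult(
        r_map=r_map,
        p_corrected_map=p_map,
        peak_mm=peak_mm,
        peak_r=float(r[peak_flat]),
        peak_p_corrected=float(p_corr[peak_flat]),
        n_subjects=n,
        n_perm=n_perm,
    )


def _max_abs_r_null(y_c, m_c, y_norm, m_norm, n_perm, rng, chunk: int = 256):
    """Max-|r| permutation null, exact per-voxel normalisation."""
    n = m_c.size
    out = np.empty(n_perm)
    done = 0
    inv = 1.0 / (y_norm * m_norm)
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perms = np.stack([m_c[rng.permutation(n)] for _ in range(k)], axis=1)
        rs = np.abs(y_c.T @ perms) * inv[:, None]
        out[done : done + k] = rs.max(axis=0)
        done += k
    return out
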