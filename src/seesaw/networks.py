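"""Identify the default-mode and task-positive networks and extract their signals.

Two routes are supported, mirroring the two analysis streams:

* **seed-derived** (GSR stream): a combined mPFC+PCC seed reference timeseries
  is correlated with every voxel, per-subject r maps are Fisher z-transformed,
  and a group one-sample t-test with voxel-level p < 1e-6 plus a 20-voxel
  cluster-extent threshold yields disjoint DMN (t > 0) and TPN (t < 0) masks.
* **predefined-ROI** (no-GSR stream): twelve literature 6-mm spheres (six DMN,
  six TPN) whose per-ROI mean timeseries are averaged within each network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .prep import VolumeSeries, extract_mean_signal

__all__ = [
    "SeedSpec",
    "NetworkMasks",
    "NetworkPair",
    "DEFAULT_SEEDS",
    "sphere_mask",
    "seed_reference_timeseries",
    "correlation_map",
    "fisher_z",
    "group_network_masks",
    "predefined_network_rois",
    "extract_network_pair",
]


@dataclass(frozen=True)
class SeedSpec:
    """A spherical ROI: MNI-mm centre plus radius."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0
    network: str | None = None  # "DMN" | "TPN" for predefined ROIs

    def __post_init__(self):
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")


@dataclass
class NetworkMasks:
    """Disjoint binary DMN and TPN masks on a common grid."""

    dmn: np.ndarray
    tpn: np.ndarray
    affine: np.ndarray
    provenance: str = "seed-derived"  # or "predefined"

    def __post_init__(self):
        self.dmn = np.asarray(self.dmn, dtype=bool)
        self.tpn = np.asarray(self.tpn, dtype=bool)
        if self.dmn.shape != self.tpn.shape:
            raise ValueError("DMN/TPN mask shapes differ")
        if (self.dmn & self.tpn).any():
            raise ValueError("DMN and TPN masks overlap")
        if not self.dmn.any() or not self.tpn.any():
            raise ValueError("network masks must be non-empty")


@dataclass
class NetworkPair:
    """One subject's DMN and TPN mean timeseries."""

    dmn_ts: np.ndarray
    tpn_ts: np.ndarray
    tr: float = 2.0
    stream: str = "GSR"  # "GSR" | "no-GSR"
    provenance: str = "seed-derived"

    def __post_init__(self):
        self.dmn_ts = np.asarray(self.dmn_ts, dtype=float).ravel()
        self.tpn_ts = np.asarray(self.tpn_ts, dtype=float).ravel()
        if self.dmn_ts.shape != self.tpn_ts.shape:
            raise ValueError("DMN/TPN series lengths differ")
        if self.dmn_ts.size < 2:
            raise ValueError("NetworkPair needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.dmn_ts.size


# Combined mPFC+PCC seed used to map both networks (MNI mm, converted from
# the original Talairach report).
DEFAULT_SEEDS = (
    SeedSpec("mPFC_seed", (-2.0, 51.0, -14.0), 6.0),
    SeedSpec("PCC_seed", (-7.0, -46.0, 46.0), 6.0),
)

# Literature ROI centres for the predefined-network route (MNI mm).
_PREDEFINED = [
    ("mPFC", "DMN", (0, 52, -6)),
    ("PCC", "DMN", (0, -53, 26)),
    ("LatPar_L", "DMN", (-48, -62, 36)),
    ("LatPar_R", "DMN", (46, -62, 32)),
    ("HF_L", "DMN", (-24, -22, -20)),
    ("HF_R", "DMN", (24, -20, -22)),
    ("FEF_L", "TPN", (-38, -4, 48)),
    ("FEF_R", "TPN", (40, -4, 48)),
    ("IPS_L", "TPN", (-24, -58, 52)),
    ("IPS_R", "TPN", (22, -58, 54)),
    ("MT+_L", "TPN", (-56, -60, -2)),
    ("MT+_R", "TPN", (54, -58, -4)),
]


def predefined_network_rois() -> list[SeedSpec]:
    """The twelve 6-mm-radius literature ROIs, six per network."""
    return [
        SeedSpec(name, tuple(float(c) for c in xyz), 6.0, network=net)
        for name, net, xyz in _PREDEFINED
    ]


def voxel_centers_mm(affine: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    """MNI-mm coordinates of every voxel centre, shape dims + (3,)."""
    idx = np.indices(dims).reshape(3, -1)
    homog = np.vstack([idx, np.ones(idx.shape[1])])
    mm = (np.asarray(affine) @ homog)[:3]
    return mm.T.reshape(*dims, 3)


def sphere_mask(seed: SeedSpec, affine: np.ndarray, dims) -> np.ndarray:
    """Voxels whose centre lies within ``radius_mm`` of the seed (inclusive)."""
    centers = voxel_centers_mm(affine, tuple(dims))
    d2 = ((centers - np.asarray(seed.center_mm)) ** 2).sum(axis=-1)
    mask = d2 <= seed.radius_mm**2 + 1e-9
    if not mask.any():
        raise ValueError(f"sphere for seed {seed.name!r} contains no voxel")
    return mask


def seed_reference_timeseries(
    prep: VolumeSeries, seeds=DEFAULT_SEEDS
) -> np.ndarray:
    """Average of the per-seed in-sphere mean timeseries.

    The averaging is ROI-wise (mean of seed means), not pooled over voxels,
    so unequal sphere sizes carry equal weight.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed required")
    means = [
        extract_mean_signal(prep, sphere_mask(s, prep.affine, prep.shape[:3]))
        for s in seeds
    ]
    return np.mean(means, axis=0)


def correlation_map(prep: VolumeSeries, ref: np.ndarray) -> np.ndarray:
    """Pearson r of every in-mask voxel's timeseries with ``ref``.

    Constant voxels get r = 0 with a warning; a constant reference is an error.
    """
    ref = np.asarray(ref, dtype=float).ravel()
    if ref.size != prep.n_frames:
        raise ValueError("reference length does not match frame count")
    ref_c = ref - ref.mean()
    ref_norm = np.linalg.norm(ref_c)
    if ref_norm < 1e-12:
        raise ValueError("constant reference timeseries")
    data = prep.data
    mask = (
        prep.brain_mask
        if prep.brain_mask is not None
        else np.ones(data.shape[:3], dtype=bool)
    )
    x = data[mask]
    x_c = x - x.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(x_c, axis=1)
    out = np.zeros(mask.sum())
    ok = x_norm > 1e-12
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} constant voxels set to r=0")
    out[ok] = (x_c[ok] @ ref_c) / (x_norm[ok] * ref_norm)
    rmap = np.zeros(data.shape[:3])
    rmap[mask] = out
    return rmap


def fisher_z(r):
    """Fisher r-to-z: atanh(r), with |r| = 1 clamped to 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    clip = 1.0 - 1e-7
    if (np.abs(r) > clip).any():
        warnings.warn("correlations at |r| >= 1 clamped before atanh")
        r = np.clip(r, -clip, clip)
    return np.arctanh(r)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18, or 26")


def cluster_extent_filter(
    mask: np.ndarray, min_cluster: int, connectivity: int = 26
) -> np.ndarray:
    """Remove connected components smaller than ``min_cluster`` voxels."""
    labels, n = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_cluster) + 1
    return np.isin(labels, keep)


def group_network_masks(
    z_maps,
    affine: np.ndarray,
    voxel_p: float = 1e-6,
    min_cluster: int = 20,
    connectivity: int = 26,
    brain_mask: np.ndarray | None = None,
) -> NetworkMasks:
    """Group one-sample t-test on Fisher-z maps -> thresholded DMN/TPN masks.

    Per voxel a two-sided one-sample t against zero is computed across
    subjects; DMN = {t > 0, p < voxel_p}, TPN = {t < 0, p < voxel_p}; each
    sign map is cluster-extent filtered (components with >= ``min_cluster``
    voxels retained).
    """
    z = np.stack([np.asarray(m, dtype=float) for m in z_maps], axis=0)
    n = z.shape[0]
    if n < 3:
        raise ValueError("group test requires at least 3 subjects")
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    sig = p < voxel_p
    if brain_mask is not None:
        sig &= np.asarray(brain_mask, dtype=bool)
    dmn = cluster_extent_filter(sig & (t > 0), min_cluster, connectivity)
    tpn = cluster_extent_filter(sig & (t < 0), min_cluster, connectivity)
    if not dmn.any() or not tpn.any():
        raise ValueError(
            "no voxels survive thresholding "
            f"(pre-extent: DMN {int((sig & (t > 0)).sum())}, "
            f"TPN {int((sig & (t < 0)).sum())} voxels; "
            f"voxel_p={voxel_p}, min_cluster={min_cluster})"
        )
    return NetworkMasks(dmn, tpn, np.asarray(affine), provenance="seed-derived")


def extract_network_pair(
    prep: VolumeSeries,
    masks_or_rois,
    stream: str = "GSR",
) -> NetworkPair:
    """Extract the per-subject DMN and TPN mean timeseries.

    With :class:`NetworkMasks` (seed-derived) the mean is voxelwise within
    each binary mask; with a list of labelled :class:`SeedSpec` ROIs
    (predefined) it is the mean of per-ROI means within each network.
    """
    if isinstance(masks_or_rois, NetworkMasks):
        dmn_ts = extract_mean_signal(prep, masks_or_rois.dmn)
        tpn_ts = extract_mean_signal(prep, masks_or_rois.tpn)
        provenance = masks_or_rois.provenance
    else:
        rois = list(masks_or_rois)
        by_net: dict[str, list[np.ndarray]] = {"DMN": [], "TPN": []}
        for roi in rois:
            if roi.network not in by_net:
                raise ValueError(f"ROI {roi.name!r} lacks a DMN/TPN network label")
            m = sphere_mask(roi, prep.affine, prep.shape[:3])
            by_net[roi.network].append(extract_mean_signal(prep, m))
        if not by_net["DMN"] or not by_net["TPN"]:
            raise ValueError("need at least one ROI per network")
        dmn_ts = np.mean(by_net["DMN"], axis=0)
        tpn_ts = np.mean(by_net["TPN"], axis=0)
        provenance = "predefined"
    return NetworkPair(dmn_ts, tpn_ts, tr=prep.tr, stream=stream, provenance=provenance)
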