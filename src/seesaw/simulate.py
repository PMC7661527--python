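"""Seeded synthetic data with the statistical structure the analysis assumes.

The latent dominance process is a two-state first-order Markov chain (state 1
= DMN-dominant) whose per-frame stay probabilities set geometric dwell-time
distributions; an optional fixed-dwell mode stress-tests dwell estimation.
Network timeseries are the mapped states (+a for the dominant network, -a for
the suppressed one) plus independent AR(1)-plus-white noise.  Cohorts add
behavioral scores with a planted dwell-anxiety correlation and an
anxiety-depression comorbidity correlation; the volume generator plants DMN,
TPN and RFIC blobs (RFIC white-noise SD coupled to the subject's transition
count) plus WM/CSF reference regions on a small 3-mm grid.

Every output is a pure function of (config, seed); planted parameters are
returned as a :class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import count_transitions, mean_dwell_time, summarize_dominance
from .inference import CohortTable, SubjectRecord
from .networks import NetworkPair, SeedSpec
from .prep import VolumeSeries

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "VolumeGeometry",
    "simulate_state_sequence",
    "simulate_state_sequences",
    "simulate_network_pair",
    "simulate_cohort",
    "simulate_volumes",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generators (defaults = study conditions).

    ``n_frames`` and ``tr`` default to the analysed acquisition (232 frames
    at TR = 2 s).  ``p_stay_*`` are per-frame stay probabilities of the
    latent chain (0.9 gives a mean dwell of 10 frames).  ``behavior_coupling``
    is the planted population correlation between standardized mean DMN dwell
    and the anxiety score; ``comorbidity`` the planted anxiety-depression
    correlation (0.60, the observed comorbidity).  ``rfic_coupling`` is the
    slope of the planted RFIC noise SD on the subject's transition count.
    """

    n_subjects: int = 287
    n_frames: int = 232
    tr: float = 2.0
    p_stay_dmn: float = 0.9
    p_stay_tpn: float = 0.9
    signal_amplitude: float = 1.0
    noise_sd: float = 0.3
    ar1_coefficient: float = 0.3
    behavior_coupling: float = 0.3
    comorbidity: float = 0.60
    rfic_coupling: float = 0.02
    rfic_base_sd: float = 0.5
    sas_mean: float = 34.0
    sas_sd: float = 6.7
    sds_mean: float = 31.0
    sds_sd: float = 6.0
    grid_dims: tuple[int, int, int] = (24, 24, 18)
    voxel_mm: float = 3.0
    grid_origin_vox: tuple[float, float, float] = (-10.0, -12.0, -8.0)
    fixed_dwell: int | None = None
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_stay_dmn, self.p_stay_tpn):
            if not 0.0 <= p < 1.0:
                raise ValueError("stay probabilities must lie in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if abs(self.behavior_coupling) >= 1.0 or abs(self.comorbidity) >= 1.0:
            raise ValueError("planted correlations must satisfy |rho| < 1")
        if not -1.0 < self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in (-1, 1)")

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        aff[:3, 3] = np.asarray(self.grid_origin_vox) * self.voxel_mm
        return aff


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    config: GeneratorConfig
    states: np.ndarray  # n_subjects x n_frames, 1 = DMN-dominant
    n_transitions: np.ndarray
    mean_dwell_dmn: np.ndarray
    anxiety_latent: np.ndarray
    depression_latent: np.ndarray
    rfic_sd: np.ndarray | None = None
    geometry: "VolumeGeometry | None" = None
    seed: int = 0


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def simulate_state_sequence(
    n_frames: int, p_stay_dmn: float, p_stay_tpn: float, seed
) -> np.ndarray:
    """One two-state Markov chain realisation (1 = DMN-dominant)."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    return simulate_state_sequences(1, n_frames, p_stay_dmn, p_stay_tpn, rng)[0]


def simulate_state_sequences(
    n_seq: int, n_frames: int, p_stay_dmn: float, p_stay_tpn: float, seed,
    fixed_dwell: int | None = None,
) -> np.ndarray:
    """Matrix of ``n_seq`` independent chains, initial state Bernoulli(0.5).

    ``fixed_dwell`` switches to the deterministic-dwell (semi-Markov) mode:
    every run lasts exactly that many frames.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    if fixed_dwell is not None:
        first = rng.integers(0, 2, size=n_seq)
        block = np.arange(n_frames) // int(fixed_dwell)
        return ((first[:, None] + block[None, :]) % 2).astype(np.int8)
    states = np.empty((n_seq, n_frames), dtype=np.int8)
    states[:, 0] = rng.integers(0, 2, size=n_seq)
    u = rng.random((n_seq, n_frames - 1))
    for t in range(1, n_frames):
        prev = states[:, t - 1]
        stay = np.where(prev == 1, p_stay_dmn, p_stay_tpn)
        states[:, t] = np.where(u[:, t - 1] < stay, prev, 1 - prev)
    return states


def _ar1_plus_white(shape, phi: float, total_sd: float, rng) -> np.ndarray:
    """AR(1) + white noise, each carrying half the total variance."""
    if total_sd == 0:
        return np.zeros(shape)
    var_half = 0.5 * total_sd**2
    white = rng.normal(0.0, np.sqrt(var_half), size=shape)
    innov_sd = np.sqrt(var_half * (1.0 - phi**2))
    eps = rng.normal(0.0, innov_sd, size=shape)
    ar = np.empty(shape)
    ar[..., 0] = rng.normal(0.0, np.sqrt(var_half), size=shape[:-1])
    for t in range(1, shape[-1]):
        ar[..., t] = phi * ar[..., t - 1] + eps[..., t]
    return ar + white


def simulate_network_pair(states, config: GeneratorConfig, seed) -> NetworkPair:
    """DMN/TPN series for one subject: +-amplitude times state, plus noise."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    s = 2.0 * np.asarray(states, dtype=float) - 1.0  # {0,1} -> {-1,+1}
    a = config.signal_amplitude
    noise = _ar1_plus_white((2, s.size), config.ar1_coefficient, config.noise_sd, rng)
    return NetworkPair(
        dmn_ts=a * s + noise[0],
        tpn_ts=-a * s + noise[1],
        tr=config.tr,
        stream="GSR",
        provenance="synthetic",
    )


def simulate_cohort(
    config: GeneratorConfig,
) -> tuple[CohortTable, list[NetworkPair], SyntheticTruth]:
    """A full behavioral cohort with planted dwell-anxiety coupling.

    The anxiety score is a linear function of the standardized (within
    cohort) mean DMN dwell plus Gaussian noise scaled so the planted
    population correlation equals ``behavior_coupling``; depression is
    generated with correlation ``comorbidity`` to the anxiety latent.  Both
    are affinely mapped to the 20-80 scale range and rounded to integers.
    """
    cfg = config
    n = cfg.n_subjects
    rng = _rng(cfg.seed, 1)
    states = simulate_state_sequences(
        n, cfg.n_frames, cfg.p_stay_dmn, cfg.p_stay_tpn, rng, cfg.fixed_dwell
    )
    noise = _ar1_plus_white(
        (n, 2, cfg.n_frames), cfg.ar1_coefficient, cfg.noise_sd, rng
    )
    s = 2.0 * states.astype(float) - 1.0
    a = cfg.signal_amplitude
    dmn = a * s + noise[:, 0]
    tpn = -a * s + noise[:, 1]
    pairs = [
        NetworkPair(dmn[i], tpn[i], tr=cfg.tr, stream="GSR", provenance="synthetic")
        for i in range(n)
    ]

    ind = (dmn > tpn).astype(np.int8)
    dwell = np.array([mean_dwell_time(ind[i], "DMN", cfg.tr)[0] for i in range(n)])
    dwell = np.nan_to_num(dwell, nan=0.0)
    z_dwell = (dwell - dwell.mean()) / (dwell.std() if dwell.std() > 0 else 1.0)

    rho = cfg.behavior_coupling
    anx = rho * z_dwell + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    rc = cfg.comorbidity
    dep = rc * anx + np.sqrt(1.0 - rc**2) * rng.standard_normal(n)

    sas = np.clip(np.rint(cfg.sas_mean + cfg.sas_sd * anx), 20, 80).astype(int)
    sds = np.clip(np.rint(cfg.sds_mean + cfg.sds_sd * dep), 20, 80).astype(int)
    age = np.clip(20.0 + 1.3 * rng.standard_normal(n), 17.0, 26.0)
    gender = np.where(rng.random(n) < 0.5, "M", "F")

    subjects = []
    for i in range(n):
        subjects.append(
            SubjectRecord(
                id=f"sub-{i:04d}",
                sas_score=float(sas[i]),
                sds_score=float(sds[i]),
                age=float(age[i]),
                gender=str(gender[i]),
                dominance=summarize_dominance(pairs[i], tr=cfg.tr),
            )
        )
    truth = SyntheticTruth(
        config=cfg,
        states=states,
        n_transitions=np.array(
            [count_transitions(states[i]) for i in range(n)]
        ),
        mean_dwell_dmn=np.array(
            [mean_dwell_time(states[i], "DMN", cfg.tr)[0] for i in range(n)]
        ),
        anxiety_latent=anx,
        depression_latent=dep,
        seed=cfg.seed,
    )
    return CohortTable(subjects), pairs, truth


@dataclass(frozen=True)
class VolumeGeometry:
    """Planted blob centres (MNI mm) and radii for the volume generator.

    Defaults keep DMN, TPN, RFIC, WM and CSF regions disjoint and place the
    RFIC blob inside the standard RFIC box mask.
    """

    dmn_center: tuple[float, float, float] = (-15.0, 24.0, 9.0)
    tpn_center: tuple[float, float, float] = (-15.0, -24.0, 9.0)
    rfic_center: tuple[float, float, float] = (33.0, 12.0, -6.0)
    wm_center: tuple[float, float, float] = (24.0, -27.0, 21.0)
    csf_center: tuple[float, float, float] = (-21.0, 21.0, -18.0)
    radius_mm: float = 7.5

    def seeds(self) -> dict[str, SeedSpec]:
        r = self.radius_mm
        return {
            "dmn": SeedSpec("dmn_blob", self.dmn_center, r, network="DMN"),
            "tpn": SeedSpec("tpn_blob", self.tpn_center, r, network="TPN"),
            "rfic": SeedSpec("rfic_blob", self.rfic_center, r),
            "wm": SeedSpec("wm_ref", self.wm_center, r),
            "csf": SeedSpec("csf_ref", self.csf_center, r),
        }


def _region_masks(cfg: GeneratorConfig, geometry: VolumeGeometry) -> dict:
    from .networks import sphere_mask

    affine = cfg.affine()
    masks = {
        k: sphere_mask(s, affine, cfg.grid_dims) for k, s in geometry.seeds().items()
    }
    stack = np.stack(list(masks.values()))
    if (stack.sum(axis=0) > 1).any():
        raise ValueError("planted regions overlap; adjust geometry")
    return masks


def simulate_volumes(
    config: GeneratorConfig,
    geometry: VolumeGeometry | None = None,
    background_sd: float = 0.2,
):
    """Yield per-subject (VolumeSeries, MotionParams-like array) volumes.

    Returns ``(subject_iterator, masks, truth)`` where ``masks`` maps region
    name -> 3-D boolean mask.  The iterator yields
    ``(volume, motion_values)`` lazily so large cohorts never co-reside in
    memory.  DMN/TPN blob voxels carry the +-amplitude state signal plus
    voxel noise; the RFIC blob is white noise whose SD is
    ``rfic_base_sd + rfic_coupling * n_transitions(subject)``.
    """
    cfg = config
    geometry = geometry or VolumeGeometry()
    masks = _region_masks(cfg, geometry)
    affine = cfg.affine()
    rng = _rng(cfg.seed, 2)
    states = simulate_state_sequences(
        cfg.n_subjects, cfg.n_frames, cfg.p_stay_dmn, cfg.p_stay_tpn, rng,
        cfg.fixed_dwell,
    )
    n_trans = np.array([count_transitions(states[i]) for i in range(cfg.n_subjects)])
    rfic_sd = cfg.rfic_base_sd + cfg.rfic_coupling * n_trans
    truth = SyntheticTruth(
        config=cfg,
        states=states,
        n_transitions=n_trans,
        mean_dwell_dmn=np.array(
            [mean_dwell_time(states[i], "DMN", cfg.tr)[0] for i in range(cfg.n_subjects)]
        ),
        anxiety_latent=np.zeros(cfg.n_subjects),
        depression_latent=np.zeros(cfg.n_subjects),
        rfic_sd=rfic_sd,
        geometry=geometry,
        seed=cfg.seed,
    )

    def subjects():
        for i in range(cfg.n_subjects):
            sub_rng = _rng(cfg.seed, 3, i)
            data = sub_rng.normal(
                0.0, background_sd, size=(*cfg.grid_dims, cfg.n_frames)
            )
            s = 2.0 * states[i].astype(float) - 1.0
            sig = cfg.signal_amplitude * s
            vox_noise = cfg.noise_sd
            for name, sign in (("dmn", 1.0), ("tpn", -1.0)):
                m = masks[name]
                data[m] = sign * sig + sub_rng.normal(
                    0.0, vox_noise, size=(int(m.sum()), cfg.n_frames)
                )
            m = masks["rfic"]
            data[m] = sub_rng.normal(
                0.0, rfic_sd[i], size=(int(m.sum()), cfg.n_frames)
            )
            motion = 0.05 * sub_rng.standard_normal((cfg.n_frames, 6))
            yield VolumeSeries(data, affine, tr=cfg.tr), motion

    return subjects(), masks, truth
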