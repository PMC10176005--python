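"""Synthetic two-timepoint MS cohort with known ground truth.

The phantom stands in for a longitudinal MS MRI dataset: per subject and
timepoint it provides tissue posterior probability volumes (NAWM, NACGM,
NADGM, CSF, lesion), a focal FLAIR-like lesion mask, the full lesion mask
(focal core plus peripheral shells), ground-truth parameter maps (MTsat,
PD, R1, R2*), and a longitudinal clinical record from which the binary
disease-activity status is derived.

Anatomy is deliberately schematic: nested ellipsoids (skull/CSF envelope,
cortical ribbon, white-matter core) with two deep-gray blobs, and spherical
white-matter lesions.  Each lesion has a focal core and concentric
peripheral shells whose parameter values interpolate between lesion-core
and NAWM truth values, so the periplaque gradient analysed downstream is
present by construction.  Lesions grow between T0 and T1 (the T1 sphere
contains the T0 sphere), the brain parenchyma shrinks at a programmed
atrophy rate, and clinically stable subjects (status 1) receive a positive
per-year shift of NAWM/NACGM MTsat and R2* emulating repair.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .mpm import ParameterMaps, MultiEchoSeries, PARAMETERS
from .protocol import AcquisitionProtocol, spgr_signal, mt_spgr_signal_te0

TISSUES = ("NAWM", "NACGM", "NADGM", "CSF", "lesion")
NORMAL_TISSUES = ("NAWM", "NACGM", "NADGM")
TIMEPOINTS = ("T0", "T1")

#: Plausible literature-like tissue truth values (config data, not claims):
#: MTsat and PD in percent units, R1 and R2* in 1/s.
DEFAULT_TISSUE_TRUTH: dict[str, dict[str, float]] = {
    "NAWM": {"MTsat": 1.9, "PD": 69.0, "R1": 1.05, "R2s": 21.0},
    "NACGM": {"MTsat": 1.1, "PD": 80.0, "R1": 0.62, "R2s": 16.0},
    "NADGM": {"MTsat": 1.3, "PD": 75.0, "R1": 0.75, "R2s": 25.0},
    "CSF": {"MTsat": 0.05, "PD": 100.0, "R1": 0.25, "R2s": 2.0},
    "lesion": {"MTsat": 1.0, "PD": 85.0, "R1": 0.70, "R2s": 14.0},
}

#: Per-year additive shift of NAWM/NACGM truth values for status-1
#: (stable/improving) subjects: positive MTsat and R2* drift emulating
#: remyelination / inflammation resorption.
DEFAULT_STATUS_EFFECT: dict[str, float] = {"MTsat": 0.039, "R2s": 0.295}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, truth values and noise levels of the synthetic cohort."""

    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 17
    n_lesions_per_subject: int = 3
    lesion_radius_focal: float = 2.0
    lesion_radius_t0: float = 3.0
    lesion_radius_t1: float = 4.0
    tissue_truth: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_TISSUE_TRUTH
    )
    peripheral_gradient: float = 0.4
    status_effect: Mapping[str, float] = field(default_factory=lambda: DEFAULT_STATUS_EFFECT)
    atrophy_percent_per_year: float = -0.67
    visit_sd_frac: float = 0.005  # per-visit tissue-level multiplicative jitter
    map_noise_frac: float = 0.02  # voxel-level multiplicative jitter of truth maps
    noise_sd: float = 0.05  # additive noise on simulated FLASH signals
    p_activity_mid: float = 0.3
    p_activity_end: float = 0.3
    interval_range_months: tuple[float, float] = (14.0, 61.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_lesions_per_subject < 0:
            raise ValueError("n_lesions_per_subject must be >= 0")
        if self.n_lesions_per_subject > 0:
            if min(self.lesion_radius_focal, self.lesion_radius_t0, self.lesion_radius_t1) <= 0:
                raise ValueError("lesion radii must be positive when lesions are requested")
            if self.lesion_radius_t1 < self.lesion_radius_t0:
                raise ValueError("lesion_radius_t1 must be >= lesion_radius_t0 (lesions enlarge)")
            if self.lesion_radius_t0 < self.lesion_radius_focal:
                raise ValueError("lesion_radius_t0 must be >= lesion_radius_focal")
        if not 0.0 <= self.peripheral_gradient <= 1.0:
            raise ValueError("peripheral_gradient must be in [0, 1]")
        for tissue, values in self.tissue_truth.items():
            for p, v in values.items():
                if v <= 0:
                    raise ValueError(f"tissue truth value {tissue}/{p} must be positive")
        if self.noise_sd < 0 or self.visit_sd_frac < 0 or self.map_noise_frac < 0:
            raise ValueError("noise levels must be >= 0")
        lo, hi = self.interval_range_months
        if lo <= 0 or hi < lo:
            raise ValueError("interval_range_months must be positive and ordered")
        for p in (self.p_activity_mid, self.p_activity_end):
            if not 0.0 <= p <= 1.0:
                raise ValueError("activity probabilities must be in [0, 1]")


@dataclass
class PhantomTimepoint:
    """Truth volumes for one subject at one scan."""

    posteriors: dict[str, np.ndarray]
    flair_mask: np.ndarray
    lesion_mask: np.ndarray  # full lesion: focal core + peripheral shell(s)
    maps: ParameterMaps
    tissue_values: dict[str, dict[str, float]]  # tissue -> parameter -> scalar truth


@dataclass
class PhantomSubject:
    subject_id: str
    status: int
    interval_months: float
    timepoints: dict[str, PhantomTimepoint]
    lesion_centers: np.ndarray  # (n_lesions, 3) voxel coordinates


@dataclass
class PhantomTruth:
    config: PhantomConfig
    clinical: pd.DataFrame
    subjects: list[PhantomSubject]


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi_axes))
    return d <= 1.0


def sphere_mask(shape, center, radius_mm, voxel_size) -> np.ndarray:
    """Rasterize a sphere of radius_mm (voxel centers inside the ball)."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center, voxel_size))
    return d2 <= radius_mm**2


@dataclass
class _Anatomy:
    skull: np.ndarray
    csf: np.ndarray
    nacgm: np.ndarray
    nadgm: np.ndarray
    nawm: np.ndarray
    wm_interior: np.ndarray  # NAWM eroded enough to host T1 lesion spheres


def _build_anatomy(config: PhantomConfig, atrophy_factor: float) -> _Anatomy:
    """Nested-ellipsoid brain; atrophy_factor scales parenchymal volume."""
    shape = np.asarray(config.grid_shape)
    center = (shape - 1) / 2.0
    skull_axes = 0.46 * shape
    lin = atrophy_factor ** (1.0 / 3.0)  # volume factor -> linear factor
    parenchyma_axes = 0.88 * skull_axes * lin
    wm_axes = 0.72 * skull_axes * lin

    skull = _ellipsoid(config.grid_shape, center, skull_axes)
    parenchyma = _ellipsoid(config.grid_shape, center, parenchyma_axes)
    wm = _ellipsoid(config.grid_shape, center, wm_axes)

    # two deep-gray blobs inside the white matter core
    dgm_r = max(2.5, 0.09 * float(shape.min()))
    off = np.array([0.28 * wm_axes[0], 0.0, 0.0])
    dgm = sphere_mask(config.grid_shape, center + off, dgm_r, config.voxel_size)
    dgm |= sphere_mask(config.grid_shape, center - off, dgm_r, config.voxel_size)
    dgm &= wm

    csf = skull & ~parenchyma
    nacgm = parenchyma & ~wm
    nawm = wm & ~dgm

    margin_vox = int(np.ceil(config.lesion_radius_t1 / min(config.voxel_size))) + 1
    interior = ndimage.binary_erosion(wm, iterations=margin_vox) & ~ndimage.binary_dilation(
        dgm, iterations=margin_vox
    )
    return _Anatomy(skull=skull, csf=csf, nacgm=nacgm, nadgm=dgm, nawm=nawm,
                    wm_interior=interior)


def _place_lesions(
    anatomy: _Anatomy, config: PhantomConfig, rng: np.random.Generator,
) -> np.ndarray:
    """Draw non-overlapping lesion centers inside the eroded WM core.

    Candidate voxels are visited in a seeded random order and accepted
    greedily when far enough from every previously accepted center, so the
    sweep is deterministic and fails only when the geometry truly cannot
    host the requested lesions.
    """
    n = config.n_lesions_per_subject
    if n == 0:
        return np.zeros((0, 3), dtype=int)
    candidates = np.argwhere(anatomy.wm_interior)
    if candidates.shape[0] == 0:
        raise RuntimeError("white-matter interior too small to host lesions")
    min_dist = 2.0 * config.lesion_radius_t1 + 1.0  # keep components separate
    vox = np.asarray(config.voxel_size)
    centers: list[np.ndarray] = []
    for c in candidates[rng.permutation(candidates.shape[0])]:
        if all(np.linalg.norm((c - o) * vox) >= min_dist for o in centers):
            centers.append(c)
            if len(centers) == n:
                return np.asarray(centers)
    raise RuntimeError(
        f"could only place {len(centers)} of {n} non-overlapping lesions; "
        "enlarge the grid or reduce lesion count/radius"
    )


# ---------------------------------------------------------------------------
# clinical table


def _edss_progression_threshold(baseline: float) -> float:
    # 0.5-point step above the EDSS 4.0 ambulation milestone, 1.0 below;
    # the boundary itself uses the 0.5-point step (see docs/methods.md).
    return 0.5 if baseline >= 4.0 else 1.0


def generate_clinical_table(
    n_subjects: int,
    seed: int,
    p_activity_mid: float = 0.3,
    p_activity_end: float = 0.3,
    interval_range_months: tuple[float, float] = (14.0, 61.0),
) -> pd.DataFrame:
    """Seeded longitudinal clinical records with a self-consistent status label.

    Disease activity (new lesion, relapse, and/or EDSS progression) is drawn
    independently for the first and second half of the interscan interval;
    the final status is 1 (stable/improving) unless activity is present in
    BOTH halves.  The emitted ``status`` column is derived by the same
    scoring rules applied downstream, so it is consistent by construction.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for p in (p_activity_mid, p_activity_end):
        if not 0.0 <= p <= 1.0:
            raise ValueError("activity probabilities must be in [0, 1]")
    lo, hi = interval_range_months
    if lo <= 0 or hi < lo:
        raise ValueError("interval range must be positive and ordered")

    from .clinical import ClinicalRecord  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rows = []
    edss_grid = np.arange(1.0, 6.5, 0.5)
    for i in range(n_subjects):
        edss0 = float(rng.choice(edss_grid))
        interval = float(rng.uniform(lo, hi))
        edss = edss0
        flags = {}
        for phase, p_act in (("mid", p_activity_mid), ("end", p_activity_end)):
            active = rng.random() < p_act
            new_lesion = relapse = "none"
            if active:
                mech = rng.random(3)
                chosen = mech < 0.5
                if not chosen.any():
                    chosen[rng.integers(3)] = True
                if chosen[0]:
                    new_lesion = "yes"
                if chosen[1]:
                    relapse = "yes"
                if chosen[2]:
                    edss = min(10.0, edss0 + _edss_progression_threshold(edss0))
            flags[phase] = (new_lesion, relapse)
            if phase == "mid":
                edss_mid = edss
        edss_end = edss
        record = ClinicalRecord(
            subject_id=f"sub-{i + 1:03d}",
            edss_t0=edss0,
            edss_mid=edss_mid,
            edss_t1=edss_end,
            new_lesion_mid=flags["mid"][0],
            new_lesion_end=flags["end"][0],
            relapse_mid=flags["mid"][1],
            relapse_end=flags["end"][1],
            interval_months=interval,
        )
        rows.append({**record.as_row(), "status": record.status()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth maps and posteriors


def _lesion_value(core: float, nawm: float, frac: float) -> float:
    return core + frac * (nawm - core)


def _subject_tissue_values(
    config: PhantomConfig,
    status: int,
    interval_years: float,
    timepoint: str,
    rng: np.random.Generator,
) -> dict[str, dict[str, float]]:
    """Tissue-level truth values for one visit: base + status drift + visit jitter."""
    values: dict[str, dict[str, float]] = {}
    for tissue in TISSUES:
        values[tissue] = {}
        for p in PARAMETERS:
            v = float(config.tissue_truth[tissue][p])
            if (
                timepoint == "T1"
                and status == 1
                and tissue in ("NAWM", "NACGM")
                and p in config.status_effect
            ):
                v += float(config.status_effect[p]) * interval_years
            v *= 1.0 + rng.normal(0.0, config.visit_sd_frac)
            values[tissue][p] = max(v, 1e-6)
    return values


def _render_timepoint(
    config: PhantomConfig,
    anatomy: _Anatomy,
    lesion_centers: np.ndarray,
    tissue_values: dict[str, dict[str, float]],
    timepoint: str,
    rng: np.random.Generator,
) -> PhantomTimepoint:
    shape = config.grid_shape
    vox = config.voxel_size

    r_full = config.lesion_radius_t0 if timepoint == "T0" else config.lesion_radius_t1
    focal = np.zeros(shape, dtype=bool)
    full = np.zeros(shape, dtype=bool)
    shell_init = np.zeros(shape, dtype=bool)
    shell_later = np.zeros(shape, dtype=bool)
    for c in lesion_centers:
        focal |= sphere_mask(shape, c, config.lesion_radius_focal, vox)
        full |= sphere_mask(shape, c, r_full, vox)
        s_t0 = sphere_mask(shape, c, config.lesion_radius_t0, vox)
        shell_init |= s_t0
        shell_later |= sphere_mask(shape, c, config.lesion_radius_t1, vox)
    shell_later &= ~shell_init
    shell_init &= ~focal

    # label volume: 0 background, then NAWM, NACGM, NADGM, CSF, lesion region
    class_of = np.zeros(shape, dtype=np.int8)
    for k, mask in enumerate(
        (anatomy.nawm, anatomy.nacgm, anatomy.nadgm, anatomy.csf), start=1
    ):
        class_of[mask] = k
    # the *later* shell is part of normal WM at T0 but already carries the
    # pre-lesional gradient in the maps; the lesion posterior covers the full
    # mask of the current timepoint only.
    class_of[full] = 5

    g = config.peripheral_gradient
    frac_init = g
    frac_later = g + (1.0 - g) * g  # second shell sits closer to NAWM

    maps = {}
    for p in PARAMETERS:
        vol = np.zeros(shape, dtype=float)
        vol[anatomy.nawm] = tissue_values["NAWM"][p]
        vol[anatomy.nacgm] = tissue_values["NACGM"][p]
        vol[anatomy.nadgm] = tissue_values["NADGM"][p]
        vol[anatomy.csf] = tissue_values["CSF"][p]
        core_v = tissue_values["lesion"][p]
        nawm_v = tissue_values["NAWM"][p]
        vol[shell_later] = _lesion_value(core_v, nawm_v, frac_later)
        vol[shell_init] = _lesion_value(core_v, nawm_v, frac_init)
        vol[focal] = core_v
        if config.map_noise_frac > 0:
            vol *= 1.0 + rng.normal(0.0, config.map_noise_frac, size=shape)
        maps[p] = np.abs(vol)

    amplitude = maps["PD"].copy()  # A is proportional to proton density (factor 1)
    pmaps = ParameterMaps(
        mtsat=maps["MTsat"], pd=maps["PD"], r1=maps["R1"], r2s=maps["R2s"], a=amplitude,
        valid=anatomy.skull.copy(),
    )

    posteriors = {t: np.zeros(shape, dtype=float) for t in TISSUES}
    p_main, p_other = 0.9, 0.05
    second = {"NAWM": "CSF", "NACGM": "CSF", "NADGM": "NAWM", "CSF": "NACGM",
              "lesion": "NAWM"}
    for k, tissue in enumerate(("NAWM", "NACGM", "NADGM", "CSF", "lesion"), start=1):
        m = class_of == k
        posteriors[tissue][m] = p_main
        posteriors[second[tissue]][m] += p_other

    return PhantomTimepoint(
        posteriors=posteriors,
        flair_mask=focal,
        lesion_mask=full,
        maps=pmaps,
        tissue_values=tissue_values,
    )


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Generate the full two-timepoint cohort (volumes + clinical table)."""
    rng = np.random.default_rng(config.seed)
    clinical = generate_clinical_table(
        config.n_subjects,
        seed=int(rng.integers(2**31 - 1)),
        p_activity_mid=config.p_activity_mid,
        p_activity_end=config.p_activity_end,
        interval_range_months=config.interval_range_months,
    )

    anatomy_t0 = _build_anatomy(config, atrophy_factor=1.0)
    subjects: list[PhantomSubject] = []
    for _, row in clinical.iterrows():
        interval_years = row.interval_months / 12.0
        atrophy = 1.0 + config.atrophy_percent_per_year / 100.0 * interval_years
        anatomy_t1 = _build_anatomy(config, atrophy_factor=atrophy)
        centers = _place_lesions(anatomy_t1, config, rng)
        timepoints = {}
        for tp, anatomy in (("T0", anatomy_t0), ("T1", anatomy_t1)):
            values = _subject_tissue_values(
                config, int(row.status), interval_years, tp, rng
            )
            timepoints[tp] = _render_timepoint(config, anatomy, centers, values, tp, rng)
        subjects.append(
            PhantomSubject(
                subject_id=row.subject_id,
                status=int(row.status),
                interval_months=float(row.interval_months),
                timepoints=timepoints,
                lesion_centers=centers,
            )
        )
    return PhantomTruth(config=config, clinical=clinical, subjects=subjects)


# ---------------------------------------------------------------------------
# forward FLASH simulation


def simulate_flash_series(
    truth: ParameterMaps,
    protocol: AcquisitionProtocol,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rician: bool = False,
) -> dict[str, MultiEchoSeries]:
    """Simulate the three weighted multi-echo FLASH series from truth maps.

    PDw and T1w follow the exact steady-state spoiled gradient-echo signal;
    the MTw series uses the small-angle MT-attenuated TE=0 amplitude (the
    exact inverse of the MTsat estimator) with the same R2* decay.  Additive
    zero-mean Gaussian noise of ``noise_sd`` (or Rician magnitude noise when
    ``rician``) is applied; ``noise_sd=0`` gives the exact forward model.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, MultiEchoSeries] = {}
    for contrast in ("MTw", "PDw", "T1w"):
        cp = protocol[contrast]
        te = np.asarray(cp.te, dtype=float)
        if contrast == "MTw":
            s0 = mt_spgr_signal_te0(
                truth.a, truth.r1, truth.mtsat, cp.flip_angle_rad, cp.tr
            )
            data = s0[..., None] * np.exp(-te * truth.r2s[..., None])
        else:
            data = spgr_signal(
                truth.a[..., None],
                truth.r1[..., None],
                truth.r2s[..., None],
                cp.flip_angle_rad,
                cp.tr,
                te,
            )
        if noise_sd > 0:
            if rician:
                re = data + rng.normal(0.0, noise_sd, size=data.shape)
                im = rng.normal(0.0, noise_sd, size=data.shape)
                data = np.hypot(re, im)
            else:
                data = data + rng.normal(0.0, noise_sd, size=data.shape)
        out[contrast] = MultiEchoSeries(contrast=contrast, data=data, te=tuple(cp.te))
    return out
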