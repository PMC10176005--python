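"""Tissue-mask construction and lesion-area algebra.

Posterior probability maps are turned into exclusive binary tissue masks
(argmax above a 0.2 threshold), small lesion components (< 10 mm^3) are
removed as likely segmentation errors, and the four mutually exclusive
lesion-related areas used for the periplaque analysis are built by set
algebra:

    focal FLAIR lesion        core visible on conventional FLAIR at T0
    initial peripheral lesion T0 lesion voxels around (not inside) the core
    later peripheral lesion   T1 lesion voxels not already lesional at T0
    NAWM                      white matter outside all three areas

Only *enlarging* lesions (connected components that intersect all three
lesion areas) enter the per-lesion analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import TISSUES  # ("NAWM", "NACGM", "NADGM", "CSF", "lesion")

#: Tie-break priority when posteriors are exactly equal (highest first).
TISSUE_PRIORITY = ("lesion", "NAWM", "NACGM", "NADGM", "CSF")

LESION_AREAS = ("focal_flair", "initial_peripheral", "later_peripheral")
MIN_LESION_VOLUME_MM3 = 10.0


@dataclass
class TissuePosteriors:
    """Posterior probability volumes on a shared grid."""

    probabilities: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        missing = [t for t in TISSUES if t not in self.probabilities]
        if missing:
            raise ValueError(f"missing posterior volumes: {missing}")
        shapes = {v.shape for v in self.probabilities.values()}
        if len(shapes) != 1:
            raise ValueError("posterior volumes must share one grid")
        total = sum(np.asarray(v, dtype=float) for v in self.probabilities.values())
        if np.any(total > 1.0 + 1e-6):
            raise ValueError("posterior probabilities sum above 1 in some voxels")
        for t, v in self.probabilities.items():
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"posterior {t} outside [0, 1]")


@dataclass
class AreaMasks:
    """The four exclusive lesion-related areas plus a labeled lesion volume."""

    focal_flair: np.ndarray
    initial_peripheral: np.ndarray
    later_peripheral: np.ndarray
    nawm: np.ndarray
    labels: np.ndarray  # integer connected-component ids over the lesion union

    def area(self, name: str) -> np.ndarray:
        return {
            "focal_flair": self.focal_flair,
            "initial_peripheral": self.initial_peripheral,
            "later_peripheral": self.later_peripheral,
            "NAWM": self.nawm,
        }[name]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def binarize_tissues(
    posteriors: TissuePosteriors,
    threshold: float = 0.2,
) -> dict[str, np.ndarray]:
    """Exclusive tissue masks: argmax class where max probability > threshold.

    The threshold is strict; sub-threshold voxels stay unassigned.  Exact
    posterior ties are resolved by a fixed priority order (lesion first).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    stack = np.stack([posteriors.probabilities[t] for t in TISSUE_PRIORITY])
    best = np.argmax(stack, axis=0)  # first max wins -> priority order
    pmax = np.max(stack, axis=0)
    assigned = pmax > threshold
    return {t: assigned & (best == k) for k, t in enumerate(TISSUE_PRIORITY)}


def clean_lesion_mask(
    mask: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    min_volume_mm3: float = MIN_LESION_VOLUME_MM3,
    connectivity: int = 26,
) -> np.ndarray:
    """Remove lesion components smaller than ``min_volume_mm3`` (strictly)."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("lesion mask must be binary")
        mask = mask.astype(bool)
    voxel_volume = float(np.prod(voxel_size))
    labels, n = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())[1:]
    keep = (counts * voxel_volume) >= min_volume_mm3
    keep_ids = np.flatnonzero(keep) + 1
    return np.isin(labels, keep_ids)


def build_lesion_areas(
    flair_t0: np.ndarray,
    lesion_t0: np.ndarray,
    lesion_t1: np.ndarray,
    wm_mask: np.ndarray,
    connectivity: int = 26,
) -> AreaMasks:
    """Build the four exclusive areas from the three lesion masks and WM.

    focal = FLAIR core; initial peripheral = T0 lesion minus core; later
    peripheral = T1 lesion minus T0 lesion; NAWM = WM minus all three.
    The FLAIR core is intersected with the T0 lesion mask first, so the
    containment assumption cannot be violated.
    """
    masks = [np.asarray(m, dtype=bool) for m in (flair_t0, lesion_t0, lesion_t1, wm_mask)]
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError("all masks must share one grid")
    flair_t0, lesion_t0, lesion_t1, wm_mask = masks

    focal = flair_t0 & lesion_t0
    initial = lesion_t0 & ~focal
    later = lesion_t1 & ~lesion_t0
    nawm = wm_mask & ~(focal | initial | later)

    union = focal | initial | later
    labels, _ = ndimage.label(union, structure=_connectivity_structure(connectivity))
    return AreaMasks(
        focal_flair=focal,
        initial_peripheral=initial,
        later_peripheral=later,
        nawm=nawm,
        labels=labels,
    )


def select_enlarging_lesions(areas: AreaMasks) -> dict[int, dict[str, np.ndarray]]:
    """Keep lesion components present in all three lesion-related areas.

    A connected component of the lesion union is *enlarging* when it
    overlaps the focal core, the initial peripheral shell and the later
    peripheral shell by at least one voxel each.  Returns, per retained
    component id, its three per-area sub-masks.
    """
    out: dict[int, dict[str, np.ndarray]] = {}
    for lesion_id in np.unique(areas.labels):
        if lesion_id == 0:
            continue
        comp = areas.labels == lesion_id
        parts = {
            "focal_flair": comp & areas.focal_flair,
            "initial_peripheral": comp & areas.initial_peripheral,
            "later_peripheral": comp & areas.later_peripheral,
        }
        if all(p.any() for p in parts.values()):
            out[int(lesion_id)] = parts
    return out


def lesion_volume_table(
    areas: AreaMasks,
    subject_id: str,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Per-lesion, per-area volume summary (mm^3) of the labeled components."""
    voxel_volume = float(np.prod(voxel_size))
    rows = []
    for lesion_id in np.unique(areas.labels):
        if lesion_id == 0:
            continue
        comp = areas.labels == lesion_id
        for name in LESION_AREAS:
            rows.append(
                {
                    "subject": subject_id,
                    "lesion_id": int(lesion_id),
                    "area": name,
                    "volume_mm3": float((comp & areas.area(name)).sum() * voxel_volume),
                }
            )
    return pd.DataFrame(rows, columns=["subject", "lesion_id", "area", "volume_mm3"])
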