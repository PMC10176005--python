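"""Brain volume fractions and their annualized changes.

From the exclusive tissue masks the stage computes, per subject and
timepoint:

    TIV = volume(NAWM + GM + CSF + lesions)       total intracranial volume
    BPF = volume(NAWM + GM + lesions) / TIV       brain parenchymal fraction
    GMF = volume(GM) / TIV                        gray-matter fraction
    LF  = volume(lesions) / TIV                   lesion fraction

with GM = NACGM + NADGM.  Percent change between sessions is annualized by
the interscan interval, and one-sample t-tests ask whether the cohort mean
annual change differs from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class VolumeFractions:
    """Volume summary of one subject at one timepoint."""

    tiv_mm3: float
    bpf: float
    gmf: float
    lf: float

    def __post_init__(self) -> None:
        for name in ("bpf", "gmf", "lf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def compute_fractions(
    tissue_masks: Mapping[str, np.ndarray],
    lesion_mask: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeFractions:
    """Exact voxel-count volumetry from exclusive masks.

    ``tissue_masks`` must provide NAWM, NACGM, NADGM and CSF; the lesion
    mask is counted separately.  Masks are assumed disjoint (as produced by
    ``binarize_tissues``).
    """
    voxel_volume = float(np.prod(voxel_size))
    vol = {t: float(np.count_nonzero(tissue_masks[t])) * voxel_volume
           for t in ("NAWM", "NACGM", "NADGM", "CSF")}
    lesions = float(np.count_nonzero(lesion_mask)) * voxel_volume
    gm = vol["NACGM"] + vol["NADGM"]
    tiv = vol["NAWM"] + gm + vol["CSF"] + lesions
    if tiv == 0:
        raise ValueError("TIV is zero: no tissue voxels found")
    return VolumeFractions(
        tiv_mm3=tiv,
        bpf=(vol["NAWM"] + gm + lesions) / tiv,
        gmf=gm / tiv,
        lf=lesions / tiv,
    )


def annualized_percent_change(v0: float, v1: float, interval_months: float) -> float:
    """Percent change from v0 to v1, per year: 100 (v1-v0)/v0 / (months/12)."""
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if interval_months <= 0:
        raise ValueError("interval must be positive")
    return 100.0 * (v1 - v0) / v0 / (interval_months / 12.0)


def one_sample_ttest(values) -> tuple[float, int, float]:
    """Two-sided one-sample t-test against zero; returns (t, df, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("sample standard deviation is zero; t statistic undefined")
    res = stats.ttest_1samp(x, 0.0)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def volume_change_table(fractions: pd.DataFrame) -> pd.DataFrame:
    """Annualized percent change of BPF/GMF/LF per subject.

    ``fractions`` has one row per subject and timepoint with columns
    subject, timepoint (T0/T1), interval_months, tiv_mm3, bpf, gmf, lf.
    Subjects with LF = 0 at T0 get a missing LF change (relative change
    from zero is undefined).
    """
    rows = []
    for subject, g in fractions.groupby("subject", sort=False):
        t0 = g[g.timepoint == "T0"].iloc[0]
        t1 = g[g.timepoint == "T1"].iloc[0]
        row = {"subject": subject, "interval_months": t0.interval_months}
        for name in ("bpf", "gmf", "lf"):
            v0, v1 = float(t0[name]), float(t1[name])
            key = f"d{name}_pct_per_year"
            row[key] = (
                annualized_percent_change(v0, v1, float(t0.interval_months))
                if v0 > 0
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
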