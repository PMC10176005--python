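"""NEDA-3 disease-activity scoring from longitudinal clinical records.

The binary status regressor used by the normal-appearing-tissue analysis is
derived from "no evidence of disease activity" (NEDA-3): a patient shows
activity in a half-interval if there is a clinical relapse, MRI activity
(new or enlarged lesion), or sustained EDSS disability progression.  NEDA-3
is evaluated once per half of the interscan interval (mid and end, both
against the T0 baseline EDSS), and the final status is 0 only when activity
is present in BOTH evaluations; otherwise the patient counts as stable or
improving (status 1).

EDSS progression uses a 1.0-point increase below the EDSS 4.0 ambulation
milestone and a 0.5-point increase at or above it.  Missing flags ("NA",
e.g. relapse for progressive patients) contribute no evidence of activity.

A 17-subject MS reference cohort table ships with the package
(``load_reference_cohort``) including its expected NEDA and score columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

FLAG_VALUES = ("yes", "none", "na")

#: EDSS milestone separating the 1.0-point from the 0.5-point progression step.
EDSS_MILESTONE = 4.0


def _check_edss(value: float, name: str = "EDSS") -> float:
    v = float(value)
    if not 0.0 <= v <= 10.0 or round(v * 2) != v * 2:
        raise ValueError(f"{name} must be in 0..10 in 0.5 steps, got {value}")
    return v


def normalize_flag(value) -> str:
    """Map assorted spellings (Yes, None, N/A, NaN...) onto yes/none/na."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "na"
    v = str(value).strip().lower().replace("/", "")
    if v in ("yes", "y", "true", "1"):
        return "yes"
    if v in ("none", "no", "n", "false", "0"):
        return "none"
    if v in ("na", "nan", ""):
        return "na"
    raise ValueError(f"cannot interpret activity flag {value!r}")


def edss_progression(baseline_edss: float, follow_edss: float) -> bool:
    """Sustained disability progression between two EDSS readings.

    A 1.0-point increase counts as progression when the baseline is below
    the 4.0 milestone; from 4.0 upward a 0.5-point increase suffices.
    """
    b = _check_edss(baseline_edss, "baseline EDSS")
    f = _check_edss(follow_edss, "follow-up EDSS")
    step = 0.5 if b >= EDSS_MILESTONE else 1.0
    return f - b >= step


def neda3(
    edss_baseline: float,
    edss_follow: float,
    new_lesion: str,
    relapse: str,
) -> bool:
    """True when no evidence of disease activity is present.

    Activity = relapse, or new/enlarged MRI lesion, or EDSS progression.
    "NA" flags are treated as absence of evidence.
    """
    return not (
        normalize_flag(relapse) == "yes"
        or normalize_flag(new_lesion) == "yes"
        or edss_progression(edss_baseline, edss_follow)
    )


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's longitudinal clinical observations."""

    subject_id: str
    edss_t0: float
    edss_mid: float
    edss_t1: float
    new_lesion_mid: str
    new_lesion_end: str
    relapse_mid: str
    relapse_end: str
    interval_months: float

    def __post_init__(self) -> None:
        for name in ("edss_t0", "edss_mid", "edss_t1"):
            _check_edss(getattr(self, name), name)
        for name in ("new_lesion_mid", "new_lesion_end", "relapse_mid", "relapse_end"):
            normalize_flag(getattr(self, name))
        if self.interval_months <= 0:
            raise ValueError("interval_months must be positive")

    def neda_mid(self) -> bool:
        return neda3(self.edss_t0, self.edss_mid, self.new_lesion_mid, self.relapse_mid)

    def neda_end(self) -> bool:
        # the end-interval evaluation also uses the T0 EDSS as baseline, so
        # progression accumulated over the whole interval is counted
        return neda3(self.edss_t0, self.edss_t1, self.new_lesion_end, self.relapse_end)

    def status(self) -> int:
        """0 only when disease activity was noted in both half-intervals."""
        return 0 if (not self.neda_mid() and not self.neda_end()) else 1

    def as_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "edss_t0": self.edss_t0,
            "edss_mid": self.edss_mid,
            "edss_t1": self.edss_t1,
            "new_lesion_mid": self.new_lesion_mid,
            "new_lesion_end": self.new_lesion_end,
            "relapse_mid": self.relapse_mid,
            "relapse_end": self.relapse_end,
            "interval_months": self.interval_months,
        }


def disease_status_score(record: ClinicalRecord) -> int:
    """Final binary disease-activity status of one record (1 = stable/improving)."""
    return record.status()


def record_from_row(row) -> ClinicalRecord:
    return ClinicalRecord(
        subject_id=str(row["subject_id"]),
        edss_t0=float(row["edss_t0"]),
        edss_mid=float(row["edss_mid"]),
        edss_t1=float(row["edss_t1"]),
        new_lesion_mid=normalize_flag(row["new_lesion_mid"]),
        new_lesion_end=normalize_flag(row["new_lesion_end"]),
        relapse_mid=normalize_flag(row["relapse_mid"]),
        relapse_end=normalize_flag(row["relapse_end"]),
        interval_months=float(row["interval_months"]),
    )


def score_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Apply the full scoring chain to a clinical table.

    Returns one row per subject with ``neda_mid``, ``neda_end`` and the
    binary ``status``.
    """
    out = []
    for _, row in clinical.iterrows():
        rec = record_from_row(row)
        out.append(
            {
                "subject_id": rec.subject_id,
                "neda_mid": rec.neda_mid(),
                "neda_end": rec.neda_end(),
                "status": rec.status(),
            }
        )
    return pd.DataFrame(out)


def load_reference_cohort() -> pd.DataFrame:
    """The bundled 17-subject MS reference cohort clinical table.

    Columns include the observed inputs (EDSS trajectory, activity flags,
    interscan interval in months) and the expected ``neda_mid``/``neda_end``/
    ``score`` columns for validation.
    """
    with resources.files("qmritrack.data").joinpath(
        "reference_cohort_clinical.csv"
    ).open() as fh:
        return pd.read_csv(fh)
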