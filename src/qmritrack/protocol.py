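"""Acquisition protocol for a three-contrast multi-echo FLASH (MPM) session.

The multiparameter-mapping protocol acquires three co-localized spoiled
gradient-echo (FLASH) series with predominantly MT, PD and T1 weighting.
Each series is described by its nominal flip angle, repetition time and
list of echo times.  Angles are degrees at the interface and radians
internally; times are seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

CONTRASTS = ("MTw", "PDw", "T1w")


@dataclass(frozen=True)
class ContrastProtocol:
    """One FLASH series: flip angle (deg), TR (s), echo times (s)."""

    flip_angle_deg: float
    tr: float
    te: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_angle_deg < 90.0:
            raise ValueError(f"flip angle must be in (0, 90) deg, got {self.flip_angle_deg}")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if len(self.te) == 0:
            raise ValueError("echo-time list must not be empty")
        te = np.asarray(self.te, dtype=float)
        if np.any(te < 0):
            raise ValueError("echo times must be >= 0")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")

    @property
    def flip_angle_rad(self) -> float:
        return math.radians(self.flip_angle_deg)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """The three weighted FLASH series of one MPM session."""

    mtw: ContrastProtocol
    pdw: ContrastProtocol
    t1w: ContrastProtocol

    def __getitem__(self, contrast: str) -> ContrastProtocol:
        try:
            return {"MTw": self.mtw, "PDw": self.pdw, "T1w": self.t1w}[contrast]
        except KeyError:
            raise KeyError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")

    @classmethod
    def default(cls) -> "AcquisitionProtocol":
        """A plausible 3T MPM protocol: 6 echoes, small flip angles.

        MTw/PDw share a small angle, T1w uses a larger one so that the pair
        (PDw, T1w) determines R1 and the amplitude A.
        """
        echoes = tuple(0.0023 + 0.0047 * i for i in range(6))
        return cls(
            mtw=ContrastProtocol(6.0, 0.025, echoes),
            pdw=ContrastProtocol(6.0, 0.025, echoes),
            t1w=ContrastProtocol(21.0, 0.025, echoes),
        )

    @classmethod
    def small_angle(cls) -> "AcquisitionProtocol":
        """A protocol inside the small-angle validity regime (all angles <= 10 deg).

        The rational FLASH approximation behind the R1/A/MTsat estimators is
        accurate to better than 1% here (given TR*R1 <= ~0.05); use this for
        quantitative round-trip work.  The ``default`` protocol's 21 deg T1w
        angle mirrors common 3T sessions but pushes the approximation to the
        few-percent level.
        """
        echoes = tuple(0.0023 + 0.0047 * i for i in range(6))
        return cls(
            mtw=ContrastProtocol(4.0, 0.024, echoes),
            pdw=ContrastProtocol(4.0, 0.024, echoes),
            t1w=ContrastProtocol(10.0, 0.024, echoes),
        )

    def to_dict(self) -> dict:
        return {
            c: {
                "flip_angle_deg": self[c].flip_angle_deg,
                "tr": self[c].tr,
                "te": list(self[c].te),
            }
            for c in CONTRASTS
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        def mk(c: str) -> ContrastProtocol:
            e = d[c]
            return ContrastProtocol(float(e["flip_angle_deg"]), float(e["tr"]), tuple(e["te"]))

        return cls(mtw=mk("MTw"), pdw=mk("PDw"), t1w=mk("T1w"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def spgr_signal(
    a: np.ndarray | float,
    r1: np.ndarray | float,
    r2s: np.ndarray | float,
    flip_angle_rad: float,
    tr: float,
    te: float | np.ndarray,
) -> np.ndarray:
    """Steady-state spoiled gradient-echo signal.

    S(TE) = A sin(a) (1 - E1) / (1 - cos(a) E1) * exp(-TE R2*),  E1 = exp(-TR R1).
    """
    a = np.asarray(a, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2s = np.asarray(r2s, dtype=float)
    e1 = np.exp(-tr * r1)
    s0 = a * np.sin(flip_angle_rad) * (1.0 - e1) / (1.0 - np.cos(flip_angle_rad) * e1)
    return s0 * np.exp(-np.asarray(te, dtype=float) * r2s)


def mt_spgr_signal_te0(
    a: np.ndarray | float,
    r1: np.ndarray | float,
    mtsat_pu: np.ndarray | float,
    flip_angle_rad: float,
    tr: float,
) -> np.ndarray:
    """TE=0 signal of the MT-weighted FLASH in the small-angle regime.

    The MT pre-pulse saturates a fraction delta of the longitudinal
    magnetization each TR.  In the rational small-angle approximation the
    TE=0 signal satisfies

        S_MT(0) = A a (TR R1) / (TR R1 + delta + a^2/2),

    which is the exact inverse of the MTsat estimator
    ``delta = (A a / S_MT(0) - 1) TR R1 - a^2/2``.  ``mtsat_pu`` is delta in
    percent units (delta * 100).
    """
    a = np.asarray(a, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    delta = np.asarray(mtsat_pu, dtype=float) / 100.0
    u = tr * r1
    return a * flip_angle_rad * u / (u + delta + flip_angle_rad**2 / 2.0)
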