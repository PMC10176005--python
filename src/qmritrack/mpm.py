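"""Multiparameter-map estimation from multi-echo FLASH series.

The estimation chain mirrors the standard MPM computation: every weighted
series is extrapolated to TE = 0 with a joint log-linear fit that shares a
single R2* decay across contrasts (the ESTATICS model); the PDw/T1w
intercepts are inverted with the rational small-flip-angle approximation of
the FLASH signal equation to give R1 and the apparent amplitude A; the MTw
intercept then yields the MT saturation; and A is calibrated to percent
units to give PD.  Field-inhomogeneity corrections (B1+/B1-, RF spoiling)
are out of scope here: flip angles are taken at their nominal values.

All arrays are voxelwise and share one grid.  Invalid voxels (non-positive
signal, infeasible closed-form solution) are flagged, never silently filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .protocol import AcquisitionProtocol, CONTRASTS

PARAMETERS = ("MTsat", "PD", "R1", "R2s")


@dataclass
class MultiEchoSeries:
    """A 4D (x, y, z, echo) weighted FLASH acquisition."""

    contrast: str
    data: np.ndarray
    te: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}, got {self.contrast!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("series data must be 4D (x, y, z, echo)")
        if self.data.shape[-1] != len(self.te):
            raise ValueError("echo dimension does not match the TE list")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series intensities must be finite")


@dataclass
class EstaticsFit:
    """Joint TE=0 extrapolation: one R2* per voxel, one intercept per contrast."""

    r2s: np.ndarray
    intercepts: dict[str, np.ndarray]
    valid: np.ndarray
    clipped: np.ndarray  # voxels where a negative fitted R2* was clipped to 0
    rss: np.ndarray


@dataclass
class ParameterMaps:
    """Voxelwise MTsat (p.u.), PD (p.u.), R1 (1/s), R2* (1/s) and amplitude A."""

    mtsat: np.ndarray
    pd: np.ndarray
    r1: np.ndarray
    r2s: np.ndarray
    a: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {np.shape(m) for m in (self.mtsat, self.pd, self.r1, self.r2s, self.a)}
        if len(shapes) != 1:
            raise ValueError("all parameter maps must share one grid")
        if self.valid is None:
            self.valid = np.ones(np.shape(self.mtsat), dtype=bool)

    def __getitem__(self, parameter: str) -> np.ndarray:
        try:
            return {"MTsat": self.mtsat, "PD": self.pd, "R1": self.r1,
                    "R2s": self.r2s, "A": self.a}[parameter]
        except KeyError:
            raise KeyError(f"unknown parameter {parameter!r}")


def fit_estatics(
    series: Iterable[MultiEchoSeries],
    weighted: bool = False,
) -> EstaticsFit:
    """Fit ln S_c(TE) = ln S_c(0) - TE * R2* with the slope shared across contrasts.

    Ordinary least squares on the log signal (optionally weighted by S^2,
    which approximates least squares in the signal domain).  Voxels with any
    non-positive signal in any echo are flagged invalid rather than raising.
    """
    series = list(series)
    if not series:
        raise ValueError("at least one series is required")
    shape = series[0].data.shape[:3]
    for s in series:
        if s.data.shape[:3] != shape:
            raise ValueError("all series must share one spatial grid")
    n_echoes = sum(len(s.te) for s in series)
    if n_echoes < 2:
        raise ValueError("need at least two echoes in total to fit a decay")

    valid = np.ones(shape, dtype=bool)
    for s in series:
        valid &= np.all(s.data > 0, axis=-1)

    # Pooled-slope (ANCOVA) closed form with per-contrast intercepts.
    sxx = 0.0 if not weighted else np.zeros(shape)
    sxy = np.zeros(shape)
    stats = []
    for s in series:
        te = np.asarray(s.te, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(s.data > 0, np.log(np.where(s.data > 0, s.data, 1.0)), 0.0)
        if weighted:
            w = s.data**2
            wsum = w.sum(axis=-1)
            te_bar = (w * te).sum(axis=-1) / wsum
            y_bar = (w * y).sum(axis=-1) / wsum
            sxx = sxx + (w * (te - te_bar[..., None]) ** 2).sum(axis=-1)
            sxy += (w * (te - te_bar[..., None]) * (y - y_bar[..., None])).sum(axis=-1)
        else:
            te_bar = te.mean()
            y_bar = y.mean(axis=-1)
            sxx = sxx + float(((te - te_bar) ** 2).sum())
            sxy += ((te - te_bar) * (y - y_bar[..., None])).sum(axis=-1)
        stats.append((te, y, te_bar, y_bar))

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    r2s = -slope
    clipped = valid & (r2s < 0)
    r2s = np.where(valid, np.clip(r2s, 0.0, None), np.nan)

    intercepts: dict[str, np.ndarray] = {}
    rss = np.zeros(shape)
    for s, (te, y, te_bar, y_bar) in zip(series, stats):
        b = y_bar - slope * (te_bar if np.isscalar(te_bar) else te_bar)
        intercepts[s.contrast] = np.where(valid, np.exp(b), np.nan)
        resid = y - (b[..., None] + slope[..., None] * te)
        rss += np.where(valid, (resid**2).sum(axis=-1), np.nan)

    return EstaticsFit(r2s=r2s, intercepts=intercepts, valid=valid, clipped=clipped, rss=rss)


def compute_r1_amplitude(
    s_t1w0: np.ndarray,
    s_pdw0: np.ndarray,
    protocol: AcquisitionProtocol,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the small-angle FLASH pair for (R1, A) in closed form.

    Both TE=0 intercepts obey S_c = A a_c (TR_c R1) / (a_c^2/2 + TR_c R1);
    eliminating one unknown gives

        R1 = 1/2 (S_T1 a_T1/TR_T1 - S_PD a_PD/TR_PD) / (S_PD/a_PD - S_T1/a_T1)
        A  = S_PD S_T1 (TR_PD a_T1/a_PD - TR_T1 a_PD/a_T1)
             / (S_T1 TR_PD a_T1 - S_PD TR_T1 a_PD).

    Returns (r1, a, valid); voxels with no positive solution are invalid.
    """
    a_t1, tr_t1 = protocol.t1w.flip_angle_rad, protocol.t1w.tr
    a_pd, tr_pd = protocol.pdw.flip_angle_rad, protocol.pdw.tr
    if np.isclose(a_t1, a_pd) and np.isclose(tr_t1, tr_pd):
        raise ValueError("degenerate protocol: PDw and T1w have identical flip angle and TR")

    s_t1w0 = np.asarray(s_t1w0, dtype=float)
    s_pdw0 = np.asarray(s_pdw0, dtype=float)
    if s_t1w0.shape != s_pdw0.shape:
        raise ValueError("intercept maps must share one grid")

    finite = np.isfinite(s_t1w0) & np.isfinite(s_pdw0)
    pos = finite & (s_t1w0 > 0) & (s_pdw0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom_r1 = s_pdw0 / a_pd - s_t1w0 / a_t1
        r1 = 0.5 * (s_t1w0 * a_t1 / tr_t1 - s_pdw0 * a_pd / tr_pd) / denom_r1
        denom_a = s_t1w0 * tr_pd * a_t1 - s_pdw0 * tr_t1 * a_pd
        amp = (s_pdw0 * s_t1w0 * (tr_pd * a_t1 / a_pd - tr_t1 * a_pd / a_t1)) / denom_a

    valid = pos & np.isfinite(r1) & np.isfinite(amp) & (r1 > 0) & (amp > 0)
    r1 = np.where(valid, r1, np.nan)
    amp = np.where(valid, amp, np.nan)
    return r1, amp, valid


def compute_mtsat(
    s_mtw0: np.ndarray,
    a: np.ndarray,
    r1: np.ndarray,
    protocol: AcquisitionProtocol,
) -> tuple[np.ndarray, np.ndarray]:
    """MT saturation in percent units from the MTw TE=0 intercept.

    delta = (A a_MT / S_MT0 - 1) R1 TR_MT - a_MT^2 / 2, returned as 100*delta.
    """
    alpha, tr = protocol.mtw.flip_angle_rad, protocol.mtw.tr
    s_mtw0 = np.asarray(s_mtw0, dtype=float)
    valid = np.isfinite(s_mtw0) & (s_mtw0 > 0) & np.isfinite(a) & np.isfinite(r1)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a * alpha / s_mtw0 - 1.0) * r1 * tr - alpha**2 / 2.0
    mtsat = np.where(valid, 100.0 * delta, np.nan)
    return mtsat, valid


def calibrate_pd(
    a: np.ndarray,
    reference_mask: np.ndarray,
    target_pu: float = 69.0,
) -> np.ndarray:
    """Scale the amplitude map so its median over the reference mask is target_pu.

    A is proportional to proton density; the calibration fixes the arbitrary
    global factor (convention: median PD in normal-appearing white matter is
    ``target_pu`` percent units) and leaves voxel ratios unchanged.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref = np.asarray(a, dtype=float)[reference_mask]
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("no finite amplitude values inside the reference mask")
    med = float(np.median(ref))
    if med == 0:
        raise ValueError("median amplitude over the reference mask is zero")
    return np.asarray(a, dtype=float) * (target_pu / med)


def estimate_parameter_maps(
    series: Iterable[MultiEchoSeries],
    protocol: AcquisitionProtocol,
    pd_reference_mask: np.ndarray | None = None,
    pd_target_pu: float = 69.0,
    weighted: bool = False,
) -> ParameterMaps:
    """Full estimation chain: ESTATICS -> (R1, A) -> MTsat -> calibrated PD."""
    series = {s.contrast: s for s in series}
    missing = [c for c in CONTRASTS if c not in series]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")
    fit = fit_estatics(series.values(), weighted=weighted)
    r1, amp, valid_r1 = compute_r1_amplitude(
        fit.intercepts["T1w"], fit.intercepts["PDw"], protocol
    )
    mtsat, valid_mt = compute_mtsat(fit.intercepts["MTw"], amp, r1, protocol)
    valid = fit.valid & valid_r1 & valid_mt
    if pd_reference_mask is not None:
        pd = calibrate_pd(amp, pd_reference_mask, target_pu=pd_target_pu)
    else:
        pd = amp.copy()
    return ParameterMaps(mtsat=mtsat, pd=pd, r1=r1, r2s=fit.r2s, a=amp, valid=valid)
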