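"""Per-lesion area analysis: long table construction and the area x time model.

Each enlarging lesion contributes, per timepoint and qMRI parameter, one
median value for each of its three areas (focal FLAIR core, initial
peripheral shell, later peripheral shell); NAWM contributes one median per
subject and timepoint.  Medians are log-transformed (they are positive and
right-skewed) and modelled per parameter with a linear mixed model

    log(median) ~ area * time + (1 | participant),

with the T0/T1 residuals of one measurement series (a lesion area, or the
subject's NAWM) allowed a common correlation — the two-timepoint reduction
of a first-order autoregressive residual model.  Estimation is REML with
the residual variance profiled out; fixed effects use deviation coding so
the Wald F-tests coincide with the classical two-way ANOVA decomposition
on balanced data.  Denominator degrees of freedom use a numerically
evaluated Satterthwaite approximation (per-contrast, combined across the
rows of multi-df hypotheses), falling back to residual df when the
information matrix is degenerate; the method used is always reported.

Pairwise area contrasts at each timepoint are adjusted with Tukey's
studentized-range procedure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .masks import AreaMasks
from .mpm import ParameterMaps, PARAMETERS

logger = logging.getLogger(__name__)

#: Area levels ordered from normal tissue toward the lesion core.
AREA_LEVELS = ("NAWM", "later_peripheral", "initial_peripheral", "focal_flair")
TIME_LEVELS = ("T0", "T1")


# ---------------------------------------------------------------------------
# long table


def build_long_table(
    maps_by_timepoint: Mapping[str, ParameterMaps],
    areas: AreaMasks,
    enlarging: Mapping[int, Mapping[str, np.ndarray]],
    subject_id: str,
    parameters=PARAMETERS,
) -> pd.DataFrame:
    """Median per lesion x area x timepoint x parameter, log-transformed.

    ``enlarging`` is the output of ``select_enlarging_lesions``.  Rows with
    an empty lesion-area intersection are omitted (logged); a non-positive
    median raises, since the log transform requires positive medians.
    """
    rows = []
    for tp in TIME_LEVELS:
        maps = maps_by_timepoint[tp]
        units: list[tuple[str, str, np.ndarray]] = [("NAWM", "NAWM", areas.nawm)]
        for lesion_id, parts in enlarging.items():
            for area, mask in parts.items():
                units.append((str(lesion_id), area, mask))
        for lesion_id, area, mask in units:
            mask = np.asarray(mask, dtype=bool)
            if maps.valid is not None:
                mask = mask & maps.valid
            if not mask.any():
                logger.warning(
                    "subject %s lesion %s area %s at %s: empty intersection, row omitted",
                    subject_id, lesion_id, area, tp,
                )
                continue
            for p in parameters:
                vals = maps[p][mask]
                vals = vals[np.isfinite(vals)]
                med = float(np.median(vals))
                if med <= 0:
                    raise ValueError(
                        f"non-positive median for {p} in {area} (lesion {lesion_id}, "
                        f"{tp}): log transform undefined"
                    )
                rows.append(
                    {
                        "subject": subject_id,
                        "lesion_id": lesion_id,
                        "area": area,
                        "timepoint": tp,
                        "parameter": p,
                        "median": med,
                        "log_value": float(np.log(med)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design helpers


def _deviation_codes(levels: tuple[str, ...], value: str) -> np.ndarray:
    """Deviation (sum-to-zero) coding, dropping the last level."""
    k = len(levels)
    row = np.zeros(k - 1)
    if value == levels[-1]:
        row[:] = -1.0
    else:
        row[levels.index(value)] = 1.0
    return row


@dataclass
class _Design:
    x: np.ndarray
    coef_names: list[str]
    areas: tuple[str, ...]
    times: tuple[str, ...]
    effect_slices: dict[str, np.ndarray]  # effect -> column indices

    def cell_row(self, area: str, time: str) -> np.ndarray:
        a = _deviation_codes(self.areas, area)
        t = _deviation_codes(self.times, time)
        return np.concatenate([[1.0], a, t, np.outer(a, t).ravel()])


def _build_design(table: pd.DataFrame) -> _Design:
    areas = tuple(a for a in AREA_LEVELS if a in set(table.area))
    times = tuple(t for t in TIME_LEVELS if t in set(table.timepoint))
    if len(areas) < 2:
        raise ValueError("need at least two areas to fit the model")
    if len(times) < 2:
        raise ValueError("need both timepoints to fit the model")
    rows, names = [], None
    for _, r in table.iterrows():
        a = _deviation_codes(areas, r.area)
        t = _deviation_codes(times, r.timepoint)
        rows.append(np.concatenate([[1.0], a, t, np.outer(a, t).ravel()]))
    x = np.asarray(rows)
    na, nt = len(areas) - 1, len(times) - 1
    names = (
        ["intercept"]
        + [f"area[{a}]" for a in areas[:-1]]
        + [f"time[{t}]" for t in times[:-1]]
        + [f"area[{a}]:time[{t}]" for a in areas[:-1] for t in times[:-1]]
    )
    slices = {
        "area": np.arange(1, 1 + na),
        "time": np.arange(1 + na, 1 + na + nt),
        "area:time": np.arange(1 + na + nt, 1 + na + nt + na * nt),
    }
    return _Design(x=x, coef_names=names, areas=areas, times=times, effect_slices=slices)


# ---------------------------------------------------------------------------
# REML machinery


def _pair_matrix(series_ids: np.ndarray) -> np.ndarray:
    """Symmetric 0/1 matrix linking the two observations of one series."""
    n = series_ids.size
    p = (series_ids[:, None] == series_ids[None, :]).astype(float)
    np.fill_diagonal(p, 0.0)
    return p


@dataclass
class _RemlProblem:
    y: np.ndarray
    x: np.ndarray
    zzt: np.ndarray  # subject random-intercept block matrix
    pair: np.ndarray  # residual-correlation pair matrix

    def v0(self, gamma: float, rho: float) -> np.ndarray:
        n = self.y.size
        return gamma * self.zzt + np.eye(n) + rho * self.pair

    def gls(self, gamma: float, rho: float):
        """Return (beta, xtvix_inv, resid, quad, logdet_v0, logdet_xtvix)."""
        v0 = self.v0(gamma, rho)
        try:
            c, low = linalg.cho_factor(v0, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_v0 = 2.0 * float(np.sum(np.log(np.diag(c))))
        vix = linalg.cho_solve((c, low), self.x, check_finite=False)
        viy = linalg.cho_solve((c, low), self.y, check_finite=False)
        xtvix = self.x.T @ vix
        try:
            beta = linalg.solve(xtvix, self.x.T @ viy, assume_a="pos")
            xtvix_inv = linalg.inv(xtvix)
        except linalg.LinAlgError:
            return None
        sign, logdet_xtvix = np.linalg.slogdet(xtvix)
        if sign <= 0:
            return None
        resid = self.y - self.x @ beta
        quad = float(resid @ linalg.cho_solve((c, low), resid, check_finite=False))
        return beta, xtvix_inv, resid, quad, logdet_v0, logdet_xtvix

    def profiled_deviance(self, gamma: float, rho: float) -> float:
        out = self.gls(gamma, rho)
        if out is None or out[3] <= 0:
            return 1e10
        _, _, _, quad, logdet_v0, logdet_xtvix = out
        n, p = self.y.size, self.x.shape[1]
        return logdet_v0 + logdet_xtvix + (n - p) * np.log(quad)

    def deviance(self, gamma: float, rho: float, sigma2: float) -> float:
        """-2 REML log-likelihood (up to the 2*pi constant) at full parameters."""
        out = self.gls(gamma, rho)
        if out is None or sigma2 <= 0:
            return 1e10
        _, _, _, quad, logdet_v0, logdet_xtvix = out
        n, p = self.y.size, self.x.shape[1]
        return (
            (n - p) * np.log(sigma2)
            + logdet_v0
            + logdet_xtvix
            + quad / sigma2
        )


def _num_hessian(f: Callable[[np.ndarray], float], x0: np.ndarray, rel_step=1e-4):
    k = x0.size
    h = np.maximum(np.abs(x0), 1.0) * rel_step
    hess = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i], ej[j] = h[i], h[j]
            if i == j:
                hess[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return hess


def _num_grad(f: Callable[[np.ndarray], float], x0: np.ndarray, rel_step=1e-4):
    k = x0.size
    h = np.maximum(np.abs(x0), 1.0) * rel_step
    g = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        g[i] = (f(x0 + e) - f(x0 - e)) / (2 * h[i])
    return g


@dataclass
class MixedModelFit:
    """REML fit of log(median) ~ area * time with participant intercept."""

    parameter: str
    coef: pd.Series
    cov_beta: np.ndarray
    varcomp: dict[str, float]  # sigma2, tau2 (subject), rho (within-series)
    fixed_tests: pd.DataFrame  # effect, F, df1, df2, p, df_method
    n_obs: int
    n_subjects: int
    converged: bool
    design: _Design = field(repr=False)
    _contrast_df: Callable[[np.ndarray], tuple[float, str]] = field(repr=False)

    def cell_mean(self, area: str, time: str) -> float:
        return float(self.design.cell_row(area, time) @ self.coef.to_numpy())


def fit_area_time_model(
    table: pd.DataFrame,
    random_intercept: bool = True,
    residual_correlation: str | None = "ar1",
    df_method: str = "satterthwaite",
) -> MixedModelFit:
    """Fit the area x time mixed model for one qMRI parameter.

    With ``random_intercept=False`` and ``residual_correlation=None`` the
    model collapses to ordinary least squares and the F-tests equal the
    classical fixed-effects two-way ANOVA (the degenerate configuration).

    ``df_method`` is "satterthwaite" (numeric, per-contrast) or "residual".
    """
    params = set(table.parameter) if "parameter" in table else {"value"}
    if len(params) != 1:
        raise ValueError("fit one parameter at a time")
    parameter = next(iter(params))
    if residual_correlation not in (None, "ar1"):
        raise ValueError("residual_correlation must be None or 'ar1'")

    table = table.reset_index(drop=True)
    subjects = table.subject.astype(str).to_numpy()
    if len(set(subjects)) < 2:
        raise ValueError("need at least two participants")
    design = _build_design(table)
    y = table.log_value.to_numpy(dtype=float)
    x = design.x
    n, p = y.size, x.shape[1]
    if n <= p:
        raise ValueError("not enough observations for the fixed-effects design")

    subj_codes = pd.factorize(subjects)[0]
    z = np.zeros((n, subj_codes.max() + 1))
    z[np.arange(n), subj_codes] = 1.0
    series = pd.factorize(
        table.subject.astype(str) + "|" + table.lesion_id.astype(str) + "|" + table.area
    )[0]
    problem = _RemlProblem(y=y, x=x, zzt=z @ z.T, pair=_pair_matrix(series))

    free: list[str] = []
    if random_intercept:
        free.append("gamma")
    if residual_correlation == "ar1":
        free.append("rho")

    gamma_hat, rho_hat, converged = 0.0, 0.0, True
    if free:
        def objective(theta: np.ndarray) -> float:
            g = theta[free.index("gamma")] if "gamma" in free else 0.0
            r = theta[free.index("rho")] if "rho" in free else 0.0
            return problem.profiled_deviance(g, r)

        x0 = np.array([0.5] * ("gamma" in free) + [0.1] * ("rho" in free))
        bounds = [(0.0, 1e3)] * ("gamma" in free) + [(-0.95, 0.95)] * ("rho" in free)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        converged = bool(res.success)
        if not converged:
            logger.warning("REML optimization did not converge: %s", res.message)
        theta = res.x
        if "gamma" in free:
            gamma_hat = float(theta[free.index("gamma")])
        if "rho" in free:
            rho_hat = float(theta[free.index("rho")])

    out = problem.gls(gamma_hat, rho_hat)
    if out is None:
        raise RuntimeError(
            "singular mixed-model fit: the marginal covariance or the design is "
            f"rank-deficient (gamma={gamma_hat:.3g}, rho={rho_hat:.3g}, n={n}, p={p})"
        )
    beta, xtvix_inv, resid, quad, _, _ = out
    sigma2 = quad / (n - p)
    cov_beta = sigma2 * xtvix_inv
    varcomp = {"sigma2": float(sigma2), "tau2": float(gamma_hat * sigma2), "rho": rho_hat}

    # ------------------------------------------------------------------ df
    theta_full = np.array([gamma_hat, rho_hat, sigma2])
    at_boundary = np.array(
        [
            ("gamma" not in free) or gamma_hat <= 1e-8,
            ("rho" not in free) or abs(rho_hat) >= 0.95 - 1e-8,
            False,
        ]
    )
    active = ~at_boundary

    w_info: np.ndarray | None = None
    if df_method == "satterthwaite" and active.any():
        def dev_active(t_act: np.ndarray) -> float:
            t = theta_full.copy()
            t[active] = t_act
            return problem.deviance(t[0], t[1], t[2])

        try:
            hess = _num_hessian(dev_active, theta_full[active])
            info = 0.5 * hess
            # a near-singular information matrix means the variance parameters
            # are not identified at this optimum; fall back to residual df
            if np.linalg.cond(info) > 1e10:
                w_info = None
            else:
                w_info = linalg.inv(info)
                if not np.all(np.isfinite(w_info)) or np.any(np.diag(w_info) < 0):
                    w_info = None
        except (linalg.LinAlgError, ValueError):
            w_info = None

    def contrast_variance(theta: np.ndarray, ell: np.ndarray) -> float:
        g, r, s2 = theta
        out_t = problem.gls(g, r)
        if out_t is None:
            return np.nan
        return float(s2 * ell @ out_t[1] @ ell)

    def contrast_df(ell: np.ndarray) -> tuple[float, str]:
        if df_method == "satterthwaite" and w_info is not None:
            def v_of(t_act: np.ndarray) -> float:
                t = theta_full.copy()
                t[active] = t_act
                return contrast_variance(t, ell)

            grad = _num_grad(v_of, theta_full[active])
            denom = float(grad @ w_info @ grad)
            v_hat = contrast_variance(theta_full, ell)
            if denom > 0 and np.isfinite(v_hat):
                nu = 2.0 * v_hat**2 / denom
                if np.isfinite(nu) and nu > 1.0:
                    return min(nu, float(n - p)), "satterthwaite"
        return float(n - p), "residual"

    tests = []
    for effect, cols in design.effect_slices.items():
        ell_mat = np.zeros((cols.size, p))
        ell_mat[np.arange(cols.size), cols] = 1.0
        est = ell_mat @ beta
        middle = ell_mat @ cov_beta @ ell_mat.T
        try:
            f_stat = float(est @ linalg.solve(middle, est, assume_a="pos")) / cols.size
        except linalg.LinAlgError:
            raise RuntimeError(f"singular contrast covariance for effect {effect!r}")
        # combine per-row Satterthwaite dfs as in lmerTest: eigen-contrasts
        evals, evecs = linalg.eigh(middle)
        dfs = []
        for k in range(cols.size):
            if evals[k] <= 0:
                continue
            ell_k = evecs[:, k] @ ell_mat
            dfs.append(contrast_df(ell_k)[0])
        method = "residual"
        if df_method == "satterthwaite" and w_info is not None and dfs:
            method = "satterthwaite"
        if dfs:
            dfs = np.asarray(dfs)
            good = dfs[dfs > 2.0]
            if good.size:
                e_sum = float(np.sum(good / (good - 2.0)))
                df2 = 2.0 * e_sum / max(e_sum - good.size, 1e-12) if e_sum > good.size else float(n - p)
            else:
                df2 = float(n - p)
            df2 = min(df2, float(n - p))
        else:
            df2 = float(n - p)
        p_val = float(stats.f.sf(f_stat, cols.size, df2))
        tests.append(
            {"effect": effect, "F": f_stat, "df1": int(cols.size), "df2": df2,
             "p": p_val, "df_method": method}
        )

    fit = MixedModelFit(
        parameter=parameter,
        coef=pd.Series(beta, index=design.coef_names),
        cov_beta=cov_beta,
        varcomp=varcomp,
        fixed_tests=pd.DataFrame(tests),
        n_obs=n,
        n_subjects=int(subj_codes.max() + 1),
        converged=converged,
        design=design,
        _contrast_df=contrast_df,
    )
    return fit


def pairwise_area_contrasts(fit: MixedModelFit) -> pd.DataFrame:
    """All pairwise area differences at each timepoint, Tukey-adjusted.

    The studentized-range adjustment uses the number of area levels as the
    family size; degrees of freedom per contrast follow the fit's df method.
    """
    areas, times = fit.design.areas, fit.design.times
    k = len(areas)
    beta = fit.coef.to_numpy()
    rows = []
    for time in times:
        for a1, a2 in itertools.combinations(areas, 2):
            ell = fit.design.cell_row(a1, time) - fit.design.cell_row(a2, time)
            est = float(ell @ beta)
            se = float(np.sqrt(ell @ fit.cov_beta @ ell))
            df, method = fit._contrast_df(ell)
            t_stat = est / se
            p_adj = float(stats.studentized_range.sf(abs(t_stat) * np.sqrt(2.0), k, df))
            rows.append(
                {
                    "timepoint": time,
                    "area_1": a1,
                    "area_2": a2,
                    "estimate": est,
                    "se": se,
                    "t": t_stat,
                    "df": df,
                    "p_tukey": min(p_adj, 1.0),
                    "df_method": method,
                }
            )
    return pd.DataFrame(rows)
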