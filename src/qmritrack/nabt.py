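"""Annual rate of change in normal-appearing tissues and its inference.

For each subject, tissue class (NAWM, NACGM, NADGM) and parameter (MTsat,
PD, R1, R2*), the median map value is extracted at both timepoints and
turned into an annual rate of change (ARoC).  Each of the 12 tissue x
parameter ARoC vectors is regressed on the binary disease-activity status,

    Y = b0 + b1 * X_status + e,

and the coefficient of determination R^2 is tested by permutation: the
status labels are shuffled n times (every draw distinct from the observed
labels), and p = #(R_perm > R_obs) / (n + 1).  The 12 p-values are
corrected with the Benjamini-Hochberg step-up procedure at q = 0.05, and
Welch two-sample t-tests are applied post hoc to the rejected tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mpm import ParameterMaps, PARAMETERS
from .phantom import NORMAL_TISSUES

N_PERMUTATIONS_DEFAULT = 5000
FDR_Q_DEFAULT = 0.05
EXHAUSTIVE_LIMIT = 10**6


@dataclass
class ArocRegression:
    """OLS fit of ARoC on the binary status regressor."""

    beta0: float
    beta1: float
    residuals: np.ndarray
    r_obs: float  # coefficient of determination


@dataclass
class PermutationResult:
    """Permutation distribution of R^2 and the resulting p-value."""

    n: int
    r_perm: np.ndarray
    r_obs: float
    p: float
    seed: int | None
    mode: str


def extract_tissue_medians(
    maps: ParameterMaps,
    tissue_masks: dict[str, np.ndarray],
    tissues=NORMAL_TISSUES,
    parameters=PARAMETERS,
) -> dict[str, dict[str, float]]:
    """Median map value over each tissue mask, ignoring invalid voxels."""
    out: dict[str, dict[str, float]] = {}
    for tissue in tissues:
        mask = np.asarray(tissue_masks[tissue], dtype=bool)
        if maps.valid is not None:
            mask = mask & maps.valid
        if not mask.any():
            raise ValueError(f"tissue mask {tissue!r} is empty (no valid voxels)")
        out[tissue] = {}
        for p in parameters:
            vals = maps[p][mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"no finite {p} values inside {tissue!r}")
            out[tissue][p] = float(np.median(vals))
    return out


def aroc(
    median_t0: float,
    median_t1: float,
    interval_years: float,
    mode: str = "absolute",
) -> float:
    """Annual rate of change between two medians.

    absolute: (T1 - T0) / years (units/year); relative: 100 (T1 - T0) / T0
    / years (%/year).
    """
    if interval_years <= 0:
        raise ValueError("interval_years must be positive")
    if mode == "absolute":
        return (median_t1 - median_t0) / interval_years
    if mode == "relative":
        if median_t0 == 0:
            raise ValueError("relative ARoC undefined for median_t0 = 0")
        return 100.0 * (median_t1 - median_t0) / median_t0 / interval_years
    raise ValueError("mode must be 'absolute' or 'relative'")


def _check_xy(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("Y and X must be 1D vectors of equal length")
    if y.size < 3:
        raise ValueError("need at least three observations")
    if not (np.any(x == 0) and np.any(x == 1)) or not np.all(np.isin(x, (0, 1))):
        raise ValueError("X must be binary with both groups present")
    return y, x


def fit_status_glm(y, x) -> ArocRegression:
    """OLS of Y on the binary status regressor.

    With binary X the slope is the group-mean difference and R^2 is the
    between-group over total sum of squares.
    """
    y, x = _check_xy(y, x)
    beta1 = float(y[x == 1].mean() - y[x == 0].mean())
    beta0 = float(y[x == 0].mean())
    fitted = beta0 + beta1 * x
    resid = y - fitted
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        import warnings

        warnings.warn("constant response: R^2 defined as 0", stacklevel=2)
        r2 = 0.0
    else:
        ssb = float(((fitted - y.mean()) ** 2).sum())
        r2 = ssb / sst
    return ArocRegression(beta0=beta0, beta1=beta1, residuals=resid, r_obs=r2)


def _r2_binary(yc: np.ndarray, xs: np.ndarray, ss_y: float, ss_x: float) -> np.ndarray:
    """R^2 of Y on each row of centered binary regressors xs (vectorized)."""
    cov = xs @ yc
    return cov**2 / (ss_x * ss_y)


def permutation_pvalue(
    y,
    x,
    n: int = N_PERMUTATIONS_DEFAULT,
    seed: int | None = None,
    mode: str = "sampled",
) -> PermutationResult:
    """Permutation test of R^2 for the status regression.

    sampled: n random shuffles of X, re-drawn on collision with the
    observed labels.  exhaustive: all distinct binary label arrangements
    different from X (requires the count to stay below 10^6); their number
    becomes n.  In both modes p = #(R_perm > R_obs) / (n + 1), strict.
    """
    y, x = _check_xy(y, x)
    if np.allclose(y, y[0]):
        raise ValueError("constant response: permutation R^2 is degenerate")
    obs = fit_status_glm(y, x)
    yc = y - y.mean()
    ss_y = float((yc**2).sum())
    ss_x = float(((x - x.mean()) ** 2).sum())  # invariant under relabelling
    # compute the observed R^2 through the same arithmetic as the permuted
    # ones so that exact ties (e.g. the label complement) cancel bit for bit
    r_obs = float(_r2_binary(yc, (x - x.mean())[None, :], ss_y, ss_x)[0])

    if mode == "exhaustive":
        n_ones = int(x.sum())
        total = math.comb(y.size, n_ones)
        if total > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"{total} arrangements exceed the exhaustive limit; use mode='sampled'"
            )
        xs = []
        for ones in itertools.combinations(range(y.size), n_ones):
            cand = np.zeros(y.size)
            cand[list(ones)] = 1.0
            if not np.array_equal(cand, x):
                xs.append(cand)
        xs = np.asarray(xs)
        n = xs.shape[0]
    elif mode == "sampled":
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        xs = np.empty((n, y.size))
        pending = np.arange(n)
        while pending.size:  # uniform shuffles; collisions with X are re-drawn
            order = np.argsort(rng.random((pending.size, y.size)), axis=1)
            cand = x[order]
            xs[pending] = cand
            pending = pending[(cand == x).all(axis=1)]
    else:
        raise ValueError("mode must be 'sampled' or 'exhaustive'")

    xs_c = xs - xs.mean(axis=1, keepdims=True)
    r_perm = _r2_binary(yc, xs_c, ss_y, ss_x)
    p = float(np.count_nonzero(r_perm > r_obs)) / (n + 1)  # strict: ties do not count
    return PermutationResult(n=n, r_perm=r_perm, r_obs=obs.r_obs, p=p, seed=seed, mode=mode)


def bh_fdr(p_values, q: float = FDR_Q_DEFAULT) -> np.ndarray:
    """Benjamini-Hochberg step-up over the supplied family; returns rejected indices."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.flatnonzero(reject)


def posthoc_group_ttest(values, labels) -> tuple[float, float, float]:
    """Welch two-sample t-test between status groups; returns (t, df, p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    g0, g1 = values[labels == 0], values[labels == 1]
    if g0.size < 2 or g1.size < 2:
        raise ValueError("both status groups need at least two observations")
    res = stats.ttest_ind(g1, g0, equal_var=False)
    v0, v1 = g0.var(ddof=1) / g0.size, g1.var(ddof=1) / g1.size
    df = (v0 + v1) ** 2 / (v0**2 / (g0.size - 1) + v1**2 / (g1.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def build_aroc_table(
    medians: pd.DataFrame,
    mode: str = "absolute",
) -> pd.DataFrame:
    """Long ARoC table from a per-subject/timepoint median table.

    ``medians`` columns: subject, timepoint, tissue, parameter, median,
    interval_months.  One output row per subject x tissue x parameter.
    """
    rows = []
    key = ["subject", "tissue", "parameter"]
    for (subject, tissue, parameter), g in medians.groupby(key, sort=False):
        t0 = g[g.timepoint == "T0"].iloc[0]
        t1 = g[g.timepoint == "T1"].iloc[0]
        years = float(t0.interval_months) / 12.0
        rows.append(
            {
                "subject": subject,
                "tissue": tissue,
                "parameter": parameter,
                "median_T0": float(t0["median"]),
                "median_T1": float(t1["median"]),
                "interval_years": years,
                "aroc": aroc(float(t0["median"]), float(t1["median"]), years, mode=mode),
            }
        )
    return pd.DataFrame(rows)


def run_nabt_analysis(
    aroc_table: pd.DataFrame,
    status: pd.DataFrame,
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    seed: int | None = None,
    q: float = FDR_Q_DEFAULT,
) -> pd.DataFrame:
    """The 12-test inference stage: regression, permutation p, FDR, post hoc.

    ``status`` maps subject -> binary status.  Returns one row per tissue x
    parameter with beta0, beta1, R2, p_perm, fdr_rejected and (for rejected
    tests) the Welch post-hoc t and p.
    """
    status_of = dict(zip(status.subject_id, status.status))
    rows = []
    rng = np.random.default_rng(seed)
    for tissue in NORMAL_TISSUES:
        for parameter in PARAMETERS:
            sub = aroc_table[
                (aroc_table.tissue == tissue) & (aroc_table.parameter == parameter)
            ]
            y = sub.aroc.to_numpy()
            x = np.array([status_of[s] for s in sub.subject], dtype=float)
            fit = fit_status_glm(y, x)
            perm = permutation_pvalue(
                y, x, n=n_permutations, seed=int(rng.integers(2**31 - 1))
            )
            rows.append(
                {
                    "tissue": tissue,
                    "parameter": parameter,
                    "beta0": fit.beta0,
                    "beta1": fit.beta1,
                    "r2": fit.r_obs,
                    "p_perm": perm.p,
                    "y": y,
                    "x": x,
                }
            )
    table = pd.DataFrame(rows)
    rejected = bh_fdr(table.p_perm.to_numpy(), q=q)
    table["fdr_rejected"] = False
    table.loc[rejected, "fdr_rejected"] = True
    table["posthoc_t"] = np.nan
    table["posthoc_df"] = np.nan
    table["posthoc_p"] = np.nan
    for i in rejected:
        try:
            t, df, p = posthoc_group_ttest(table.at[i, "y"], table.at[i, "x"])
        except ValueError as exc:  # a status group with < 2 subjects
            import warnings

            warnings.warn(
                f"post-hoc t-test skipped for {table.at[i, 'tissue']}/"
                f"{table.at[i, 'parameter']}: {exc}",
                stacklevel=2,
            )
            continue
        table.at[i, "posthoc_t"] = t
        table.at[i, "posthoc_df"] = df
        table.at[i, "posthoc_p"] = p
    return table.drop(columns=["y", "x"])
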