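"""Long lesion table and the area x time mixed model."""

import numpy as np
import pandas as pd
import pytest

from qmritrack import masks as msk
from qmritrack.lesions import (
    AREA_LEVELS,
    build_long_table,
    fit_area_time_model,
    pairwise_area_contrasts,
)
from qmritrack.mpm import ParameterMaps
from qmritrack.phantom import PhantomConfig, generate_phantom, sphere_mask


def _phantom_long_table(seed=3, n_subjects=4, status_effect=None, visit_sd=0.005):
    cfg = PhantomConfig(
        n_subjects=n_subjects,
        seed=seed,
        grid_shape=(40, 46, 40),
        n_lesions_per_subject=2,
        status_effect=status_effect or {},
        visit_sd_frac=visit_sd,
    )
    truth = generate_phantom(cfg)
    tables = []
    for s in truth.subjects:
        b = {
            tp: msk.binarize_tissues(
                msk.TissuePosteriors(s.timepoints[tp].posteriors, cfg.voxel_size)
            )
            for tp in ("T0", "T1")
        }
        l0 = msk.clean_lesion_mask(b["T0"]["lesion"], cfg.voxel_size)
        l1 = msk.clean_lesion_mask(b["T1"]["lesion"], cfg.voxel_size)
        areas = msk.build_lesion_areas(
            s.timepoints["T0"].flair_mask, l0, l1, b["T0"]["NAWM"] | l0 | l1
        )
        enlarging = msk.select_enlarging_lesions(areas)
        maps = {tp: s.timepoints[tp].maps for tp in ("T0", "T1")}
        tables.append(build_long_table(maps, areas, enlarging, s.subject_id))
    return pd.concat(tables, ignore_index=True)


def _balanced_table(rng, n_subjects=4, n_lesions=3, area_effects=None,
                    time_effect=0.0, subject_sd=0.0, noise_sd=0.1, rho=0.0):
    """Synthetic long table with known effects for oracle comparisons."""
    area_effects = area_effects or {a: 0.0 for a in AREA_LEVELS}
    rows = []
    for si in range(n_subjects):
        b_subj = rng.normal(0, subject_sd) if subject_sd > 0 else 0.0
        for lid in range(n_lesions):
            for area in AREA_LEVELS:
                shared = rng.normal(0, noise_sd)
                for tp, tval in (("T0", 0.0), ("T1", time_effect)):
                    eps = rho * shared + np.sqrt(1 - rho**2) * rng.normal(0, noise_sd)
                    mu = 1.0 + area_effects[area] + tval + b_subj + eps
                    rows.append(
                        dict(subject=f"s{si}", lesion_id=str(lid), area=area,
                             timepoint=tp, parameter="MTsat",
                             median=float(np.exp(mu)), log_value=mu)
                    )
    return pd.DataFrame(rows)


class TestLongTable:
    def test_row_count_single_lesion(self):
        shape = (24, 24, 24)
        flair = sphere_mask(shape, (12, 12, 12), 2.0, (1, 1, 1))
        t0 = sphere_mask(shape, (12, 12, 12), 4.0, (1, 1, 1))
        t1 = sphere_mask(shape, (12, 12, 12), 6.0, (1, 1, 1))
        areas = msk.build_lesion_areas(flair, t0, t1, np.ones(shape, dtype=bool))
        enlarging = msk.select_enlarging_lesions(areas)
        arr = np.full(shape, 2.0)
        maps = ParameterMaps(mtsat=arr, pd=arr, r1=arr, r2s=arr, a=arr)
        table = build_long_table({"T0": maps, "T1": maps}, areas, enlarging, "s0")
        # (3 lesion areas + NAWM) x 2 timepoints x 4 parameters
        assert len(table) == 32

    def test_phantom_gradient_ordering(self):
        """Programmed periplaque gradient: focal < initial < later < NAWM."""
        table = _phantom_long_table(seed=5, n_subjects=2)
        mt = table[table.parameter == "MTsat"]
        means = mt.groupby("area").log_value.mean()
        assert (
            means["focal_flair"]
            < means["initial_peripheral"]
            < means["later_peripheral"]
            < means["NAWM"]
        )
        pd_means = table[table.parameter == "PD"].groupby("area").log_value.mean()
        assert (
            pd_means["focal_flair"]
            > pd_means["initial_peripheral"]
            > pd_means["later_peripheral"]
            > pd_means["NAWM"]
        )

    def test_negative_values_fail_log(self):
        shape = (24, 24, 24)
        flair = sphere_mask(shape, (12, 12, 12), 2.0, (1, 1, 1))
        t0 = sphere_mask(shape, (12, 12, 12), 4.0, (1, 1, 1))
        t1 = sphere_mask(shape, (12, 12, 12), 6.0, (1, 1, 1))
        areas = msk.build_lesion_areas(flair, t0, t1, np.ones(shape, dtype=bool))
        enlarging = msk.select_enlarging_lesions(areas)
        arr = np.full(shape, -1.0)
        maps = ParameterMaps(mtsat=arr, pd=arr, r1=arr, r2s=arr, a=arr)
        with pytest.raises(ValueError, match="log"):
            build_long_table({"T0": maps, "T1": maps}, areas, enlarging, "s0")


class TestFitReducesToAnova:
    def test_matches_fixed_effects_anova_oracle(self, rng):
        """Degenerate configuration equals the two-way OLS ANOVA exactly."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        table = _balanced_table(rng, subject_sd=0.0, rho=0.0,
                                area_effects={"NAWM": 0.6, "later_peripheral": 0.4,
                                              "initial_peripheral": 0.2,
                                              "focal_flair": 0.0},
                                time_effect=0.05)
        fit = fit_area_time_model(table, random_intercept=False,
                                  residual_correlation=None)
        ols = smf.ols("log_value ~ C(area, Sum) * C(timepoint, Sum)", data=table).fit()
        anova = sm.stats.anova_lm(ols, typ=3)
        oracle = {
            "area": anova.loc["C(area, Sum)", "F"],
            "time": anova.loc["C(timepoint, Sum)", "F"],
            "area:time": anova.loc["C(area, Sum):C(timepoint, Sum)", "F"],
        }
        for _, row in fit.fixed_tests.iterrows():
            assert abs(row.F - oracle[row.effect]) < 1e-6
            assert row.df2 == pytest.approx(table.shape[0] - 8, abs=1e-6)

    def test_row_order_invariance(self, rng):
        table = _balanced_table(rng, subject_sd=0.2, rho=0.3)
        fit1 = fit_area_time_model(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = fit_area_time_model(shuffled)
        pd.testing.assert_series_equal(fit1.coef, fit2.coef, rtol=1e-5)
        np.testing.assert_allclose(
            fit1.fixed_tests.F.to_numpy(), fit2.fixed_tests.F.to_numpy(), rtol=1e-5
        )

    def test_scale_shifts_only_intercept(self, rng):
        table = _balanced_table(rng, subject_sd=0.2, rho=0.2)
        fit1 = fit_area_time_model(table)
        scaled = table.copy()
        scaled["median"] = scaled["median"] * 3.7
        scaled["log_value"] = np.log(scaled["median"])
        fit2 = fit_area_time_model(scaled)
        np.testing.assert_allclose(
            fit1.fixed_tests.F.to_numpy(), fit2.fixed_tests.F.to_numpy(), rtol=1e-6
        )
        assert fit2.coef["intercept"] - fit1.coef["intercept"] == pytest.approx(
            np.log(3.7), abs=1e-6
        )
        np.testing.assert_allclose(
            fit1.coef.drop("intercept").to_numpy(),
            fit2.coef.drop("intercept").to_numpy(),
            atol=1e-6,
        )


class TestVarianceComponents:
    def test_random_intercept_matches_mixedlm(self, rng):
        """Cross-check the REML machinery against statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        table = _balanced_table(rng, n_subjects=6, subject_sd=0.3, rho=0.0)
        fit = fit_area_time_model(table, residual_correlation=None)
        lmm = smf.mixedlm(
            "log_value ~ C(area, Sum) * C(timepoint, Sum)",
            data=table,
            groups=table.subject,
        ).fit(reml=True)
        assert fit.varcomp["tau2"] == pytest.approx(
            float(lmm.cov_re.iloc[0, 0]), rel=0.05, abs=1e-4
        )
        assert fit.varcomp["sigma2"] == pytest.approx(float(lmm.scale), rel=0.02)
        assert fit.coef["intercept"] == pytest.approx(
            float(lmm.params["Intercept"]), rel=1e-4
        )

    def test_known_effects_recovered(self, rng):
        """Area contrasts track programmed values over replicates."""
        effects = {"NAWM": 0.6, "later_peripheral": 0.4,
                   "initial_peripheral": 0.2, "focal_flair": 0.0}
        diffs = []
        for _ in range(60):
            table = _balanced_table(rng, n_subjects=3, n_lesions=2,
                                    area_effects=effects, subject_sd=0.1,
                                    noise_sd=0.08, rho=0.3)
            fit = fit_area_time_model(table)
            diffs.append(fit.cell_mean("NAWM", "T0") - fit.cell_mean("focal_flair", "T0"))
        diffs = np.asarray(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean() - 0.6) < 2 * mc_se + 1e-3

    def test_effect_attribution(self, rng):
        """Pure area effect: area F dominates, time/interaction stay small."""
        effects = {"NAWM": 0.5, "later_peripheral": 0.3,
                   "initial_peripheral": 0.15, "focal_flair": 0.0}
        area_f, time_p, inter_p = [], [], []
        for _ in range(100):
            table = _balanced_table(rng, n_subjects=3, n_lesions=2,
                                    area_effects=effects, time_effect=0.0,
                                    subject_sd=0.1, noise_sd=0.1)
            fit = fit_area_time_model(table)
            t = fit.fixed_tests.set_index("effect")
            area_f.append(t.loc["area", "F"])
            time_p.append(t.loc["time", "p"])
            inter_p.append(t.loc["area:time", "p"])
        assert np.median(area_f) > 20
        # null effects reject at roughly the nominal 5% level
        assert np.mean(np.asarray(time_p) < 0.05) < 0.15
        assert np.mean(np.asarray(inter_p) < 0.05) < 0.15


class TestContrasts:
    def test_six_pairs_per_timepoint(self, rng):
        table = _balanced_table(rng, subject_sd=0.1, rho=0.2)
        fit = fit_area_time_model(table)
        contrasts = pairwise_area_contrasts(fit)
        assert len(contrasts) == 12
        assert (contrasts.groupby("timepoint").size() == 6).all()

    def test_equal_means_not_significant(self, rng):
        table = _balanced_table(rng, n_subjects=5, noise_sd=0.2)
        fit = fit_area_time_model(table)
        contrasts = pairwise_area_contrasts(fit)
        assert contrasts.p_tukey.min() > 0.05

    def test_phantom_gradient_all_significant(self):
        table = _phantom_long_table(seed=9, n_subjects=3)
        fit = fit_area_time_model(table[table.parameter == "MTsat"])
        contrasts = pairwise_area_contrasts(fit)
        assert (contrasts.p_tukey < 0.05).all()
        # ordering NAWM > later > initial > focal for MTsat
        for time in ("T0", "T1"):
            assert fit.cell_mean("NAWM", time) > fit.cell_mean("later_peripheral", time)
            assert fit.cell_mean("later_peripheral", time) > fit.cell_mean(
                "initial_peripheral", time
            )
            assert fit.cell_mean("initial_peripheral", time) > fit.cell_mean(
                "focal_flair", time
            )

    def test_insufficient_data_raises(self):
        table = pd.DataFrame(
            dict(subject=["s0"] * 4, lesion_id=["0"] * 4,
                 area=["NAWM", "NAWM", "focal_flair", "focal_flair"],
                 timepoint=["T0", "T1", "T0", "T1"], parameter=["MTsat"] * 4,
                 median=[1.0] * 4, log_value=[0.0] * 4)
        )
        with pytest.raises(ValueError, match="participants"):
            fit_area_time_model(table)
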