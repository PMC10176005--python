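# qmritrack

Longitudinal quantitative-MRI analysis of multiple-sclerosis brain, built
as a reusable, tested pipeline.  From two scanning sessions per patient it
tracks microstructural change in normal-appearing tissue and around
white-matter plaques using the four multiparameter-mapping (MPM) maps —
magnetization-transfer saturation (MTsat), proton density (PD), and the
relaxation rates R1 = 1/T1 and R2* = 1/T2* — which are sensitive to myelin,
iron and water content.

The package is aimed at neuroimaging researchers who want the complete
analysis chain runnable and testable without access to patient data: a
synthetic two-timepoint phantom cohort with known ground truth stands in
for the MRI dataset, so every stage can be validated end to end.

## What the pipeline computes

1. **Map estimation** (`qmritrack.mpm`).  From three multi-echo FLASH
   series (MTw/PDw/T1w), a shared-R2\* log-linear fit (ESTATICS)
   extrapolates each series to TE = 0; the intercepts are inverted with the
   rational small-flip-angle FLASH approximation to give R1 and the
   amplitude A, then MTsat
   `δ = (A·α/S_MT(0) − 1)·TR·R1 − α²/2` and a PD map calibrated to median
   69 p.u. in normal-appearing white matter.
2. **Masks** (`qmritrack.masks`).  Tissue posteriors are binarized (argmax,
   strict 0.2 threshold), lesion components < 10 mm³ removed, and four
   exclusive areas built per subject: focal FLAIR lesion, initial
   peripheral (T0), later peripheral (T1 \ T0), and lesion-excluded NAWM.
   Only *enlarging* lesions — present in all three lesion areas — enter the
   per-lesion analysis.
3. **Volumetrics** (`qmritrack.volumetry`).  TIV, brain-parenchymal,
   gray-matter and lesion fractions, annualized percent change, one-sample
   t-tests.
4. **Disease activity** (`qmritrack.clinical`).  NEDA-3 per half-interval
   (relapse, new/enlarged lesion, sustained EDSS progression: 1.0 point
   below the EDSS 4.0 milestone, 0.5 from 4.0 up), with final status
   `X = 0` only when both half-intervals show activity.
5. **NABT inference** (`qmritrack.nabt`).  Annual rate of change (ARoC) of
   each tissue median, regressed on status (`Y = β₀ + β₁X + ε`);
   permutation inference on R² with `p = #(R_π > R_obs)/(n+1)` at n = 5000,
   Benjamini–Hochberg FDR over the 12 tests (3 tissues × 4 parameters),
   Welch post-hoc t-tests.
6. **Lesion model** (`qmritrack.lesions`).  Per-lesion area × time linear
   mixed model on log medians with a participant random intercept and
   correlated within-series residuals (the two-timepoint reduction of
   AR(1)), REML estimation, Satterthwaite df, Tukey-adjusted pairwise area
   contrasts.

`docs/methods.md` documents the models, defaults and design decisions.

## Worked example

Run the numbered drivers in `analysis/` (they share one seeded cohort and
write tables under `results/`), or call the library directly:

```python
from qmritrack.pipeline import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(seed=0), out_dir="results/pipeline")
print(results["nabt"][["tissue", "parameter", "beta1", "p_perm", "fdr_rejected"]])
```

On the default 17-subject cohort this prints (abridged; `analysis/06`
formats the full table):

```
 MTsat: +0.042 (0.000)*  +0.038 (0.000)*  +0.001 (0.864)
    PD: +0.000 (0.940)   -0.031 (0.889)   -0.263 (0.083)
    R1: -0.000 (0.978)   +0.000 (0.981)   -0.000 (0.759)
   R2s: +0.298 (0.000)*  +0.294 (0.000)*  +0.010 (0.835)
columns: NAWM, NACGM, NADGM;  * = significant after FDR (q = 0.05)
```

Each cell is the status coefficient β₁ (units/year) with its permutation
p-value.  The phantom programs a "repair" drift of +0.039 p.u./yr MTsat and
+0.295 /s/yr R2\* into the NAWM and cortical GM of clinically stable
subjects, and exactly those four tests are recovered as significant after
FDR; deep gray matter, PD and R1 — which carry no programmed effect — stay
null.  The volumetric stage on the same cohort reports
`BPF: mean −0.70 ± 0.06 %/yr, t(16) = −51.3` against a programmed atrophy
of −0.67 %/yr (the residual is rasterization error), and
`LF: +48.6 ± 25.2 %/yr` from the programmed lesion growth.

The per-lesion stage (`analysis/07`) recovers the periplaque gradient —
median MTsat/R1/R2\* increasing from the focal lesion through the initial
and later peripheral shells to NAWM, PD decreasing — with all 48
Tukey-adjusted area contrasts significant and a dominant area effect
(e.g. MTsat `F(3,172) ≈ 3.7·10⁴`).

A command-line interface mirrors the stages
(`qmritrack simulate | fit-mpm | segment-areas | status | nabt | lesions |
run`); volumes are NIfTI, tables CSV, configuration YAML.

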