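"""End-to-end orchestration of the longitudinal qMRI analysis.

One call runs: phantom cohort simulation -> (optional) FLASH forward
simulation and map re-estimation -> tissue/lesion mask construction ->
volumetrics -> clinical status scoring -> normal-appearing-tissue ARoC
inference -> per-lesion area x time mixed models.  All randomness flows
from a single master seed through per-stage derived seeds; stage tables are
written as CSV together with a JSON manifest recording configuration,
seeds and output hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import lesions as les
from . import masks as msk
from . import nabt
from . import volumetry as vol
from .mpm import PARAMETERS, ParameterMaps, estimate_parameter_maps
from .phantom import (
    NORMAL_TISSUES,
    PhantomConfig,
    PhantomTruth,
    generate_phantom,
    simulate_flash_series,
)
from .protocol import AcquisitionProtocol


@dataclass
class PipelineConfig:
    """Defaults reproduce the analysis constants: binarization threshold 0.2,
    lesion cleaning below 10 mm^3, 5000 permutations, FDR q = 0.05,
    26-connectivity, absolute ARoC."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol.default)
    use_estimated_maps: bool = True
    binarization_threshold: float = 0.2
    min_lesion_volume_mm3: float = 10.0
    connectivity: int = 26
    n_permutations: int = 5000
    fdr_q: float = 0.05
    aroc_mode: str = "absolute"
    seed: int = 0

    def derived(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31 - 1)


@dataclass
class SubjectData:
    """Per-subject per-timepoint processed volumes."""

    maps: dict[str, ParameterMaps]
    tissue_masks: dict[str, dict[str, np.ndarray]]
    lesion_mask: dict[str, np.ndarray]
    areas: msk.AreaMasks
    enlarging: dict


def _subject_volumes(config: PipelineConfig, truth, subject) -> SubjectData:
    vox = config.phantom.voxel_size
    maps: dict[str, ParameterMaps] = {}
    tissue_masks: dict[str, dict[str, np.ndarray]] = {}
    lesion_mask: dict[str, np.ndarray] = {}
    for tp, tpdata in subject.timepoints.items():
        post = msk.TissuePosteriors(probabilities=tpdata.posteriors, voxel_size=vox)
        binarized = msk.binarize_tissues(post, threshold=config.binarization_threshold)
        cleaned = msk.clean_lesion_mask(
            binarized["lesion"],
            voxel_size=vox,
            min_volume_mm3=config.min_lesion_volume_mm3,
            connectivity=config.connectivity,
        )
        binarized["lesion"] = cleaned
        tissue_masks[tp] = binarized
        lesion_mask[tp] = cleaned
        if config.use_estimated_maps:
            series = simulate_flash_series(
                tpdata.maps,
                config.protocol,
                noise_sd=config.phantom.noise_sd,
                seed=config.derived(f"flash:{subject.subject_id}:{tp}"),
            )
            maps[tp] = estimate_parameter_maps(
                series.values(),
                config.protocol,
                pd_reference_mask=binarized["NAWM"],
            )
        else:
            maps[tp] = tpdata.maps
    areas = msk.build_lesion_areas(
        subject.timepoints["T0"].flair_mask,
        lesion_mask["T0"],
        lesion_mask["T1"],
        tissue_masks["T0"]["NAWM"] | lesion_mask["T0"] | lesion_mask["T1"],
        connectivity=config.connectivity,
    )
    enlarging = msk.select_enlarging_lesions(areas)
    return SubjectData(
        maps=maps,
        tissue_masks=tissue_masks,
        lesion_mask=lesion_mask,
        areas=areas,
        enlarging=enlarging,
    )


def _nabt_masks(data: SubjectData, tp: str) -> dict[str, np.ndarray]:
    """Tissue masks for median extraction; NAWM excludes all lesion areas."""
    m = dict(data.tissue_masks[tp])
    m["NAWM"] = data.areas.nawm & m["NAWM"]
    return m


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run every stage on the synthetic cohort; return the result bundle.

    When ``out_dir`` is given, stage tables are written as CSV plus a
    ``manifest.json`` listing outputs, their SHA-256 hashes and all seeds.
    """
    # all randomness flows from the master seed via per-stage derived seeds
    phantom_cfg = PhantomConfig(
        **{**asdict(config.phantom), "seed": config.derived("phantom")}
    )
    truth = generate_phantom(phantom_cfg)

    status = clin.score_table(truth.clinical)

    fraction_rows, median_rows, long_tables = [], [], []
    for subject in truth.subjects:
        data = _subject_volumes(config, truth, subject)
        for tp in ("T0", "T1"):
            fr = vol.compute_fractions(
                data.tissue_masks[tp], data.lesion_mask[tp], phantom_cfg.voxel_size
            )
            fraction_rows.append(
                {
                    "subject": subject.subject_id,
                    "timepoint": tp,
                    "interval_months": subject.interval_months,
                    "tiv_mm3": fr.tiv_mm3,
                    "bpf": fr.bpf,
                    "gmf": fr.gmf,
                    "lf": fr.lf,
                }
            )
            med = nabt.extract_tissue_medians(data.maps[tp], _nabt_masks(data, tp))
            for tissue in NORMAL_TISSUES:
                for p in PARAMETERS:
                    median_rows.append(
                        {
                            "subject": subject.subject_id,
                            "timepoint": tp,
                            "tissue": tissue,
                            "parameter": p,
                            "median": med[tissue][p],
                            "interval_months": subject.interval_months,
                        }
                    )
        long_tables.append(
            les.build_long_table(data.maps, data.areas, data.enlarging, subject.subject_id)
        )

    fractions = pd.DataFrame(fraction_rows)
    changes = vol.volume_change_table(fractions)
    volume_tests = {}
    for name in ("dbpf_pct_per_year", "dgmf_pct_per_year", "dlf_pct_per_year"):
        vals = changes[name].dropna().to_numpy()
        if vals.size >= 2 and np.std(vals, ddof=1) > 0:
            t, df, p = vol.one_sample_ttest(vals)
            volume_tests[name] = {"t": t, "df": df, "p": p, "mean": float(vals.mean())}

    medians = pd.DataFrame(median_rows)
    aroc_table = nabt.build_aroc_table(medians, mode=config.aroc_mode)
    status_in = status.rename(columns={})
    nabt_table = nabt.run_nabt_analysis(
        aroc_table,
        status_in,
        n_permutations=config.n_permutations,
        seed=config.derived("nabt"),
        q=config.fdr_q,
    )

    long_table = pd.concat(long_tables, ignore_index=True)
    lesion_fits, lesion_contrasts = {}, []
    for p in PARAMETERS:
        sub = long_table[long_table.parameter == p]
        try:
            fit = les.fit_area_time_model(sub)
        except (ValueError, RuntimeError) as exc:
            lesion_fits[p] = {"error": str(exc)}
            continue
        lesion_fits[p] = fit
        contrasts = les.pairwise_area_contrasts(fit)
        contrasts.insert(0, "parameter", p)
        lesion_contrasts.append(contrasts)
    contrast_table = (
        pd.concat(lesion_contrasts, ignore_index=True) if lesion_contrasts else pd.DataFrame()
    )

    results = {
        "config": config,
        "clinical": truth.clinical,
        "status": status,
        "fractions": fractions,
        "volume_changes": changes,
        "volume_tests": volume_tests,
        "medians": medians,
        "aroc": aroc_table,
        "nabt": nabt_table,
        "lesion_long_table": long_table,
        "lesion_fits": lesion_fits,
        "lesion_contrasts": contrast_table,
    }

    if out_dir is not None:
        _write_bundle(results, out_dir, config)
    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_bundle(results: dict, out_dir, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "clinical.csv": results["clinical"],
        "status.csv": results["status"],
        "volume_fractions.csv": results["fractions"],
        "volume_changes.csv": results["volume_changes"],
        "nabt_medians.csv": results["medians"],
        "nabt_aroc.csv": results["aroc"],
        "nabt_inference.csv": results["nabt"],
        "lesion_long_table.csv": results["lesion_long_table"],
        "lesion_contrasts.csv": results["lesion_contrasts"],
    }
    fixed_rows = []
    for p, fit in results["lesion_fits"].items():
        if isinstance(fit, dict):
            continue
        t = fit.fixed_tests.copy()
        t.insert(0, "parameter", p)
        fixed_rows.append(t)
    if fixed_rows:
        tables["lesion_fixed_tests.csv"] = pd.concat(fixed_rows, ignore_index=True)

    written = {}
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False)
        written[name] = _sha256(path)

    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: config.derived(s) for s in ("phantom", "nabt")},
        "config": {
            "phantom": asdict(config.phantom),
            "protocol": config.protocol.to_dict(),
            "use_estimated_maps": config.use_estimated_maps,
            "binarization_threshold": config.binarization_threshold,
            "min_lesion_volume_mm3": config.min_lesion_volume_mm3,
            "connectivity": config.connectivity,
            "n_permutations": config.n_permutations,
            "fdr_q": config.fdr_q,
            "aroc_mode": config.aroc_mode,
        },
        "volume_tests": results["volume_tests"],
        "outputs": written,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
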