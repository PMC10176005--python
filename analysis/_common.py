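"""Shared plumbing for the analysis drivers: one cached pipeline run."""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

MASTER_SEED = 0


def ensure_pipeline_outputs(seed: int = MASTER_SEED) -> Path:
    """Run the default pipeline once and cache its tables under results/.

    Every driver reads from this bundle, so the whole analysis shares one
    seeded cohort.  Delete ``results/pipeline`` to force a re-run.
    """
    out = RESULTS / "pipeline"
    if not (out / "manifest.json").exists():
        from qmritrack.pipeline import PipelineConfig, run_pipeline

        print(f"[pipeline] running full pipeline (seed={seed}) -> {out}")
        run_pipeline(PipelineConfig(seed=seed), out_dir=out)
    return out


def banner(text: str) -> None:
    print(f"\n== {text} ==")
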