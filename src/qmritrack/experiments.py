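"""Replicated phantom experiments: error rates and power of the ARoC inference.

These helpers run the normal-appearing-tissue inference stage on many
independently seeded phantom cohorts to measure its operating
characteristics: the fraction of the 12 tissue x parameter tests rejected
after FDR on null cohorts (no programmed status effect), and the rejection
rate of individual tests when a status effect of realistic magnitude is
programmed.

To keep many replicates affordable the cohorts use a reduced grid and no
lesions (the stage under study only reads normal-appearing tissue), and
the maps are the phantom truth volumes — voxel noise, per-visit tissue
jitter and the status effect are all still present.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from . import masks as msk
from . import nabt
from .clinical import score_table
from .mpm import PARAMETERS
from .phantom import NORMAL_TISSUES, PhantomConfig, generate_phantom

#: Reduced problem size for replicated runs.
REPLICATE_CONFIG = dict(
    grid_shape=(24, 28, 24),
    n_subjects=17,
    n_lesions_per_subject=0,
    atrophy_percent_per_year=0.0,
)


def cohort_nabt_table(
    config: PhantomConfig,
    n_permutations: int = nabt.N_PERMUTATIONS_DEFAULT,
    seed: int | None = None,
    q: float = nabt.FDR_Q_DEFAULT,
) -> pd.DataFrame:
    """Run phantom -> masks -> medians -> ARoC -> permutation/FDR once."""
    truth = generate_phantom(config)
    status = score_table(truth.clinical)
    rows = []
    for subject in truth.subjects:
        for tp in ("T0", "T1"):
            tpdata = subject.timepoints[tp]
            post = msk.TissuePosteriors(tpdata.posteriors, config.voxel_size)
            tissue_masks = msk.binarize_tissues(post)
            med = nabt.extract_tissue_medians(tpdata.maps, tissue_masks)
            for tissue in NORMAL_TISSUES:
                for p in PARAMETERS:
                    rows.append(
                        {
                            "subject": subject.subject_id,
                            "timepoint": tp,
                            "tissue": tissue,
                            "parameter": p,
                            "median": med[tissue][p],
                            "interval_months": subject.interval_months,
                        }
                    )
    aroc_table = nabt.build_aroc_table(pd.DataFrame(rows))
    return nabt.run_nabt_analysis(
        aroc_table, status, n_permutations=n_permutations, seed=seed, q=q
    )


def replicate_rejections(
    n_cohorts: int,
    seed: int,
    status_effect: dict[str, float] | None = None,
    n_permutations: int = nabt.N_PERMUTATIONS_DEFAULT,
    q: float = nabt.FDR_Q_DEFAULT,
    **config_overrides,
) -> pd.DataFrame:
    """FDR rejection indicators over replicated phantom cohorts.

    ``status_effect=None`` (or {}) programs null cohorts.  Returns one row
    per cohort x tissue x parameter with the rejection flag.  Cohorts whose
    clinical draw yields a single status group are re-drawn (the regression
    needs both groups), which does not bias the per-test error rate: the
    status labels are independent of the imaging noise.
    """
    rng = np.random.default_rng(seed)
    base = dict(REPLICATE_CONFIG)
    base["status_effect"] = status_effect or {}
    base.update(config_overrides)
    out = []
    done = 0
    while done < n_cohorts:
        cfg = PhantomConfig(seed=int(rng.integers(2**31 - 1)), **base)
        try:
            table = cohort_nabt_table(
                cfg,
                n_permutations=n_permutations,
                seed=int(rng.integers(2**31 - 1)),
                q=q,
            )
        except ValueError:
            continue  # single status group in this clinical draw
        table = table[["tissue", "parameter", "p_perm", "fdr_rejected"]].copy()
        table.insert(0, "cohort", done)
        out.append(table)
        done += 1
    return pd.concat(out, ignore_index=True)
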