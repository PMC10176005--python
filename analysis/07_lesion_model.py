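"""Per-lesion area x time mixed models with Tukey-adjusted area contrasts.

Reads the cached pipeline bundle: the long per-lesion median table, the
REML mixed-model F-tests per qMRI parameter, and all pairwise area
contrasts at each timepoint.
"""

import pandas as pd

from _common import banner, ensure_pipeline_outputs

bundle = ensure_pipeline_outputs()
tests = pd.read_csv(bundle / "lesion_fixed_tests.csv")
contrasts = pd.read_csv(bundle / "lesion_contrasts.csv")
long_table = pd.read_csv(bundle / "lesion_long_table.csv")

banner("fixed-effect F tests per parameter")
for parameter, g in tests.groupby("parameter"):
    cells = [f"{r.effect}: F({r.df1},{r.df2:.0f}) = {r.F:.2f}, p = {r.p:.3g}"
             for _, r in g.iterrows()]
    print(f"{parameter:>6}:  " + " | ".join(cells))

banner("area ordering (mean log median at T0)")
order = long_table[long_table.timepoint == "T0"].groupby(
    ["parameter", "area"]).log_value.mean().unstack()
print(order[["focal_flair", "initial_peripheral", "later_peripheral", "NAWM"]]
      .to_string(float_format=lambda v: f"{v:.3f}"))

banner("Tukey-adjusted pairwise area contrasts")
sig = contrasts[contrasts.p_tukey < 0.05]
print(f"significant contrasts: {len(sig)}/{len(contrasts)}")
n_lesions = long_table[long_table.lesion_id != "NAWM"].groupby(
    "subject").lesion_id.nunique()
print(f"enlarging lesions per subject: {n_lesions.min()}-{n_lesions.max()}")
print("\nthe periplaque gradient (focal < initial < later < NAWM for MTsat/R1/R2*,")
print("reversed for PD) drives a dominant area effect.  Lesion-area values are")
print("time-stationary by construction; the residual time effect in MTsat/R2*")
print("comes from the programmed repair drift of stable subjects' NAWM and is")
print("orders of magnitude below the area effect.")
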