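"""Score disease activity (NEDA-3 chain) for the reference and phantom cohorts.

Applies EDSS-progression, NEDA-3 at mid- and end-interval, and the
both-intervals rule.  The bundled 17-subject MS reference table includes
its expected NEDA and score columns, so the chain is validated row by row.
"""

import pandas as pd

from _common import RESULTS, banner, ensure_pipeline_outputs
from qmritrack.clinical import load_reference_cohort, score_table

out = RESULTS
out.mkdir(parents=True, exist_ok=True)

reference = load_reference_cohort()
derived = score_table(reference)
derived["expected_score"] = reference.score
derived.to_csv(out / "reference_cohort_status.csv", index=False)

banner("reference cohort scoring")
matches = int((derived.status == derived.expected_score).sum())
print(f"reproduced scores: {matches}/17")
for sid in ("sub-008", "sub-011", "sub-014"):
    row = derived[derived.subject_id == sid].iloc[0]
    print(f"  {sid}: NEDA mid={bool(row.neda_mid)}, end={bool(row.neda_end)} "
          f"-> status {int(row.status)}")

bundle = ensure_pipeline_outputs()
status = pd.read_csv(bundle / "status.csv")
banner("phantom cohort status")
print(status.status.value_counts().rename("subjects").to_string())
print(f"wrote {out / 'reference_cohort_status.csv'}")
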