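#!/usr/bin/env python
"""Relate predicted regional stresses to the experimental damage scores.

Expands the shipped group failure counts into per-specimen rows (six
specimens per loading scenario), attaches each specimen's scenario-wise
predicted stresses from the complex-load battery, and fits per-predictor
ordinary least squares of the damage score on each (section, subsection,
direction) stress plus the interface stress. Writes the slope/p-value table
and the significant subset, then classifies the predicted stresses against
the failure-risk thresholds.

Requires analysis/03_complex_loads.py to have produced the stress tables.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from discfem.failure import classify_risk, load_failure_counts, \
    regress_stress_vs_score, specimen_scores

OUT = Path(__file__).resolve().parents[1] / "results"
stress_file = OUT / "complex_loads_regional_stresses.csv"
if not stress_file.exists():
    raise SystemExit("run analysis/03_complex_loads.py first")

tidy = pd.read_csv(stress_file)
iface = pd.read_csv(OUT / "complex_loads_interface.csv")

# wide predictor matrix: one row per scenario
tidy["predictor"] = (tidy["section"] + "/" + tidy["subsection"] + "/"
                     + tidy["direction"])
wide = tidy.pivot_table(index="scenario", columns="predictor",
                        values="value")
ifw = iface.pivot_table(index="scenario", columns="section",
                        values="interface_stress_MPa")
ifw.columns = [f"{c}/interface" for c in ifw.columns]
wide = wide.join(ifw)

spec = specimen_scores(load_failure_counts())
spec["scenario_id"] = "case" + spec["scenario"].astype(str)
X = wide.loc[spec["scenario_id"]].reset_index(drop=True)
res = regress_stress_vs_score(X, spec["score"].to_numpy())

res.table.to_csv(OUT / "regression_full.csv", index=False)
sig = res.significant().sort_values("pvalue")
sig.to_csv(OUT / "regression_significant.csv", index=False)

print(f"{len(sig)} of {len(res.table)} stress predictors are significant "
      "(p < 0.05) for the damage score.")
print("Most predictive stresses:")
print(sig.head(12).to_string(index=False))

axial_sig = sig[sig.predictor.str.contains("axial")]
circ_sig = sig[sig.predictor.str.contains("circumferential")]
print(f"\nAxial predictors flagged: {len(axial_sig)}; "
      f"circumferential: {len(circ_sig)} - the fiber-plane normal stresses "
      "carry the predictive signal, the radial direction much less.")

# risk classification of the case-wise posterior stresses
risk = {}
for scen in wide.index:
    entries = {}
    for s in ("POST", "POST-LAT1", "POST-LAT2"):
        for d in ("axial", "circumferential"):
            entries[f"{s}/{d}"] = float(wide.loc[scen, f"{s}/all/{d}"])
        col = f"{s}/interface"
        if col in wide.columns and np.isfinite(wide.loc[scen, col]):
            entries[col] = float(wide.loc[scen, col])
    risk[scen] = classify_risk(entries)
(OUT / "complex_loads_risk_classified.json").write_text(
    json.dumps(risk, indent=2))
print("\nRisk labels written to complex_loads_risk_classified.json")
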