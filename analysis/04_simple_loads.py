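#!/usr/bin/env python
"""Run the simple loading battery: each load alone and in pairs.

Same pipeline as the complex battery, for axial compression (AC), axial
rotation (AR), lateral bending (LB) and flexion (FL) applied alone or in
couples. The interesting outputs are which pure load stresses the posterior
annulus most, and how the flexion pairs compare with the complex cases.
"""

import logging
from pathlib import Path

import pandas as pd

from discfem import scenarios as sc

logging.basicConfig(level=logging.INFO)
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

ids = ["AC", "AR", "LB", "FL", "AC+FL", "AC+AR", "AC+LB", "FL+AR", "LB+AR",
       "FL+LB"]
tidy, report, results = sc.run_battery(ids)

tidy.to_csv(OUT / "simple_loads_regional_stresses.csv", index=False)
report.to_csv(OUT / "simple_loads_ranking.csv", index=False)

print("\nRanking by mean posterior tensile axial stress:")
print(report.to_string(index=False))
pure = report[report.scenario.isin(["AC", "AR", "LB", "FL"])]
if not pure.empty and pure.iloc[0]["scenario"] == "FL":
    print("\nFlexion is the most demanding pure load on the posterior "
          "annulus, consistent with it being the main driver of failure.")
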