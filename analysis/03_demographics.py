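"""Demographic summary of the synthetic visual-impairment cohorts, side by
side with the shipped full-corpus reference percentages.

Writes results/demographics.csv and prints female/US percentages per drug.
"""

from pathlib import Path

import pandas as pd

from basalvig import reference
from basalvig.pipeline import RunConfig, run
from basalvig.synthetic_data import SyntheticConfig

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    run(RunConfig(out_dir=ROOT, synthetic=SyntheticConfig(seed=0), seed=0,
                  stages=("demographics",)))
    demo = pd.read_csv(ROOT / "demographics.csv")
    endpoint = demo[demo.cohort == "endpoint"]
    ref = reference.load_demographics()
    totals = reference.cohort_sizes()
    print("visual-impairment cohorts: synthetic vs full-corpus reference")
    for drug in totals:
        sub = endpoint[endpoint.drug == drug]
        n = sub[sub.variable == "sex"]["count"].sum()
        f = sub[(sub.variable == "sex") & (sub.level == "Female")]["percent"].iloc[0]
        us = sub[(sub.variable == "country") & (sub.level == "United States")]["percent"].iloc[0]
        rf = 100 * int(ref.loc[(ref.variable == "sex") & (ref.level == "Female"), drug].iloc[0]) / totals[drug]
        print(f"  {drug}: n={n}, female {f:.1f}% (reference {rf:.1f}%), US {us:.1f}%")
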