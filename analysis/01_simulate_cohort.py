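#!/usr/bin/env python
"""Generate the default synthetic cohort and write it under results/cohort.

The cohort mirrors the study design the pipeline targets: 59 children in
four groups (15 control/typically-developing, 12 control/delayed, 15
alcohol-exposed/typically-developing, 17 alcohol-exposed/delayed), a
40-analyte plasma panel on a lognormal scale, three planted cytokine
networks driving group differences, and detection censoring at 27-92% on
six analytes.
"""

import argparse
from pathlib import Path

from cytonet.synthetic import default_planted_model, simulate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

model = default_planted_model(seed=args.seed)
cohort = simulate_cohort(model)
cohort.write(args.out)

censored = int(cohort.censor_mask.to_numpy().sum())
print(f"cohort: {model.n_samples} samples x {model.n_analytes} analytes")
print(f"group sizes: {dict(zip(['C/TD','C/ND','A/TD','A/ND'], model.group_sizes))}")
print(f"planted networks: {model.k}; censored cells: {censored}")
print(f"written to {args.out}")
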