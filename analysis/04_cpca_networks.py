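#!/usr/bin/env python
"""Constrained PCA of the analysis panel on group membership.

Projects the Blom-scale cytokine matrix onto the group design (per-group
mean profiles), decomposes the predictable variance, Varimax-rotates the
retained components, scores each group's involvement by indicator-score
correlations, and assigns network membership from the rotated loadings.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cytonet.cpca import run_cpca
from cytonet.panel import AnalytePanel

parser = argparse.ArgumentParser()
parser.add_argument("--preprocess", type=Path, default=Path("results/preprocess"))
parser.add_argument("--out", type=Path, default=Path("results/cpca"))
parser.add_argument("--threshold", type=float, default=0.40)
parser.add_argument("--k", type=int, default=None)
args = parser.parse_args()

panel = AnalytePanel.from_csv(
    args.preprocess / "analysis_concentrations.csv",
    args.preprocess / "analysis_metadata.csv",
    args.preprocess / "analysis_lod.csv",
    scale="transformed",
)
solution = run_cpca(panel, k=args.k, threshold=args.threshold)

args.out.mkdir(parents=True, exist_ok=True)
(args.out / "cpca_solution.json").write_text(json.dumps(solution.to_dict(), indent=2))
solution.loadings_rotated.rename_axis("analyte").to_csv(args.out / "loadings.csv")
solution.scores.rename_axis("sample_id").to_csv(args.out / "scores.csv")

print(f"retained {solution.k} components (predictable-variance shares: "
      + ", ".join(f"{p:.1f}%" for p in solution.pct_predictable_variance) + ")")
for net in solution.networks:
    members = ", ".join(f"{a} ({s}, {m:.2f})" for a, s, m in net.members)
    print(f"  {net.component}: {members or '(empty)'}")
corr = solution.group_correlations.pivot(index="group", columns="component", values="r")
print("group-component correlations (r):")
print(corr.round(2).to_string())
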