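#!/usr/bin/env python
"""Preprocess the cohort panel: LOD zeroing, exclusion, Winsorize, Blom.

Reads the cohort written by 01_simulate_cohort.py, applies the four-step
preprocessing chain, and writes the analysis-ready (Blom-scale) panel,
the full 40-analyte heatmap panel, and a JSON report of every decision
(zeroed cells, exclusions with undetectable fractions, Winsorized cells).
"""

import argparse
import json
from pathlib import Path

from cytonet.panel import AnalytePanel
from cytonet.preprocess import preprocess_panel

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results/preprocess"))
args = parser.parse_args()

panel = AnalytePanel.from_csv(
    args.cohort / "panel_concentrations.csv",
    args.cohort / "panel_metadata.csv",
    args.cohort / "panel_lod.csv",
)
analysis, heatmap_panel, report = preprocess_panel(panel)

args.out.mkdir(parents=True, exist_ok=True)
analysis.to_csv(args.out, prefix="analysis")
heatmap_panel.to_csv(args.out, prefix="heatmap")
(args.out / "preprocess_report.json").write_text(json.dumps(report.to_dict(), indent=2))

frac = report.undetectable_fraction
print(f"zeroed {report.n_zeroed} below-LOD cells")
print(f"excluded {len(report.excluded_analytes)} analytes (>10% undetectable):")
for a in sorted(report.excluded_analytes):
    print(f"  {a}: {100 * frac[a]:.1f}% undetectable")
print(f"retained {analysis.n_analytes} analytes for analysis; "
      f"heatmap path keeps {heatmap_panel.n_analytes}")
print(f"Winsorized {len(report.winsorized_cells)} cells at |z| > 3.29")
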