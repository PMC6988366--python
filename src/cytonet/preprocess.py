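"""Panel preprocessing: LOD zeroing, exclusion, Winsorization, Blom transform.

The analysis-ready matrix is produced in four ordered steps:

1. concentrations strictly below the analyte's limit of detection are set
   to exactly zero;
2. analytes undetectable in more than 10% of samples are excluded from
   the analysis panel (the full panel is kept for the heatmap path);
3. per-analyte outliers beyond |3.29| SD of the mean are Winsorized to
   the boundary value, in a single pass with mean/SD computed once over
   all samples;
4. each analyte is Blom-transformed, i.e. mapped through the rank-based
   inverse normal transform Phi^-1((r - 3/8) / (n + 1/4)) with average
   ranks for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AnalytePanel, PanelError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "WinsorizedCell",
    "assign_below_lod_zero",
    "filter_undetectable_analytes",
    "winsorize",
    "blom_transform",
    "preprocess_panel",
]

#: two-sided z bound for Winsorization (0.001-level normal quantile).
WINSOR_Z_BOUND = 3.29

#: an analyte is excluded when undetectable in strictly more than this
#: fraction of samples.
UNDETECTABLE_THRESHOLD = 0.10


class WinsorizedCell(NamedTuple):
    sample: str
    analyte: str
    original: float
    replacement: float


@dataclass
class PreprocessReport:
    """Ledger of every preprocessing decision, serializable to JSON."""

    n_zeroed: int = 0
    undetectable_fraction: pd.Series | None = None
    excluded_analytes: list[str] = field(default_factory=list)
    winsorized_cells: list[WinsorizedCell] = field(default_factory=list)
    skipped_zero_sd: list[str] = field(default_factory=list)
    transform: list[str] = field(default_factory=list)

    def record(self, step: str) -> None:
        self.transform.append(step)

    def to_dict(self) -> dict:
        return {
            "n_zeroed": self.n_zeroed,
            "undetectable_fraction": (
                {} if self.undetectable_fraction is None
                else {k: float(v) for k, v in self.undetectable_fraction.items()}
            ),
            "excluded_analytes": list(self.excluded_analytes),
            "winsorized_cells": [c._asdict() for c in self.winsorized_cells],
            "skipped_zero_sd": list(self.skipped_zero_sd),
            "transform": list(self.transform),
        }


def assign_below_lod_zero(
    panel: AnalytePanel, report: PreprocessReport | None = None
) -> AnalytePanel:
    """Set every cell strictly below its analyte's LOD to exactly zero.

    Values equal to the LOD are detectable and left unchanged.
    """
    if (panel.concentrations.to_numpy() < 0).any():
        raise PanelError("negative concentrations are not valid input")
    conc = panel.concentrations.copy()
    below = conc.lt(panel.lod, axis=1)
    conc = conc.where(~below, 0.0)
    if report is not None:
        report.n_zeroed = int(below.to_numpy().sum())
        report.record("assign_below_lod_zero")
    return panel.with_concentrations(conc)


def filter_undetectable_analytes(
    panel: AnalytePanel,
    threshold: float = UNDETECTABLE_THRESHOLD,
    report: PreprocessReport | None = None,
) -> tuple[AnalytePanel, PreprocessReport]:
    """Drop analytes undetectable (== 0 after zeroing) in > ``threshold``
    of samples.  Returns the reduced analysis panel; callers keep their
    own pre-exclusion copy for the heatmap path."""
    if not (0 < threshold < 1):
        raise ParameterRangeError(f"threshold must lie in (0, 1), got {threshold}")
    if report is None:
        report = PreprocessReport()
    frac = panel.concentrations.eq(0.0).mean(axis=0)
    excluded = frac.index[frac > threshold].tolist()
    report.undetectable_fraction = frac
    report.excluded_analytes = excluded
    report.record(f"filter_undetectable_analytes(threshold={threshold})")
    kept = [a for a in panel.analyte_ids if a not in set(excluded)]
    return panel.subset_analytes(kept), report


class ParameterRangeError(ValueError):
    """Raised when a preprocessing parameter is out of range."""


def winsorize(
    panel: AnalytePanel,
    z_bound: float = WINSOR_Z_BOUND,
    report: PreprocessReport | None = None,
) -> tuple[AnalytePanel, PreprocessReport]:
    """Clip cells with |z| > ``z_bound`` to ``mean ± z_bound * SD``.

    Mean and sample SD (n-1 denominator) are computed once per analyte
    over all samples, outliers included; replacement is single-pass (no
    re-estimation after clipping).  Cells at exactly the bound are left
    unchanged (strict inequality).  Analytes with zero SD are skipped
    with a logged warning.
    """
    if panel.n_samples < 3:
        raise PanelError("Winsorization needs at least 3 samples per analyte")
    if report is None:
        report = PreprocessReport()
    conc = panel.concentrations.copy()
    means = conc.mean(axis=0)
    sds = conc.std(axis=0, ddof=1)
    for analyte in conc.columns:
        sd = sds[analyte]
        if sd == 0 or not np.isfinite(sd):
            logger.warning("winsorize: analyte %s has zero SD, skipped", analyte)
            report.skipped_zero_sd.append(analyte)
            continue
        mu = means[analyte]
        z = (conc[analyte] - mu) / sd
        flagged = z.index[np.abs(z) > z_bound]
        for sample in flagged:
            original = conc.at[sample, analyte]
            replacement = mu + np.sign(z[sample]) * z_bound * sd
            conc.at[sample, analyte] = replacement
            report.winsorized_cells.append(
                WinsorizedCell(str(sample), str(analyte), float(original), float(replacement))
            )
    report.record(f"winsorize(z_bound={z_bound})")
    return panel.with_concentrations(conc), report


def blom_scores(values: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse normal transform of a 1-D array.

    Uses average ranks for ties, so tied inputs map to equal outputs.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise PanelError("Blom transform needs at least 2 observations")
    r = stats.rankdata(values, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (n + 1.0 / 4.0))


def blom_transform(
    panel: AnalytePanel, report: PreprocessReport | None = None
) -> AnalytePanel:
    """Apply the Blom transform to every analyte column."""
    conc = panel.concentrations.copy()
    for analyte in conc.columns:
        conc[analyte] = blom_scores(conc[analyte].to_numpy())
    if report is not None:
        report.record("blom_transform")
    return panel.with_concentrations(conc, scale="transformed")


def preprocess_panel(
    panel: AnalytePanel,
    threshold: float = UNDETECTABLE_THRESHOLD,
    z_bound: float = WINSOR_Z_BOUND,
) -> tuple[AnalytePanel, AnalytePanel, PreprocessReport]:
    """Full pipeline: zero -> exclude -> Winsorize -> Blom.

    Returns ``(analysis_panel, heatmap_panel, report)`` where
    ``heatmap_panel`` is the post-zeroing panel retaining all analytes
    (exclusion applies to the analysis only).
    """
    report = PreprocessReport()
    zeroed = assign_below_lod_zero(panel, report)
    heatmap_panel = zeroed.copy()
    reduced, report = filter_undetectable_analytes(zeroed, threshold, report)
    clipped, report = winsorize(reduced, z_bound, report)
    transformed = blom_transform(clipped, report)
    return transformed, heatmap_panel, report
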