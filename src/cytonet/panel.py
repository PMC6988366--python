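"""Sample x analyte concentration panel container and CSV round-tripping.

The panel bundles three aligned tables: plasma concentrations (pg/mL),
per-analyte lower limits of detection (LOD), and per-sample metadata
(study group plus the covariates used for adjustment: maternal smoking,
pre-pregnancy BMI, child sex, child age at blood draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Fixed group order: controls vs alcohol-exposed mothers, crossed with
#: typically-developing vs neurodevelopmentally-delayed children.
GROUP_ORDER: tuple[str, ...] = ("C/TD", "C/ND", "A/TD", "A/ND")

#: 40-analyte V-PLEX-style human biomarker panel (pro-inflammatory,
#: cytokine, chemokine, angiogenesis and vascular-injury sub-panels).
DEFAULT_ANALYTES: tuple[str, ...] = (
    # pro-inflammatory
    "IFN-g", "IL-1b", "IL-2", "IL-4", "IL-6", "IL-8", "IL-10",
    "IL-12p70", "IL-13", "TNF-a",
    # cytokine
    "GM-CSF", "IL-1a", "IL-5", "IL-7", "IL-12p40", "IL-15", "IL-16",
    "IL-17A", "TNF-b", "VEGF-A",
    # chemokine
    "eotaxin", "MIP-1b", "eotaxin-3", "TARC", "IP-10", "MIP-1a",
    "MCP-1", "MDC", "MCP-4",
    # angiogenesis
    "VEGF", "VEGF-C", "VEGF-D", "Tie-2", "Flt-1", "PlGF", "bFGF",
    # vascular injury
    "SAA", "CRP", "VCAM-1", "ICAM-1",
)

COVARIATE_COLUMNS: tuple[str, ...] = ("smoking", "bmi", "sex", "age_years")
META_COLUMNS: tuple[str, ...] = ("group",) + COVARIATE_COLUMNS


class PanelError(ValueError):
    """Raised when a panel violates its structural contract."""


@dataclass
class AnalytePanel:
    """Aligned concentration matrix, LODs and sample metadata.

    Parameters
    ----------
    concentrations
        samples x analytes DataFrame of non-negative concentrations in
        pg/mL; index holds unique sample IDs, columns unique analyte IDs.
    lod
        Per-analyte lower limit of detection (> 0), indexed by analyte.
    meta
        Per-sample DataFrame with columns ``group`` (one of
        :data:`GROUP_ORDER`), ``smoking`` (0/1), ``bmi`` (kg/m^2),
        ``sex`` (0/1), ``age_years``.
    """

    concentrations: pd.DataFrame
    lod: pd.Series
    meta: pd.DataFrame
    #: "concentration" (pg/mL, non-negative) or "transformed" (e.g. Blom
    #: scores, where negative values are expected).
    scale: str = "concentration"

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        conc = self.concentrations
        if conc.index.has_duplicates or conc.columns.has_duplicates:
            raise PanelError("sample and analyte IDs must be unique")
        if conc.isna().any().any():
            raise PanelError(
                "panel has missing cells; undetectable values must be "
                "encoded as values below the LOD, not as NaN"
            )
        if self.scale == "concentration" and (conc.to_numpy() < 0).any():
            raise PanelError("negative concentrations are not valid")
        if not self.lod.index.equals(conc.columns):
            missing = conc.columns.difference(self.lod.index).tolist()
            if missing:
                raise PanelError(f"LOD missing for analytes: {missing}")
            self.lod = self.lod.reindex(conc.columns)
        if (self.lod.to_numpy() <= 0).any():
            raise PanelError("every LOD must be > 0")
        if not self.meta.index.equals(conc.index):
            raise PanelError("metadata index must match sample IDs")
        unknown = set(self.meta["group"]) - set(GROUP_ORDER)
        if unknown:
            raise PanelError(f"unknown group labels: {sorted(unknown)}")

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.concentrations.index

    @property
    def analyte_ids(self) -> pd.Index:
        return self.concentrations.columns

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.concentrations.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.meta["group"]

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts().reindex(GROUP_ORDER, fill_value=0)

    def with_concentrations(
        self, conc: pd.DataFrame, scale: str | None = None
    ) -> "AnalytePanel":
        """Return a copy with a replaced concentration matrix.

        Analytes may be dropped (columns subset); samples must match.
        """
        return AnalytePanel(
            concentrations=conc,
            lod=self.lod.reindex(conc.columns),
            meta=self.meta,
            scale=self.scale if scale is None else scale,
        )

    def subset_analytes(self, analytes: Sequence[str]) -> "AnalytePanel":
        return self.with_concentrations(self.concentrations[list(analytes)])

    def copy(self) -> "AnalytePanel":
        return AnalytePanel(
            concentrations=self.concentrations.copy(),
            lod=self.lod.copy(),
            meta=self.meta.copy(),
            scale=self.scale,
        )

    # -- I/O --------------------------------------------------------------
    def to_csv(self, out_dir: str | Path, prefix: str = "panel") -> dict[str, Path]:
        """Write concentrations / metadata / LOD as three CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "concentrations": out / f"{prefix}_concentrations.csv",
            "metadata": out / f"{prefix}_metadata.csv",
            "lod": out / f"{prefix}_lod.csv",
        }
        self.concentrations.rename_axis("sample_id").to_csv(paths["concentrations"])
        self.meta.rename_axis("sample_id").to_csv(paths["metadata"])
        self.lod.rename_axis("analyte").rename("lod").to_csv(paths["lod"])
        return paths

    @classmethod
    def from_csv(
        cls,
        concentrations: str | Path,
        metadata: str | Path,
        lod: str | Path,
        scale: str = "concentration",
    ) -> "AnalytePanel":
        conc = pd.read_csv(concentrations, index_col=0).rename_axis(None)
        meta = pd.read_csv(metadata, index_col=0).rename_axis(None)
        lod_s = pd.read_csv(lod, index_col=0)["lod"].rename_axis(None).rename(None)
        return cls(concentrations=conc, lod=lod_s, meta=meta, scale=scale)


def make_group_labels(group_sizes: Iterable[int]) -> list[str]:
    """Expand per-group counts (in :data:`GROUP_ORDER`) into labels."""
    sizes = list(group_sizes)
    if len(sizes) != len(GROUP_ORDER):
        raise PanelError(
            f"expected {len(GROUP_ORDER)} group sizes, got {len(sizes)}"
        )
    labels: list[str] = []
    for g, n in zip(GROUP_ORDER, sizes):
        labels.extend([g] * int(n))
    return labels
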