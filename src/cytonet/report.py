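"""Group-profile heatmaps and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
import yaml

from . import __version__
from .cpca import run_cpca
from .panel import GROUP_ORDER, AnalytePanel
from .preprocess import preprocess_panel
from .synthetic import PlantedModel, default_planted_model, simulate_cohort
from .univariate import regress_all_analytes

logger = logging.getLogger(__name__)

__all__ = ["GroupProfile", "group_profile", "render_heatmap", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class GroupProfile:
    """Groups x analytes matrix of group-mean z scores.

    z-scoring is over all samples per analyte, so the group-size-weighted
    mean of the four group means is zero for every analyte.
    """

    matrix: pd.DataFrame
    group_sizes: pd.Series

    @property
    def group_order(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def analyte_order(self) -> list[str]:
        return list(self.matrix.columns)


def group_profile(panel: AnalytePanel) -> GroupProfile:
    """z-score each analyte over all samples, then average within group.

    Uses the pre-exclusion panel: the heatmap shows all analytes, including
    those dropped from the statistical analysis.  Zero-SD analytes yield a
    column of zeros with a logged warning.
    """
    conc = panel.concentrations
    mu = conc.mean(axis=0)
    sd = conc.std(axis=0, ddof=1)
    zero_sd = sd.index[sd == 0].tolist()
    if zero_sd:
        logger.warning("group_profile: zero-SD analytes set to 0: %s", zero_sd)
        sd = sd.replace(0, 1.0)
    z = (conc - mu) / sd
    order = [g for g in GROUP_ORDER if (panel.groups == g).any()]
    matrix = z.groupby(panel.groups).mean().reindex(order)
    return GroupProfile(matrix=matrix, group_sizes=panel.group_sizes().reindex(order))


def render_heatmap(profile: GroupProfile, out: str | Path) -> Path:
    """Write a diverging-colormap heatmap (centered at 0) to PNG/SVG."""
    out = Path(out)
    vmax = max(float(np.abs(profile.matrix.to_numpy()).max()), 1e-12)
    fig, ax = plt.subplots(
        figsize=(max(8.0, 0.28 * profile.matrix.shape[1]), 3.2)
    )
    sns.heatmap(
        profile.matrix,
        cmap="RdBu_r",
        center=0.0,
        vmin=-vmax,
        vmax=vmax,
        ax=ax,
        cbar_kws={"label": "group mean (z score)"},
    )
    ax.set_xlabel("analyte")
    ax.set_ylabel("group")
    fig.tight_layout()
    try:
        fig.savefig(out, dpi=150)
    except OSError as exc:
        plt.close(fig)
        raise OSError(f"cannot write heatmap to {out}: {exc}") from exc
    plt.close(fig)
    return out


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> Path:
    """simulate (optional) -> preprocess -> univariate -> cpca -> report.

    The config either names panel/metadata/LOD CSVs or requests a
    simulated cohort; options cover the membership threshold, a K
    override, and the seed.  All artifacts plus a machine-readable run
    log land in the output directory.  Outputs are deterministic under a
    fixed config and seed.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    threshold = float(cfg.get("membership_threshold", 0.40))
    k_override = cfg.get("k")

    # --- input stage -------------------------------------------------------
    truth_summary = None
    if "panel" in cfg:
        try:
            panel = AnalytePanel.from_csv(
                cfg["panel"], cfg["metadata"], cfg["lod"]
            )
        except Exception as exc:
            raise PipelineError("preprocess", exc) from exc
    else:
        sim_cfg = cfg.get("simulate", {}) or {}
        model = default_planted_model(seed=seed, **sim_cfg)
        cohort = simulate_cohort(model)
        cohort.write(out / "cohort")
        panel = cohort.panel
        truth_summary = {
            "group_sizes": list(model.group_sizes),
            "n_networks": model.k,
        }

    # --- preprocess --------------------------------------------------------
    try:
        analysis_panel, heatmap_panel, report = preprocess_panel(panel)
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc
    (out / "preprocess_report.json").write_text(
        json.dumps(report.to_dict(), indent=2)
    )

    # --- univariate --------------------------------------------------------
    try:
        regression_table = regress_all_analytes(analysis_panel)
    except Exception as exc:
        raise PipelineError("univariate", exc) from exc
    regression_table.to_csv(out / "univariate_regression.csv")

    # --- cpca ---------------------------------------------------------------
    try:
        solution = run_cpca(analysis_panel, k=k_override, threshold=threshold)
    except Exception as exc:
        raise PipelineError("cpca", exc) from exc
    (out / "cpca_solution.json").write_text(json.dumps(solution.to_dict(), indent=2))
    solution.loadings_rotated.rename_axis("analyte").to_csv(out / "cpca_loadings.csv")
    solution.scores.rename_axis("sample_id").to_csv(out / "cpca_scores.csv")
    network_rows = [
        {
            "component": n.component,
            "analyte": a,
            "sign": s,
            "loading_magnitude": m,
        }
        for n in solution.networks
        for a, s, m in n.members
    ]
    pd.DataFrame(
        network_rows, columns=["component", "analyte", "sign", "loading_magnitude"]
    ).to_csv(out / "networks.csv", index=False)

    # --- report -------------------------------------------------------------
    try:
        profile = group_profile(heatmap_panel)
        render_heatmap(profile, out / "heatmap.png")
        profile.matrix.rename_axis("group").to_csv(out / "group_profile.csv")
    except Exception as exc:
        raise PipelineError("report", exc) from exc

    summary = {
        "n_samples": panel.n_samples,
        "n_analytes_total": panel.n_analytes,
        "n_analytes_excluded": len(report.excluded_analytes),
        "excluded_analytes": sorted(report.excluded_analytes),
        "n_analytes_retained": analysis_panel.n_analytes,
        "n_components_retained": solution.k,
        "pct_predictable_variance": solution.pct_predictable_variance.tolist(),
        "membership_threshold": threshold,
        "truth": truth_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    run_log = {
        "cytonet_version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "stages": ["simulate" if "panel" not in cfg else "load"]
        + ["preprocess", "univariate", "cpca", "report"],
        "decisions": {
            "winsorize_z_bound": 3.29,
            "undetectable_threshold": 0.10,
            "pipeline_order": report.transform,
            "membership_threshold": threshold,
            "k_override": k_override,
        },
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    logger.info("pipeline complete: %s", out)
    return out
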