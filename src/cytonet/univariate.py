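"""Per-analyte covariate-adjusted hierarchical regression and group tests.

For each analyte a two-step ordinary least squares model is fit on the
Blom-transformed values: step 1 adjusts for maternal smoking,
pre-pregnancy BMI, child sex, and child age at blood draw; step 2 adds
three group indicators (reference-coded against C/TD).  The group block
is judged by the F test on the R-squared increment, and all six pairwise
group contrasts are read off the step-2 model.  Post-hoc p values for
group characteristic tables go through the Holm-Bonferroni step-down
adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import COVARIATE_COLUMNS, GROUP_ORDER, AnalytePanel

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "PairwiseContrast",
    "hierarchical_regression",
    "regress_all_analytes",
    "holm_bonferroni",
    "group_characteristics",
    "GroupTestResult",
]

REFERENCE_GROUP = GROUP_ORDER[0]  # C/TD


class DesignError(ValueError):
    """Raised when the regression design matrix is rank-deficient."""


class DataError(ValueError):
    """Raised for invalid statistical input."""


@dataclass
class PairwiseContrast:
    group_a: str
    group_b: str
    estimate: float
    p_value: float


@dataclass
class RegressionResult:
    analyte: str
    n_used: int
    r_squared_covariates: float
    r_squared_full: float
    delta_r_squared_group: float
    f_group_block: float
    p_group_block: float
    pairwise_contrasts: list[PairwiseContrast] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.pairwise_contrasts])


def _design_matrices(
    panel: AnalytePanel, analyte: str
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame, list[str]]:
    """y, covariate-only X, full X with group indicators, dropped samples."""
    meta = panel.meta
    y = panel.concentrations[analyte]
    covs = meta[list(COVARIATE_COLUMNS)].astype(float)
    complete = covs.notna().all(axis=1) & y.notna()
    dropped = y.index[~complete].tolist()
    if dropped:
        logger.warning(
            "hierarchical_regression: dropped %d samples with missing covariates",
            len(dropped),
        )
    y = y[complete]
    covs = covs[complete]
    x1 = sm.add_constant(covs, has_constant="add")
    dummies = pd.get_dummies(meta.loc[complete, "group"]).reindex(
        columns=list(GROUP_ORDER), fill_value=0
    )
    indicators = dummies.drop(columns=[REFERENCE_GROUP]).astype(float)
    indicators.columns = [f"group[{g}]" for g in indicators.columns]
    x2 = pd.concat([x1, indicators], axis=1)
    return y, x1, x2, dropped


def _check_rank(x: pd.DataFrame) -> None:
    arr = x.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the offending column: first column whose removal restores rank
        for col in x.columns:
            rest = x.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(arr):
                raise DesignError(f"design matrix is collinear in column {col!r}")
        raise DesignError("design matrix is rank-deficient")


def hierarchical_regression(panel: AnalytePanel, analyte: str) -> RegressionResult:
    """Two-step OLS for one analyte; group block tested by its R² increment."""
    if analyte not in panel.analyte_ids:
        raise DataError(f"analyte {analyte!r} not in panel")
    y, x1, x2, dropped = _design_matrices(panel, analyte)
    _check_rank(x2)
    fit1 = sm.OLS(y, x1).fit()
    fit2 = sm.OLS(y, x2).fit()
    f_stat, p_block, _ = fit2.compare_f_test(fit1)

    # six pairwise contrasts among the four groups from the step-2 model
    coef = {REFERENCE_GROUP: 0.0}
    names = list(x2.columns)
    for g in GROUP_ORDER[1:]:
        coef[g] = f"group[{g}]"
    contrasts: list[PairwiseContrast] = []
    for ga, gb in itertools.combinations(GROUP_ORDER, 2):
        vec = np.zeros(len(names))
        for g, sign in ((ga, 1.0), (gb, -1.0)):
            if g != REFERENCE_GROUP:
                vec[names.index(f"group[{g}]")] += sign
        tt = fit2.t_test(vec)
        contrasts.append(
            PairwiseContrast(ga, gb, float(np.squeeze(tt.effect)), float(tt.pvalue))
        )

    r2_cov = float(fit1.rsquared)
    r2_full = float(fit2.rsquared)
    return RegressionResult(
        analyte=analyte,
        n_used=int(len(y)),
        r_squared_covariates=r2_cov,
        r_squared_full=r2_full,
        delta_r_squared_group=max(r2_full - r2_cov, 0.0),
        f_group_block=float(f_stat),
        p_group_block=float(p_block),
        pairwise_contrasts=contrasts,
        dropped_samples=[str(s) for s in dropped],
    )


def regress_all_analytes(panel: AnalytePanel) -> pd.DataFrame:
    """Hierarchical regression for every analyte; tidy results table.

    Per the analysis convention, the per-analyte group-block p values are
    reported unadjusted across analytes (an optional Holm column is
    provided alongside for sensitivity).
    """
    rows = []
    for analyte in panel.analyte_ids:
        res = hierarchical_regression(panel, analyte)
        row = {
            "analyte": res.analyte,
            "n": res.n_used,
            "r_squared_covariates": res.r_squared_covariates,
            "r_squared_full": res.r_squared_full,
            "delta_r_squared_group": res.delta_r_squared_group,
            "f_group_block": res.f_group_block,
            "p_group_block": res.p_group_block,
        }
        for c in res.pairwise_contrasts:
            key = f"{c.group_a} vs {c.group_b}"
            row[f"estimate[{key}]"] = c.estimate
            row[f"p[{key}]"] = c.p_value
        rows.append(row)
    table = pd.DataFrame(rows).set_index("analyte")
    adj, _ = holm_bonferroni(table["p_group_block"].to_numpy())
    table["p_group_block_holm"] = adj
    return table


def holm_bonferroni(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjustment.

    Sorted ascending, adjusted p_i = max_{j<=i} min(1, (m-j+1) * p_(j));
    rejections follow the sequential rule at ``alpha``.  Returns
    (adjusted p, reject flags) in the original order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p <= 0) | (p > 1)).any():
        raise DataError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.maximum.accumulate(
        np.minimum((m - np.arange(m)) * p[order], 1.0)
    )
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    reject = adjusted <= alpha
    return adjusted, reject


@dataclass
class GroupTestResult:
    variable: str
    test: str  # "kruskal-wallis" | "fisher-exact" | "chi-square"
    statistic: float | None
    p_value: float
    posthoc: pd.DataFrame | None = None


def _fisher_exact_rxc(
    table: np.ndarray, n_mc: int = 20000, seed: int = 0
) -> float:
    """Monte-Carlo Fisher exact p for an r x c table under fixed margins.

    Samples tables by Patefield's algorithm and estimates
    P(prob(table) <= prob(observed)); the (1 + count)/(1 + n) estimator
    keeps the p value valid.  2x2 tables should use the exact routine.
    """
    table = np.asarray(table, dtype=int)
    row = table.sum(axis=1)
    col = table.sum(axis=0)

    def log_prob(t: np.ndarray) -> float:
        from scipy.special import gammaln

        return float(
            gammaln(row + 1).sum()
            + gammaln(col + 1).sum()
            - gammaln(table.sum() + 1)
            - gammaln(t + 1).sum()
        )

    obs = log_prob(table)
    rng = np.random.default_rng(seed)
    samples = stats.random_table(row, col).rvs(n_mc, random_state=rng)
    lp = np.array([log_prob(t) for t in samples])
    count = int((lp <= obs + 1e-9).sum())
    return (1 + count) / (1 + n_mc)


def _categorical_test(
    table: pd.DataFrame, method: str | None, seed: int
) -> tuple[str, float | None, float]:
    arr = table.to_numpy(dtype=int)
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError("categorical variable is constant; test is degenerate")
    chi2, p_chi, _, expected = stats.chi2_contingency(arr, correction=False)
    if method is None:
        method = "fisher-exact" if (expected < 5).any() else "chi-square"
    if method == "chi-square":
        return "chi-square", float(chi2), float(p_chi)
    if arr.shape == (2, 2):
        _, p = stats.fisher_exact(arr)
        return "fisher-exact", None, float(p)
    return "fisher-exact", None, _fisher_exact_rxc(arr, seed=seed)


def group_characteristics(
    meta: pd.DataFrame,
    variable: str,
    kind: str,
    method: str | None = None,
    posthoc: bool = True,
    seed: int = 0,
) -> GroupTestResult:
    """Omnibus group test for one sample characteristic with Holm post hocs.

    Continuous variables use the Kruskal-Wallis rank sum test; categorical
    variables use Fisher's exact test when any expected cell count is
    below 5 and the chi-square test otherwise (overridable via
    ``method``).  Pairwise post-hoc p values are Holm-adjusted.
    """
    if variable not in meta.columns:
        raise DataError(f"variable {variable!r} not in metadata")
    data = meta[["group", variable]].dropna()
    present = [g for g in GROUP_ORDER if (data["group"] == g).any()]
    if len(present) < 2:
        raise DataError("variable present for fewer than 2 groups")
    if data[variable].nunique() < 2:
        raise DataError(f"variable {variable!r} is constant; test is degenerate")

    if kind == "continuous":
        samples = [data.loc[data["group"] == g, variable].to_numpy() for g in present]
        stat, p = stats.kruskal(*samples)
        result = GroupTestResult(variable, "kruskal-wallis", float(stat), float(p))
    elif kind == "categorical":
        table = pd.crosstab(data["group"], data[variable]).reindex(present)
        test, stat, p = _categorical_test(table, method, seed)
        result = GroupTestResult(variable, test, stat, p)
    else:
        raise DataError(f"kind must be 'continuous' or 'categorical', got {kind!r}")

    if posthoc:
        rows = []
        for ga, gb in itertools.combinations(present, 2):
            sub = data[data["group"].isin([ga, gb])]
            if kind == "continuous":
                a = sub.loc[sub["group"] == ga, variable].to_numpy()
                b = sub.loc[sub["group"] == gb, variable].to_numpy()
                try:
                    _, p_pair = stats.kruskal(a, b)
                except ValueError:  # identical constant values in the pair
                    p_pair = 1.0
            else:
                tab = pd.crosstab(sub["group"], sub[variable])
                try:
                    _, _, p_pair = _categorical_test(tab, method, seed)
                except DataError:
                    p_pair = 1.0
            rows.append({"group_a": ga, "group_b": gb, "p_raw": float(p_pair)})
        ph = pd.DataFrame(rows)
        adj, rej = holm_bonferroni(ph["p_raw"].to_numpy())
        ph["p_holm"] = adj
        ph["reject_0.05"] = rej
        result.posthoc = ph
    return result
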