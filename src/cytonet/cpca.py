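"""Constrained principal component analysis of a cytokine panel on group.

CPCA proceeds in two stages.  The analyte matrix Y (samples x analytes,
Blom-transformed) is first regressed on the group indicator matrix G; the
fitted values ``G (G'G)^- G' Y`` are the *predicted scores* — the part of
each cytokine's variance predictable from group membership.  With pure
indicator coding the prediction for a sample is simply its group's mean
profile, so the predicted matrix has rank at most (number of groups - 1)
after column centering.  A PCA of the centered predicted matrix then
yields components ("networks") of analytes that move together across
groups; loadings are Varimax-rotated with Kaiser normalization, and each
group's involvement in a network is scored by the Pearson correlation
between the group's indicator column and the component scores.

Network membership is read off the rotated loadings: analytes whose
absolute loading clears a threshold belong to the component, a positive
loading meaning "activated" and a negative one "inhibited".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .panel import GROUP_ORDER, AnalytePanel

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDesign",
    "CPCASolution",
    "NetworkDefinition",
    "build_design",
    "predict_scores",
    "pca_predicted",
    "extract_components",
    "varimax_rotate",
    "group_component_correlations",
    "assign_networks",
    "fit_cpca",
    "tucker_congruence",
    "match_loadings",
]

DEFAULT_MEMBERSHIP_THRESHOLD = 0.40


class DataLabelError(ValueError):
    """Raised for unknown group labels or empty groups."""


class ExtractionError(ValueError):
    """Raised when no component can be extracted."""


@dataclass
class GroupDesign:
    """Samples x groups 0/1 indicator matrix in fixed group order."""

    matrix: pd.DataFrame
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = self.matrix.to_numpy()
        if not np.array_equal(arr.sum(axis=1), np.ones(arr.shape[0])):
            raise DataLabelError("each sample must belong to exactly one group")

    @property
    def sizes(self) -> pd.Series:
        return self.matrix.sum(axis=0)


def build_design(panel_or_labels) -> GroupDesign:
    """Indicator matrix from an :class:`AnalytePanel` or a label sequence."""
    if isinstance(panel_or_labels, AnalytePanel):
        labels = panel_or_labels.groups
    else:
        labels = pd.Series(panel_or_labels)
    unknown = set(labels) - set(GROUP_ORDER)
    if unknown:
        raise DataLabelError(f"unknown group labels: {sorted(unknown)}")
    dummies = pd.get_dummies(labels).reindex(columns=list(GROUP_ORDER), fill_value=0)
    present = [g for g in GROUP_ORDER if dummies[g].sum() > 0]
    return GroupDesign(matrix=dummies[present].astype(float), group_order=tuple(present))


def predict_scores(Y: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Least-squares projection of Y onto the group design.

    ``predicted = G (G'G)^- G' Y`` via a pseudoinverse (the four-indicator
    coding is deliberately intercept-free; the projection is unique even
    though coefficients are not).  With indicator coding the result equals
    each sample's group mean profile — asserted, not assumed.
    """
    G = design.matrix.to_numpy(dtype=float)
    if (G.sum(axis=0) == 0).any():
        raise DataLabelError("design contains an empty group column")
    Yv = np.asarray(Y, dtype=float)
    if G.shape[0] != Yv.shape[0]:
        raise DataLabelError("Y and design are not row-conformable")
    beta, *_ = np.linalg.lstsq(G, Yv, rcond=None)
    predicted = G @ beta

    group_means = (G / G.sum(axis=0)).T @ Yv  # groups x analytes
    expected = G @ group_means
    if not np.allclose(predicted, expected, atol=1e-8):
        raise AssertionError(
            "projection does not reduce to per-group means under indicator coding"
        )
    return pd.DataFrame(predicted, index=Y.index, columns=Y.columns)


def pca_predicted(
    predicted: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """PCA of the column-centered predicted matrix.

    Returns ``(eigenvalues, loadings, scores)`` with components in
    descending eigenvalue order.  Loadings carry correlation-like scaling
    (eigenvector times sqrt(eigenvalue)); scores are standardized to unit
    sample variance per component.  Eigenvalues use the n-1 denominator so
    their sum equals the total (sample) variance of the centered matrix.
    """
    X = np.asarray(predicted, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0.0):
        logger.warning("pca_predicted: centered matrix is zero; no components")
        k = min(X.shape)
        return (
            np.zeros(k),
            pd.DataFrame(0.0, index=predicted.columns, columns=_comp_names(k)),
            pd.DataFrame(0.0, index=predicted.index, columns=_comp_names(k)),
        )
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    k = len(s)
    loadings = Vt.T * (s / np.sqrt(n - 1))  # eigvec * sqrt(eigval)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(s > 0, U * np.sqrt(n - 1), 0.0)
    names = _comp_names(k)
    return (
        eigenvalues,
        pd.DataFrame(loadings, index=predicted.columns, columns=names),
        pd.DataFrame(scores, index=predicted.index, columns=names),
    )


def _comp_names(k: int) -> list[str]:
    return [f"C{i + 1}" for i in range(k)]


def extract_components(
    eigenvalues: np.ndarray,
    method: str = "tolerance",
    k: int | None = None,
    rel_tol: float = 1e-10,
) -> int:
    """Number of components to retain from the scree of eigenvalues.

    ``tolerance`` keeps eigenvalues above ``rel_tol`` times the largest
    (the rank of the group-mean configuration); ``elbow`` takes the point
    of maximum second difference of the scree curve; ``k`` overrides both.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0 or ev[0] <= 0:
        raise ExtractionError("no positive eigenvalue to extract")
    if np.any(np.diff(ev) > 1e-12):
        raise ExtractionError("eigenvalues must be in descending order")
    if k is not None:
        logger.info("extract_components: manual override K=%d", k)
        return int(k)
    if method == "tolerance":
        chosen = int((ev > rel_tol * ev[0]).sum())
    elif method == "elbow":
        if ev.size < 3:
            chosen = 1
        else:
            second_diff = ev[:-2] - 2 * ev[1:-1] + ev[2:]
            chosen = int(np.argmax(second_diff)) + 1
    else:
        raise ExtractionError(f"unknown extraction method {method!r}")
    logger.info("extract_components: method=%s K=%d", method, chosen)
    return chosen


def _varimax_criterion(L: np.ndarray) -> float:
    """Sum over components of the variance of squared loadings."""
    sq = L**2
    return float((sq**2).sum(axis=0).sum() - (sq.sum(axis=0) ** 2).sum() / L.shape[0])


def varimax_rotate(
    loadings: pd.DataFrame | np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Varimax rotation with Kaiser normalization (pairwise Jacobi sweeps).

    Rows are divided by the square root of their communality, planar
    rotations are applied pairwise until the Varimax criterion improves by
    less than ``tol`` over a full sweep (or ``max_sweeps`` is reached),
    and rows are de-normalized.  Returns ``(rotated loadings, rotation)``
    with ``rotated = loadings @ rotation`` exactly.  K = 1 is the identity.
    """
    is_frame = isinstance(loadings, pd.DataFrame)
    L0 = np.asarray(loadings, dtype=float)
    p, k = L0.shape
    R = np.eye(k)
    if k == 1:
        return (loadings.copy() if is_frame else L0.copy()), R

    comm = np.sqrt((L0**2).sum(axis=1))
    zero_rows = comm == 0
    if zero_rows.any():
        logger.warning(
            "varimax_rotate: %d zero-communality rows excluded from "
            "normalization", int(zero_rows.sum())
        )
    if kaiser:
        scale = np.where(zero_rows, 1.0, comm)
        L = L0 / scale[:, None]
    else:
        L = L0.copy()

    crit = _varimax_criterion(L)
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2 * x * y
                a, b = u.sum(), v.sum()
                c = (u**2 - v**2).sum()
                d = (2 * u * v).sum()
                num = d - 2 * a * b / p
                den = c - (a**2 - b**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                cs, sn = np.cos(phi), np.sin(phi)
                rot = np.array([[cs, -sn], [sn, cs]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        new_crit = _varimax_criterion(L)
        if new_crit - crit < tol:
            break
        crit = new_crit

    rotated = L0 @ R  # de-normalization is implicit: D D^-1 = I
    if is_frame:
        rotated = pd.DataFrame(rotated, index=loadings.index, columns=loadings.columns)
    return rotated, R


def group_component_correlations(
    design: GroupDesign, scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (and two-sided p on n-2 df) between each group indicator
    and each component's scores, over all samples."""
    rows = []
    for g in design.group_order:
        indicator = design.matrix[g].to_numpy()
        for comp in scores.columns:
            sc = scores[comp].to_numpy()
            if np.ptp(sc) == 0:
                raise DataLabelError(
                    f"component {comp} has constant scores; correlation undefined"
                )
            r, p = stats.pearsonr(indicator, sc)
            rows.append({"group": g, "component": comp, "r": r, "p": p})
    return pd.DataFrame(rows)


@dataclass
class NetworkDefinition:
    """One component's member analytes with activation sign and loading."""

    component: str
    members: list[tuple[str, str, float]]  # (analyte, sign label, |loading|)
    label: str = ""

    def analytes(self) -> set[str]:
        return {m[0] for m in self.members}

    def signs(self) -> dict[str, str]:
        return {m[0]: m[1] for m in self.members}


def assign_networks(
    loadings_rotated: pd.DataFrame, threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD
) -> list[NetworkDefinition]:
    """Threshold the rotated loadings into per-component networks.

    An analyte joins a network when its absolute rotated loading is at
    least ``threshold``; positive loadings are 'activated', negative
    'inhibited'.  Members are sorted by loading magnitude, descending.
    Empty networks are permitted and reported.
    """
    if threshold <= 0:
        raise ValueError("membership threshold must be > 0")
    networks = []
    for comp in loadings_rotated.columns:
        col = loadings_rotated[comp]
        members = [
            (str(a), "activated" if v > 0 else "inhibited", float(abs(v)))
            for a, v in col.items()
            if abs(v) >= threshold
        ]
        members.sort(key=lambda m: -m[2])
        networks.append(NetworkDefinition(component=str(comp), members=members))
    return networks


@dataclass
class CPCASolution:
    """Everything the constrained PCA produces, ready to serialize."""

    design: GroupDesign
    predicted: pd.DataFrame
    eigenvalues: np.ndarray
    loadings_unrotated: pd.DataFrame
    loadings_rotated: pd.DataFrame
    rotation: np.ndarray
    scores: pd.DataFrame
    pct_predictable_variance: np.ndarray
    group_correlations: pd.DataFrame
    networks: list[NetworkDefinition]
    k: int
    membership_threshold: float

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "membership_threshold": self.membership_threshold,
            "eigenvalues": self.eigenvalues.tolist(),
            "pct_predictable_variance": self.pct_predictable_variance.tolist(),
            "rotation": self.rotation.tolist(),
            "loadings_rotated": self.loadings_rotated.round(10).to_dict(),
            "group_correlations": self.group_correlations.round(10).to_dict("records"),
            "networks": [
                {
                    "component": n.component,
                    "members": [
                        {"analyte": a, "sign": s, "loading_magnitude": m}
                        for a, s, m in n.members
                    ],
                }
                for n in self.networks
            ],
        }


def fit_cpca(
    Y: pd.DataFrame,
    groups,
    k: int | None = None,
    extraction: str = "tolerance",
    threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD,
) -> CPCASolution:
    """Full CPCA: design -> projection -> PCA -> Varimax -> correlations."""
    design = build_design(groups)
    predicted = predict_scores(Y, design)
    eigenvalues, loadings, scores = pca_predicted(predicted)

    n_groups = len(design.group_order)
    n_effective = int((eigenvalues > 1e-10 * max(eigenvalues.max(), 1e-300)).sum())
    if n_effective > n_groups - 1:
        raise AssertionError("rank bound violated: more components than groups - 1")

    k_keep = extract_components(eigenvalues, method=extraction, k=k)
    k_keep = min(k_keep, loadings.shape[1])
    L = loadings.iloc[:, :k_keep]
    S = scores.iloc[:, :k_keep]
    L_rot, R = varimax_rotate(L)
    S_rot = pd.DataFrame(S.to_numpy() @ R, index=S.index, columns=S.columns)
    correlations = group_component_correlations(design, S_rot)

    total = eigenvalues.sum()
    pct = 100.0 * eigenvalues[:k_keep] / total if total > 0 else np.zeros(k_keep)
    return CPCASolution(
        design=design,
        predicted=predicted,
        eigenvalues=eigenvalues,
        loadings_unrotated=L,
        loadings_rotated=L_rot,
        rotation=R,
        scores=S_rot,
        pct_predictable_variance=pct,
        group_correlations=correlations,
        networks=assign_networks(L_rot, threshold),
        k=k_keep,
        membership_threshold=threshold,
    )


def run_cpca(panel: AnalytePanel, **kwargs) -> CPCASolution:
    """CPCA on a preprocessed panel (columns = retained analytes)."""
    return fit_cpca(panel.concentrations, panel.groups, **kwargs)


# --- recovery scoring ------------------------------------------------------

def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine) between two loading vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return 0.0
    return float(x @ y / denom)


def match_loadings(
    estimated: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match estimated loading columns to planted ones by |congruence|.

    Returns ``(congruences, permutation, signs)`` where
    ``estimated[:, permutation[k]] * signs[k]`` best matches
    ``truth[:, k]`` under a one-to-one (Hungarian) assignment, and
    ``congruences[k]`` is the signed congruence after sign alignment
    (so each entry is non-negative).
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    kt, ke = tru.shape[1], est.shape[1]
    C = np.zeros((kt, ke))
    for i in range(kt):
        for j in range(ke):
            C[i, j] = tucker_congruence(tru[:, i], est[:, j])
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(kt, dtype=int)
    signs = np.empty(kt)
    congruences = np.empty(kt)
    for i, j in zip(rows, cols):
        perm[i] = j
        signs[i] = 1.0 if C[i, j] >= 0 else -1.0
        congruences[i] = abs(C[i, j])
    return congruences, perm, signs
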