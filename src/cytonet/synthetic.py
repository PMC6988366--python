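"""Synthetic cohort generator with planted group-driven cytokine networks.

The generative model mirrors the statistical structure the downstream
analysis assumes.  Each subject in group ``g`` draws a K-vector of latent
network scores around that group's activation profile; analyte values are
a linear mixture of those scores plus analyte noise; concentrations are
obtained by a per-analyte lognormal back-transform (multiplex cytokine
panels are strongly right-skewed).  Detection censoring and gross outliers
are then imposed, and the full ground truth (loadings, activations,
censored-cell mask, outlier ledger) is carried alongside the panel so
that every pipeline stage can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import (
    DEFAULT_ANALYTES,
    GROUP_ORDER,
    AnalytePanel,
    make_group_labels,
)

__all__ = [
    "PlantedModel",
    "SyntheticCohort",
    "default_planted_model",
    "generate_cohort",
    "apply_detection_censoring",
    "inject_outliers",
    "simulate_cohort",
    "DEFAULT_NETWORKS",
    "DEFAULT_GROUP_ACTIVATIONS",
    "DEFAULT_CENSOR_RATES",
]


class ParameterError(ValueError):
    """Raised for out-of-range simulation parameters."""


class DimensionError(ValueError):
    """Raised for non-conformable model matrices."""


#: Planted networks: analyte -> signed weight, one dict per component.
#: Network 1 is activated specifically in control children with delay;
#: network 2 splits the two alcohol-exposed groups (PlGF and CRP move
#: opposite to the chemokines); network 3 tracks alcohol exposure itself.
DEFAULT_NETWORKS: tuple[dict[str, float], ...] = (
    {"IL-2": 1.0, "TNF-b": 1.0, "IL-10": 1.0, "IL-15": 1.0},
    {"MIP-1b": 1.0, "MDC": 1.0, "MCP-4": 1.0, "PlGF": -1.0, "CRP": -1.0},
    {"eotaxin-3": 1.0, "eotaxin": 1.0, "bFGF": 1.0},
)

#: Group mean activation of each network, rows in GROUP_ORDER.  The
#: columns are (group-size-weighted) uncorrelated across groups so the
#: planted networks are identifiable by an orthogonal rotation; the sign
#: pattern encodes the qualitative story: network 1 activated in C/ND and
#: inhibited under alcohol exposure, network 2 splitting A/TD (+) from
#: A/ND (−), network 3 activated in both alcohol groups and inhibited in
#: C/TD.
DEFAULT_GROUP_ACTIVATIONS: np.ndarray = np.array(
    [
        #   N1     N2     N3
        [-0.27, 0.02, -1.91],  # C/TD
        [1.90, 0.02, 0.31],    # C/ND
        [-0.61, 1.58, 0.80],   # A/TD
        [-0.57, -1.43, 0.76],  # A/ND
    ]
)

#: Undetectable fractions for the six heavily censored analytes.
DEFAULT_CENSOR_RATES: dict[str, float] = {
    "GM-CSF": 0.27,
    "IL-1a": 0.49,
    "IL-4": 0.58,
    "IL-13": 0.73,
    "IL-1b": 0.73,
    "IL-12p70": 0.92,
}


@dataclass
class PlantedModel:
    """Ground-truth parameters for cohort simulation.

    Attributes
    ----------
    analytes : list of analyte names (defines panel width and order).
    group_sizes : samples per group, in :data:`~cytonet.panel.GROUP_ORDER`.
    loadings : analytes x K signed network weights.
    group_activations : groups x K mean latent score per group.
    subject_score_sd : SD of a subject's latent score around its group mean.
    analyte_noise_sd : per-analyte (or scalar) SD of measurement noise on
        the latent scale.
    log_scale_mu, log_scale_sigma : per-analyte (or scalar) lognormal
        location/scale mapping latent values to pg/mL.
    lod : per-analyte limit of detection; defaults to
        ``exp(mu - 4 * sigma)`` so uncensored analytes are essentially
        fully detected.
    censor_rates : per-analyte fraction of samples forced below the LOD.
    outlier_rate : fraction of cells displaced to gross outliers.
    outlier_magnitude_sd : displacement in latent-scale SDs (> 3.29).
    covariate_group_effect : optional confounding knob; per-group shift
        of the smoking probability (0 keeps covariates independent of
        group).
    seed : integer seed; generation is bit-reproducible given the seed.
    """

    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    group_sizes: tuple[int, ...] = (15, 12, 15, 17)
    loadings: np.ndarray | None = None
    group_activations: np.ndarray = field(
        default_factory=lambda: DEFAULT_GROUP_ACTIVATIONS.copy()
    )
    subject_score_sd: float = 1.0
    analyte_noise_sd: float | np.ndarray = 0.5
    log_scale_mu: float | np.ndarray = 2.0
    log_scale_sigma: float | np.ndarray = 0.5
    lod: np.ndarray | None = None
    censor_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENSOR_RATES)
    )
    outlier_rate: float = 0.0
    outlier_magnitude_sd: float = 5.0
    covariate_group_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.analytes = tuple(self.analytes)
        if self.loadings is None:
            self.loadings = build_loadings(self.analytes, DEFAULT_NETWORKS)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.group_activations = np.asarray(self.group_activations, dtype=float)
        if self.loadings.shape[0] != self.n_analytes:
            raise DimensionError(
                f"loadings has {self.loadings.shape[0]} rows for "
                f"{self.n_analytes} analytes"
            )
        if self.group_activations.shape != (len(self.group_sizes), self.k):
            raise DimensionError(
                "group_activations must be groups x K = "
                f"{(len(self.group_sizes), self.k)}, got "
                f"{self.group_activations.shape}"
            )
        if any(n < 2 for n in self.group_sizes):
            raise ParameterError("every group needs at least 2 subjects")
        if (np.abs(self.loadings).sum(axis=0) == 0).any():
            raise ParameterError("planted loading columns must not be all-zero")
        rates = np.array(
            [self.censor_rates.get(a, 0.0) for a in self.analytes], dtype=float
        )
        if ((rates < 0) | (rates >= 1)).any():
            raise ParameterError("censor_rates must lie in [0, 1)")
        if not (0 <= self.outlier_rate < 1):
            raise ParameterError("outlier_rate must lie in [0, 1)")
        self._rates = rates
        self._mu = np.broadcast_to(
            np.asarray(self.log_scale_mu, dtype=float), (self.n_analytes,)
        ).copy()
        self._sigma = np.broadcast_to(
            np.asarray(self.log_scale_sigma, dtype=float), (self.n_analytes,)
        ).copy()
        self._noise_sd = np.broadcast_to(
            np.asarray(self.analyte_noise_sd, dtype=float), (self.n_analytes,)
        ).copy()
        if self.lod is None:
            self.lod = np.exp(self._mu - 4.0 * self._sigma)
        self.lod = np.asarray(self.lod, dtype=float)

    @property
    def n_analytes(self) -> int:
        return len(self.analytes)

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def censor_rate_vector(self) -> np.ndarray:
        return self._rates


def build_loadings(
    analytes: Sequence[str], networks: Sequence[dict[str, float]]
) -> np.ndarray:
    """Expand sparse network definitions into an analytes x K matrix."""
    loadings = np.zeros((len(analytes), len(networks)))
    index = {a: i for i, a in enumerate(analytes)}
    for k, network in enumerate(networks):
        for analyte, weight in network.items():
            if analyte not in index:
                raise DimensionError(f"network analyte {analyte!r} not in panel")
            loadings[index[analyte], k] = weight
    return loadings


def default_planted_model(seed: int = 0, **overrides) -> PlantedModel:
    """The study-design default: 59 subjects (15/12/15/17) x 40 analytes,
    three planted networks, printed censoring rates on six analytes."""
    return PlantedModel(seed=seed, **overrides)


@dataclass
class SyntheticCohort:
    """A generated panel plus the truth needed to score recovery."""

    panel: AnalytePanel
    truth: PlantedModel
    subject_scores: pd.DataFrame  # samples x K latent network scores
    latent: pd.DataFrame          # samples x analytes pre-transform values
    censor_mask: pd.DataFrame     # True where a cell was forced below LOD
    outlier_ledger: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = (self.truth.n_samples, self.truth.n_analytes)
        if self.panel.concentrations.shape != expected:
            raise DimensionError(
                f"panel shape {self.panel.concentrations.shape} != {expected}"
            )

    def write(self, out_dir: str | Path) -> None:
        """Write panel CSVs and a JSON truth file."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.panel.to_csv(out)
        truth = {
            "seed": self.truth.seed,
            "analytes": list(self.truth.analytes),
            "group_sizes": list(self.truth.group_sizes),
            "loadings": self.truth.loadings.tolist(),
            "group_activations": self.truth.group_activations.tolist(),
            "subject_score_sd": self.truth.subject_score_sd,
            "censor_rates": {
                a: r
                for a, r in zip(self.truth.analytes, self.truth.censor_rate_vector)
                if r > 0
            },
            "censored_cells": [
                {
                    "sample": str(self.censor_mask.index[i]),
                    "analyte": str(self.censor_mask.columns[j]),
                }
                for i, j in zip(*np.nonzero(self.censor_mask.to_numpy()))
            ],
            "outliers": self.outlier_ledger,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _draw_covariates(model: PlantedModel, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates: independent of group unless the confounding knob is on."""
    labels = make_group_labels(model.group_sizes)
    n = len(labels)
    group_idx = np.array([GROUP_ORDER.index(g) for g in labels])
    # baseline smoking probability ~ cohort-wide smoking prevalence
    p_smoke = 0.25 + model.covariate_group_effect * (
        group_idx - np.mean(np.arange(len(GROUP_ORDER)))
    ) / len(GROUP_ORDER)
    p_smoke = np.clip(p_smoke, 0.01, 0.99)
    return pd.DataFrame(
        {
            "group": labels,
            "smoking": (rng.random(n) < p_smoke).astype(int),
            "bmi": np.round(rng.normal(23.8, 3.5, n), 1),
            "sex": rng.integers(0, 2, n),
            "age_years": np.round(rng.uniform(2.0, 3.5, n), 2),
        },
        index=[f"S{i + 1:03d}" for i in range(n)],
    )


def generate_cohort(model: PlantedModel) -> SyntheticCohort:
    """Draw a cohort from the planted latent-network model (no censoring).

    Subject ``i`` in group ``g`` has latent scores
    ``~ Normal(group_activations[g], subject_score_sd)``; the latent
    analyte value is ``scores @ loadings.T + noise`` and the measured
    concentration is ``exp(mu + sigma * latent)``.
    """
    rng = np.random.default_rng(model.seed)
    meta = _draw_covariates(model, rng)
    group_idx = np.array([GROUP_ORDER.index(g) for g in meta["group"]])

    scores = model.group_activations[group_idx] + model.subject_score_sd * rng.standard_normal(
        (model.n_samples, model.k)
    )
    noise = model._noise_sd * rng.standard_normal(
        (model.n_samples, model.n_analytes)
    )
    latent = scores @ model.loadings.T + noise
    conc = np.exp(model._mu + model._sigma * latent)

    sample_ids = meta.index
    analytes = list(model.analytes)
    panel = AnalytePanel(
        concentrations=pd.DataFrame(conc, index=sample_ids, columns=analytes),
        lod=pd.Series(model.lod, index=analytes),
        meta=meta,
    )
    return SyntheticCohort(
        panel=panel,
        truth=model,
        subject_scores=pd.DataFrame(
            scores, index=sample_ids, columns=[f"N{k + 1}" for k in range(model.k)]
        ),
        latent=pd.DataFrame(latent, index=sample_ids, columns=analytes),
        censor_mask=pd.DataFrame(False, index=sample_ids, columns=analytes),
    )


def apply_detection_censoring(cohort: SyntheticCohort) -> SyntheticCohort:
    """Force a deterministic count of cells per analyte below the LOD.

    For analyte ``j`` exactly ``round(censor_rates[j] * n_samples)`` cells
    (chosen uniformly under the model seed) are replaced by ``LOD / 2``.
    The count is deterministic rather than Bernoulli so that downstream
    exclusion tests are exact.
    """
    model = cohort.truth
    rates = model.censor_rate_vector
    if ((rates < 0) | (rates >= 1)).any():
        raise ParameterError("censor_rates must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 1]))
    conc = cohort.panel.concentrations.copy()
    mask = cohort.censor_mask.copy()
    n = model.n_samples
    for j, analyte in enumerate(model.analytes):
        n_cens = int(np.rint(rates[j] * n))
        if n_cens == 0:
            continue
        rows = rng.choice(n, size=n_cens, replace=False)
        conc.iloc[rows, j] = model.lod[j] / 2.0
        mask.iloc[rows, j] = True
    panel = AnalytePanel(concentrations=conc, lod=cohort.panel.lod, meta=cohort.panel.meta)
    return SyntheticCohort(
        panel=panel,
        truth=model,
        subject_scores=cohort.subject_scores,
        latent=cohort.latent,
        censor_mask=mask,
        outlier_ledger=list(cohort.outlier_ledger),
    )


def inject_outliers(
    cohort: SyntheticCohort,
    outlier_rate: float | None = None,
    magnitude_sd: float | None = None,
) -> SyntheticCohort:
    """Displace a recorded set of uncensored cells to gross outliers.

    Displacement happens on the latent scale: the chosen cell is moved to
    ``mean_j + sign * magnitude_sd * sd_j`` of its analyte's latent
    distribution and the concentration recomputed, so the Winsorization
    step downstream has a known set of cells to flag.
    """
    model = cohort.truth
    rate = model.outlier_rate if outlier_rate is None else outlier_rate
    mag = model.outlier_magnitude_sd if magnitude_sd is None else magnitude_sd
    if rate >= 1 or rate < 0:
        raise ParameterError("outlier_rate must lie in [0, 1)")
    if mag <= 3.29:
        raise ParameterError(
            "outlier magnitude must exceed the 3.29-SD Winsorization bound"
        )
    n_cells = model.n_samples * model.n_analytes
    n_out = int(np.rint(rate * n_cells))
    if n_out == 0:
        return cohort

    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 2]))
    latent = cohort.latent.copy()
    conc = cohort.panel.concentrations.copy()
    mask = cohort.censor_mask.to_numpy()
    eligible = np.flatnonzero(~mask.ravel())
    chosen = rng.choice(eligible, size=n_out, replace=False)
    means = latent.to_numpy().mean(axis=0)
    sds = latent.to_numpy().std(axis=0, ddof=1)
    ledger: list[dict] = list(cohort.outlier_ledger)
    for flat in chosen:
        i, j = divmod(int(flat), model.n_analytes)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        new_latent = means[j] + sign * mag * sds[j]
        old_conc = conc.iat[i, j]
        latent.iat[i, j] = new_latent
        conc.iat[i, j] = np.exp(model._mu[j] + model._sigma[j] * new_latent)
        ledger.append(
            {
                "sample": str(conc.index[i]),
                "analyte": str(conc.columns[j]),
                "old_concentration": float(old_conc),
                "new_concentration": float(conc.iat[i, j]),
                "latent_sd_displacement": sign * mag,
            }
        )
    panel = AnalytePanel(concentrations=conc, lod=cohort.panel.lod, meta=cohort.panel.meta)
    return SyntheticCohort(
        panel=panel,
        truth=model,
        subject_scores=cohort.subject_scores,
        latent=latent,
        censor_mask=cohort.censor_mask,
        outlier_ledger=ledger,
    )


def simulate_cohort(model: PlantedModel | None = None, seed: int | None = None) -> SyntheticCohort:
    """generate -> censor -> inject outliers, under the model defaults."""
    if model is None:
        model = default_planted_model(seed=0 if seed is None else seed)
    elif seed is not None:
        model = dataclasses.replace(model, seed=seed)
    cohort = generate_cohort(model)
    cohort = apply_detection_censoring(cohort)
    if model.outlier_rate > 0:
        cohort = inject_outliers(cohort)
    return cohort
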