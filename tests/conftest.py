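import numpy as np
import pandas as pd
import pytest

from cytonet.panel import AnalytePanel, make_group_labels
from cytonet.synthetic import default_planted_model, generate_cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 59 x 40 cohort (censoring applied), shared read-only."""
    return simulate_cohort(seed=0)


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    from cytonet.preprocess import preprocess_panel

    analysis, heatmap, report = preprocess_panel(default_cohort.panel)
    return analysis, heatmap, report


def build_panel(values, lod=None, groups=None, seed=0, scale="transformed"):
    """Small hand-made panel: values is samples x analytes array-like."""
    arr = np.asarray(values, dtype=float)
    n, p = arr.shape
    analytes = [f"A{j + 1}" for j in range(p)]
    samples = [f"S{i + 1}" for i in range(n)]
    if groups is None:
        sizes = [n - 3 * (n // 4)] + [n // 4] * 3
        groups = make_group_labels(sizes)
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame(
        {
            "group": groups,
            "smoking": rng.integers(0, 2, n),
            "bmi": rng.normal(24, 3, n),
            "sex": rng.integers(0, 2, n),
            "age_years": rng.uniform(2, 3.5, n),
        },
        index=samples,
    )
    lod_s = pd.Series(
        np.full(p, 1e-6) if lod is None else np.asarray(lod, dtype=float),
        index=analytes,
    )
    return AnalytePanel(
        concentrations=pd.DataFrame(arr, index=samples, columns=analytes),
        lod=lod_s,
        meta=meta,
        scale=scale,
    )


@pytest.fixture
def panel_factory():
    return build_panel
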