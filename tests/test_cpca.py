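"""CPCA: design coding, projection, PCA, Varimax, correlations, networks."""

import numpy as np
import pandas as pd
import pytest

from cytonet.cpca import (
    DataLabelError,
    ExtractionError,
    assign_networks,
    build_design,
    extract_components,
    fit_cpca,
    group_component_correlations,
    match_loadings,
    pca_predicted,
    predict_scores,
    tucker_congruence,
    varimax_rotate,
)
from cytonet.panel import GROUP_ORDER, make_group_labels


def _frame(arr, prefix="A"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"S{i + 1}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j + 1}" for j in range(arr.shape[1])],
    )


class TestBuildDesign:
    def test_study_sizes(self):
        design = build_design(make_group_labels([15, 12, 15, 17]))
        assert design.matrix.shape == (59, 4)
        assert design.sizes.tolist() == [15, 12, 15, 17]
        assert (design.matrix.sum(axis=1) == 1).all()

    def test_single_group(self):
        design = build_design(["C/TD"] * 5)
        assert design.matrix.shape == (5, 1)
        assert (design.matrix.to_numpy() == 1).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(DataLabelError, match="unknown"):
            build_design(["C/TD", "B/XX"])


class TestPredictScores:
    def test_equals_group_means_brute_force(self):
        rng = np.random.default_rng(0)
        labels = make_group_labels([2, 2, 1, 1])
        Y = _frame(rng.standard_normal((6, 4)))
        pred = predict_scores(Y, build_design(labels))
        for g in set(labels):
            idx = [i for i, l in enumerate(labels) if l == g]
            mean = Y.iloc[idx].mean(axis=0)
            for i in idx:
                assert pred.iloc[i].to_numpy() == pytest.approx(
                    mean.to_numpy(), abs=1e-12
                )

    def test_identical_group_means_center_to_zero(self):
        labels = make_group_labels([3, 3, 3, 3])
        base = np.tile(np.arange(4.0), (12, 1))
        pred = predict_scores(_frame(base), build_design(labels))
        centered = pred - pred.mean(axis=0)
        assert np.allclose(centered, 0.0)

    def test_residual_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        labels = make_group_labels([15, 12, 15, 17])
        Y = _frame(rng.standard_normal((59, 6)))
        design = build_design(labels)
        resid = Y.to_numpy() - predict_scores(Y, design).to_numpy()
        inner = design.matrix.to_numpy().T @ resid
        assert np.abs(inner).max() < 1e-8


class TestPcaPredicted:
    def test_four_groups_give_three_nonzero_eigenvalues(self):
        rng = np.random.default_rng(2)
        labels = make_group_labels([15, 12, 15, 17])
        Y = _frame(rng.standard_normal((59, 10)))
        pred = predict_scores(Y, build_design(labels))
        ev, _, _ = pca_predicted(pred)
        assert int((ev > 1e-10 * ev[0]).sum()) == 3

    def test_two_groups_give_one(self):
        rng = np.random.default_rng(3)
        labels = ["C/TD"] * 6 + ["A/ND"] * 6
        Y = _frame(rng.standard_normal((12, 5)))
        pred = predict_scores(Y, build_design(labels))
        ev, _, _ = pca_predicted(pred)
        assert int((ev > 1e-10 * ev[0]).sum()) == 1

    def test_eigenvalue_sum_conserves_variance(self):
        rng = np.random.default_rng(4)
        labels = make_group_labels([15, 12, 15, 17])
        Y = _frame(rng.standard_normal((59, 8)))
        pred = predict_scores(Y, build_design(labels))
        ev, _, _ = pca_predicted(pred)
        total = pred.to_numpy().var(axis=0, ddof=1).sum()
        assert ev.sum() == pytest.approx(total, abs=1e-10)

    def test_eigenvalues_match_direct_svd(self):
        rng = np.random.default_rng(5)
        labels = make_group_labels([2, 2, 1, 1])
        Y = _frame(rng.standard_normal((6, 4)))
        pred = predict_scores(Y, build_design(labels))
        ev, loadings, scores = pca_predicted(pred)
        X = pred.to_numpy() - pred.to_numpy().mean(axis=0)
        s = np.linalg.svd(X, compute_uv=False)
        assert ev == pytest.approx(s**2 / (len(Y) - 1), abs=1e-10)
        # scores have unit variance on non-degenerate components
        for j, lam in enumerate(ev):
            if lam > 1e-12:
                assert scores.iloc[:, j].var(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_plain_pca_limit(self):
        """With each sample its own 'group' the projection is the identity
        and CPCA reduces to ordinary PCA of Y."""
        rng = np.random.default_rng(6)
        Y = _frame(rng.standard_normal((7, 4)))
        identity = pd.DataFrame(
            np.eye(7), index=Y.index, columns=[f"g{i}" for i in range(7)]
        )
        from cytonet.cpca import GroupDesign

        design = GroupDesign(matrix=identity, group_order=tuple(identity.columns))
        pred = predict_scores(Y, design)
        ev, _, _ = pca_predicted(pred)
        Xc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        direct = np.linalg.svd(Xc, compute_uv=False) ** 2 / 6
        assert ev[: len(direct)] == pytest.approx(direct, abs=1e-10)


class TestExtractComponents:
    @pytest.mark.parametrize(
        "ev, kwargs, expected",
        [
            ([5, 3, 1, 1e-16], {}, 3),
            ([10, 0.1, 0.09], {"method": "elbow"}, 1),
            ([5, 3, 1], {"k": 2}, 2),
        ],
    )
    def test_rules(self, ev, kwargs, expected):
        assert extract_components(np.array(ev, dtype=float), **kwargs) == expected

    def test_no_positive_eigenvalue(self):
        with pytest.raises(ExtractionError):
            extract_components(np.array([0.0, 0.0]))


class TestVarimax:
    def test_axis_aligned_is_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.9, 0.8, 0.7]
        L[3:, 1] = [0.6, 0.8, 0.5]
        rotated, R = varimax_rotate(L)
        # identity up to column sign/permutation
        P = np.abs(R)
        assert np.allclose(P @ P.T, np.eye(2), atol=1e-6)
        assert np.allclose(np.abs(rotated), np.abs(L), atol=1e-6)

    def test_recovers_45_degree_rotation(self):
        truth = np.zeros((8, 2))
        truth[:4, 0] = [0.9, 0.85, 0.8, 0.75]
        truth[4:, 1] = [0.7, 0.8, 0.9, 0.6]
        theta = np.pi / 4
        mix = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rotated, R = varimax_rotate(truth @ mix)
        cong, perm, signs = match_loadings(rotated, truth)
        aligned = rotated[:, perm] * signs
        assert np.abs(aligned - truth).max() < 1e-6

    def test_rotation_is_orthogonal_and_consistent(self):
        rng = np.random.default_rng(8)
        L = pd.DataFrame(rng.standard_normal((10, 3)))
        rotated, R = varimax_rotate(L)
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-10
        assert np.allclose(rotated.to_numpy(), L.to_numpy() @ R, atol=1e-12)
        # total explained variance is rotation-invariant
        assert np.sum(rotated.to_numpy() ** 2) == pytest.approx(
            np.sum(L.to_numpy() ** 2), abs=1e-10
        )

    def test_criterion_non_decreasing(self):
        from cytonet.cpca import _varimax_criterion

        rng = np.random.default_rng(9)
        L = rng.standard_normal((12, 3))
        rotated, _ = varimax_rotate(L, kaiser=False)
        assert _varimax_criterion(np.asarray(rotated)) >= _varimax_criterion(L) - 1e-12

    def test_single_component_identity(self):
        L = np.array([[0.5], [0.7], [-0.2]])
        rotated, R = varimax_rotate(L)
        assert np.array_equal(R, np.eye(1))
        assert np.allclose(rotated, L)

    def test_zero_communality_row_stays_zero(self):
        L = np.zeros((5, 2))
        L[0, 0] = 1.0
        L[1, 1] = 1.0
        rotated, R = varimax_rotate(L)
        assert np.allclose(rotated[2:], 0.0)


class TestGroupComponentCorrelations:
    def test_centered_indicator_scores_give_unit_r(self):
        labels = make_group_labels([15, 12, 15, 17])
        design = build_design(labels)
        ind = design.matrix["C/ND"].to_numpy()
        scores = pd.DataFrame(
            {"C1": ind - ind.mean()}, index=design.matrix.index
        )
        table = group_component_correlations(design, scores)
        r = table.set_index("group")["r"]
        assert abs(r["C/ND"]) == pytest.approx(1.0, abs=1e-12)
        assert table.set_index("group")["p"]["C/ND"] < 1e-20

    def test_null_scores_calibrated(self):
        rng = np.random.default_rng(10)
        labels = make_group_labels([15, 12, 15, 17])
        design = build_design(labels)
        n_rep = 2000
        hits = 0
        for _ in range(n_rep):
            scores = pd.DataFrame(
                {"C1": rng.standard_normal(59)}, index=design.matrix.index
            )
            table = group_component_correlations(design, scores)
            hits += (table["p"] <= 0.05).sum()
        rate = hits / (n_rep * 4)
        assert 0.03 <= rate <= 0.07

    def test_constant_scores_rejected(self):
        labels = make_group_labels([3, 3, 3, 3])
        design = build_design(labels)
        scores = pd.DataFrame({"C1": np.ones(12)}, index=design.matrix.index)
        with pytest.raises(DataLabelError, match="constant"):
            group_component_correlations(design, scores)


class TestAssignNetworks:
    def test_members_thresholded_and_sorted(self):
        L = pd.DataFrame(
            {"C1": [0.8, -0.5, 0.1], "C2": [0.0, 0.2, -0.9]},
            index=["IL-2", "CRP", "IL-6"],
        )
        nets = assign_networks(L, threshold=0.4)
        assert nets[0].members == [
            ("IL-2", "activated", 0.8),
            ("CRP", "inhibited", 0.5),
        ]
        assert nets[1].members == [("IL-6", "inhibited", 0.9)]

    def test_all_below_threshold_empty(self):
        L = pd.DataFrame({"C1": [0.1, -0.2]}, index=["a", "b"])
        nets = assign_networks(L, threshold=0.4)
        assert nets[0].members == []

    def test_sign_flip_invariance(self):
        L = pd.DataFrame({"C1": [0.8, -0.5]}, index=["a", "b"])
        nets = assign_networks(L)
        flipped = assign_networks(-L)
        assert nets[0].analytes() == flipped[0].analytes()
        assert all(
            nets[0].signs()[a] != flipped[0].signs()[a] for a in nets[0].analytes()
        )


class TestFitCpca:
    def test_rank_bound_never_exceeded(self, preprocessed):
        analysis, _, _ = preprocessed
        from cytonet.cpca import run_cpca

        sol = run_cpca(analysis)
        assert sol.k <= 3
        assert (
            int((sol.eigenvalues > 1e-10 * sol.eigenvalues[0]).sum())
            <= len(sol.design.group_order) - 1
        )

    def test_rotated_loadings_consistent(self, preprocessed):
        analysis, _, _ = preprocessed
        from cytonet.cpca import run_cpca

        sol = run_cpca(analysis)
        assert np.allclose(
            sol.loadings_rotated.to_numpy(),
            sol.loadings_unrotated.to_numpy() @ sol.rotation,
            atol=1e-10,
        )
        assert np.abs(sol.rotation.T @ sol.rotation - np.eye(sol.k)).max() < 1e-10
        # rotated scores remain unit variance
        assert sol.scores.var(ddof=1).to_numpy() == pytest.approx(
            np.ones(sol.k), abs=1e-8
        )

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(11)
        Y = _frame(rng.standard_normal((6, 3)))
        with pytest.raises(Exception):
            fit_cpca(Y, ["C/TD"] * 3 + ["BAD"] * 3)


class TestTuckerCongruence:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert tucker_congruence(v, v) == pytest.approx(1.0)
        assert tucker_congruence(v, -v) == pytest.approx(-1.0)

    def test_matching_handles_permutation_and_sign(self):
        rng = np.random.default_rng(12)
        truth = rng.standard_normal((10, 3))
        est = truth[:, [2, 0, 1]] * np.array([-1, 1, -1])
        cong, perm, signs = match_loadings(est, truth)
        assert cong == pytest.approx(np.ones(3), abs=1e-12)
        assert np.allclose(est[:, perm] * signs, truth)
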