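"""Wilks' Lambda, forward selection, allocation and canonical variates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from napus_phenomics.discriminant import (
    SingularScatterError, allocate, canonical_projection, forward_select,
    wilks_lambda,
)


def _lambda_oracle(X: np.ndarray, g: np.ndarray) -> float:
    """Independent Wilks' Lambda via explicit scatter sums."""
    grand = X.mean(axis=0)
    T = sum(np.outer(x - grand, x - grand) for x in X)
    W = np.zeros_like(T)
    for level in np.unique(g):
        mu = X[g == level].mean(axis=0)
        W += sum(np.outer(x - mu, x - mu) for x in X[g == level])
    return float(np.linalg.det(W) / np.linalg.det(T))


class TestWilksLambda:
    def test_four_point_hand_example(self):
        # groups {1,2} and {3,4}: T = 5, W = 1, Lambda = 0.2
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        g = pd.Series(["a", "a", "b", "b"])
        assert wilks_lambda(df, g, ["x"]) == pytest.approx(0.2)

    def test_identical_group_means_give_unity(self):
        df = pd.DataFrame({"x": [1.0, 3.0, 1.0, 3.0, 0.0, 4.0]})
        g = pd.Series(["a", "a", "b", "b", "c", "c"])
        assert wilks_lambda(df, g, ["x"]) == pytest.approx(1.0)

    def test_duplicated_trait_column_raises_singularity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=20)})
        df["y"] = df["x"]
        g = pd.Series(np.repeat(["a", "b"], 10))
        with pytest.raises(SingularScatterError):
            wilks_lambda(df, g, ["x", "y"])

    def test_matches_independent_scatter_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        g = np.repeat(["a", "b", "c", "d"], 10)
        X[g == "b"] += 1.0
        df = pd.DataFrame(X, columns=["t1", "t2", "t3"])
        lam = wilks_lambda(df, pd.Series(g), ["t1", "t2", "t3"])
        assert lam == pytest.approx(_lambda_oracle(X, g), rel=1e-10)

    def test_affine_rescaling_leaves_lambda_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        g = np.repeat(["a", "b", "c"], 10)
        X[g == "a"] += 0.8
        df = pd.DataFrame(X, columns=["t1", "t2"])
        lam = wilks_lambda(df, pd.Series(g), ["t1", "t2"])
        scaled = df * np.array([100.0, 0.01])
        lam2 = wilks_lambda(scaled, pd.Series(g), ["t1", "t2"])
        assert lam2 == pytest.approx(lam, rel=1e-9)

    def test_orthogonal_rotation_leaves_lambda_unchanged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(36, 3))
        g = np.repeat(["a", "b", "c"], 12)
        X[g == "c"] -= 1.2
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        df = pd.DataFrame(X, columns=["t1", "t2", "t3"])
        dfr = pd.DataFrame(X @ Q, columns=["t1", "t2", "t3"])
        lam = wilks_lambda(df, pd.Series(g), ["t1", "t2", "t3"])
        lam2 = wilks_lambda(dfr, pd.Series(g), ["t1", "t2", "t3"])
        assert lam2 == pytest.approx(lam, rel=1e-9)


class TestForwardSelection:
    def test_stronger_single_trait_added_first(self):
        rng = np.random.default_rng(6)
        g = np.repeat(["a", "b"], 30)
        df = pd.DataFrame({
            "weak": rng.normal(size=60) + 0.3 * (g == "b"),
            "strong": rng.normal(size=60) + 3.0 * (g == "b"),
        })
        steps = forward_select(df, pd.Series(g), ["weak", "strong"])
        assert steps[0].trait == "strong"

    def test_each_step_minimises_lambda_over_remaining(self):
        # exhaustive oracle on <= 3 traits and 12 observations
        rng = np.random.default_rng(7)
        g = np.repeat(["a", "b"], 6)
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=["t1", "t2", "t3"])
        df.loc[g == "b", "t2"] += 2.0
        df.loc[g == "b", "t3"] += 1.0
        steps = forward_select(df, pd.Series(g), ["t1", "t2", "t3"])
        selected: list[str] = []
        for step in steps:
            best = min(
                (c for c in ["t1", "t2", "t3"] if c not in selected),
                key=lambda c: _lambda_oracle(
                    df[selected + [c]].to_numpy(), g),
            )
            assert step.trait == best
            selected.append(step.trait)
            assert step.wilks_lambda == pytest.approx(
                _lambda_oracle(df[selected].to_numpy(), g), rel=1e-9)

    def test_lambda_sequence_non_increasing(self):
        rng = np.random.default_rng(8)
        g = np.repeat(["a", "b", "c"], 40)
        X = rng.normal(size=(120, 6))
        X[g == "b", :2] += 1.0
        X[g == "c", 3] -= 1.5
        df = pd.DataFrame(X, columns=[f"t{i}" for i in range(6)])
        steps = forward_select(df, pd.Series(g), list(df.columns))
        lams = [s.wilks_lambda for s in steps]
        assert all(l2 <= l1 + 1e-12 for l1, l2 in zip(lams, lams[1:]))
        assert all(0 < l <= 1 + 1e-12 for l in lams)

    def test_pure_noise_lambda_near_one_specificity_near_chance(self):
        rng = np.random.default_rng(9)
        g = np.repeat(["a", "b"], 250)
        df = pd.DataFrame(rng.normal(size=(500, 4)),
                          columns=["t1", "t2", "t3", "t4"])
        steps = forward_select(df, pd.Series(g), list(df.columns),
                               max_steps=2)
        assert steps[0].wilks_lambda > 0.95
        mean_spec = np.mean(list(steps[-1].specificity.values()))
        assert mean_spec == pytest.approx(0.5, abs=0.12)


class TestAllocation:
    def test_disjoint_ranges_give_perfect_specificity(self):
        df = pd.DataFrame({"x": [0.0, 0.1, 0.2, 10.0, 10.1, 10.2]})
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        _, spec = allocate(df, g, ["x"])
        assert spec == {"a": 1.0, "b": 1.0}

    def test_equidistant_observation_goes_to_first_group(self):
        df = pd.DataFrame({"x": [0.0, 2.0, 2.0, 4.0]})
        g = pd.Series(["a", "a", "b", "b"])
        pred, _ = allocate(df, g, ["x"])
        # both x=2 observations sit exactly between the group means
        assert pred.iloc[1] == "a" and pred.iloc[2] == "a"

    def test_three_separated_groups_high_specificity(self):
        # group means 3 pooled SDs apart; a group with two neighbours at
        # that distance misallocates ~2*Phi(-1.5) ~ 13% of members in the
        # worst case, so every specificity should clear 0.85
        rng = np.random.default_rng(10)
        n_per = 100
        g = np.repeat(["a", "b", "c"], n_per)
        centres = {"a": (0, 0), "b": (3, 0), "c": (0, 3)}
        X = np.vstack([rng.normal(centres[k], 1.0, size=(n_per, 2))
                       for k in ("a", "b", "c")])
        df = pd.DataFrame(X, columns=["t1", "t2"])
        _, spec = allocate(df, pd.Series(g), ["t1", "t2"])
        assert all(v > 0.85 for v in spec.values())

    def test_matches_sklearn_lda_with_equal_priors(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(11)
        g = np.repeat(["a", "b", "c"], [50, 30, 20])
        X = rng.normal(size=(100, 3))
        X[g == "b", 0] += 1.5
        X[g == "c", 1] -= 1.5
        df = pd.DataFrame(X, columns=["t1", "t2", "t3"])
        pred, _ = allocate(df, pd.Series(g), ["t1", "t2", "t3"])
        lda = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, g)
        agree = np.mean(pred.to_numpy() == lda.predict(X))
        assert agree > 0.99

    def test_rescaling_leaves_allocation_unchanged(self):
        rng = np.random.default_rng(12)
        g = np.repeat(["a", "b"], 25)
        X = rng.normal(size=(50, 2))
        X[g == "b"] += 1.0
        df = pd.DataFrame(X, columns=["t1", "t2"])
        pred1, _ = allocate(df, pd.Series(g), ["t1", "t2"])
        pred2, _ = allocate(df * np.array([1e3, 1e-3]), pd.Series(g),
                            ["t1", "t2"])
        assert (pred1 == pred2).all()


class TestCanonicalProjection:
    def test_collinear_group_means_have_null_second_axis(self):
        rng = np.random.default_rng(13)
        g = np.repeat(["a", "b", "c"], 40)
        X = rng.normal(size=(120, 2), scale=0.5)
        shift = {"a": 0.0, "b": 3.0, "c": 6.0}
        X[:, 0] += np.vectorize(shift.get)(g)  # means on a line
        df = pd.DataFrame(X, columns=["t1", "t2"])
        proj = canonical_projection(df, pd.Series(g), ["t1", "t2"])
        assert proj.eigenvalues[1] == pytest.approx(
            0.0, abs=0.05 * proj.eigenvalues[0])

    def test_singleton_group_circle_radius_is_chi2_quantile(self):
        rng = np.random.default_rng(14)
        g = np.array(["a"] * 10 + ["b"] * 10 + ["c"])
        X = rng.normal(size=(21, 2))
        X[g == "b"] += 2.0
        X[g == "c"] += 4.0
        df = pd.DataFrame(X, columns=["t1", "t2"])
        proj = canonical_projection(df, pd.Series(g), ["t1", "t2"])
        assert proj.circle_radius["c"] == pytest.approx(
            np.sqrt(stats.chi2.ppf(0.95, 2)), rel=1e-9)
        assert proj.circle_radius["c"] == pytest.approx(2.448, abs=5e-4)

    def test_scores_have_unit_within_group_variance(self):
        rng = np.random.default_rng(15)
        g = np.repeat(["a", "b", "c"], 60)
        X = rng.normal(size=(180, 3))
        X[g == "b", 0] += 2.0
        X[g == "c", 1] += 2.0
        df = pd.DataFrame(X, columns=["t1", "t2", "t3"])
        proj = canonical_projection(df, pd.Series(g), ["t1", "t2", "t3"])
        within = []
        for lv in ("a", "b", "c"):
            sub = proj.scores[proj.scores["group"] == lv][["cv1", "cv2"]]
            within.append((sub - sub.mean()).to_numpy())
        pooled = np.vstack(within)
        cov = pooled.T @ pooled / (len(pooled) - 3)
        np.testing.assert_allclose(np.diag(cov), [1.0, 1.0], atol=0.05)

    def test_polygons_enclose_all_group_members(self):
        from matplotlib.path import Path as MplPath
        rng = np.random.default_rng(16)
        g = np.repeat(["a", "b", "c"], 30)
        X = rng.normal(size=(90, 2))
        X[g == "b", 0] += 3.0
        X[g == "c", 1] += 3.0
        df = pd.DataFrame(X, columns=["t1", "t2"])
        proj = canonical_projection(df, pd.Series(g), ["t1", "t2"])
        for lv in ("a", "b", "c"):
            pts = proj.scores[proj.scores["group"] == lv][["cv1", "cv2"]]
            poly = MplPath(proj.polygons[lv])
            inside = poly.contains_points(pts.to_numpy(), radius=1e-9)
            assert inside.mean() > 0.99  # hull vertices sit on the boundary
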