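"""PCA reduction and flexible discriminant analysis, checked against
closed-form eigendecomposition and pooled-covariance LDA oracles."""

import numpy as np
import pandas as pd
import pytest

from minkpat.classify import assign, coefficient_importance, fit_fda, pca_reduce


def lda_oracle_predict(X: np.ndarray, y: np.ndarray, Xnew: np.ndarray) -> np.ndarray:
    """Closed-form pooled-covariance linear discriminant assignments."""
    classes = np.unique(y)
    n, J = len(X), len(classes)
    mus = np.array([X[y == c].mean(axis=0) for c in classes])
    Sw = sum(
        (X[y == c] - mus[i]).T @ (X[y == c] - mus[i]) for i, c in enumerate(classes)
    ) / (n - J)
    Swi = np.linalg.inv(Sw)
    priors = np.array([(y == c).mean() for c in classes])
    scores = np.stack(
        [Xnew @ Swi @ mus[i] - 0.5 * mus[i] @ Swi @ mus[i] + np.log(priors[i]) for i in range(J)],
        axis=1,
    )
    return classes[np.argmax(scores, axis=1)]


def make_dataset(rng, n=40, p=4, J=2, sep=1.5):
    y = rng.integers(0, J, n)
    y[: 2 * J] = np.repeat(np.arange(J), 2)  # every class populated
    centers = rng.normal(scale=sep, size=(J, p))
    X = rng.normal(size=(n, p)) + centers[y]
    Xdf = pd.DataFrame(X, columns=[f"t{i}" for i in range(p)])
    return Xdf, np.array([f"c{j}" for j in y])


class TestPcaReduce:
    def test_rank_one_data_needs_one_component(self, rng):
        base = rng.normal(size=50)
        X = pd.DataFrame({"a": base, "b": 2 * base + 1, "c": -base})
        scores, loadings, frac = pca_reduce(X, var_fraction=0.99)
        assert scores.shape[1] == 1
        assert frac[0] == pytest.approx(1.0)

    def test_full_rank_with_var_fraction_one_keeps_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        scores, _, frac = pca_reduce(X, var_fraction=1.0)
        assert scores.shape[1] == 4
        assert frac.sum() == pytest.approx(1.0)

    def test_explained_fractions_match_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        _, _, frac = pca_reduce(X, var_fraction=1.0)
        z = (X - X.mean()) / X.std(ddof=1)
        ev = np.linalg.eigvalsh(np.cov(z.to_numpy().T))[::-1]
        np.testing.assert_allclose(frac, ev / ev.sum(), atol=1e-10)

    def test_invalid_inputs(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            pca_reduce(X, var_fraction=0.0)
        with pytest.raises(ValueError):
            pca_reduce(X.iloc[:1], var_fraction=0.9)


class TestFitFda:
    def test_linear_basis_matches_lda_oracle_across_datasets(self, rng):
        for _ in range(30):
            Xdf, y = make_dataset(
                rng,
                n=int(rng.integers(20, 60)),
                p=int(rng.integers(2, 6)),
                J=int(rng.integers(2, 4)),
            )
            model = fit_fda(Xdf, y, basis="linear")
            np.testing.assert_array_equal(
                model.predict(Xdf), lda_oracle_predict(Xdf.to_numpy(), y, Xdf.to_numpy())
            )

    def test_perfect_separation_gives_full_resubstitution(self, rng):
        X = pd.DataFrame(
            {"t0": np.r_[rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10)],
             "t1": rng.normal(size=20)}
        )
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_fda(X, y)
        rates = assign(model, X, y, scheme="resubstitution")
        assert rates["a"] == 100.0 and rates["b"] == 100.0

    def test_permuted_labels_stay_near_chance(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 5)), columns=[f"t{i}" for i in range(5)])
        y = np.array(["a", "b"] * 250)
        rng.shuffle(y)
        model = fit_fda(X, y)
        acc = (model.predict(X) == y).mean() * 100
        assert acc <= 55.0  # chance + resubstitution optimism margin

    def test_constant_column_rejected(self, rng):
        X = pd.DataFrame({"t0": rng.normal(size=10), "t1": np.ones(10)})
        y = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError, match="constant"):
            fit_fda(X, y)

    def test_singular_design_suggests_ridge(self, rng):
        base = rng.normal(size=12)
        X = pd.DataFrame({"t0": base, "t1": 2 * base})  # perfectly collinear
        y = np.array(["a", "b"] * 6)
        with pytest.raises(ValueError, match="ridge"):
            fit_fda(X, y)
        fit_fda(X, y, ridge=1e-3)  # regularized fit succeeds

    def test_polynomial_basis_separates_nonlinear_classes(self, rng):
        # radial classes: linear FDA fails, degree-2 basis succeeds
        r = np.r_[rng.uniform(0, 1, 40), rng.uniform(2, 3, 40)]
        th = rng.uniform(0, 2 * np.pi, 80)
        X = pd.DataFrame({"x": r * np.cos(th), "y": r * np.sin(th)})
        y = np.array(["inner"] * 40 + ["outer"] * 40)
        linear_acc = (fit_fda(X, y, "linear").predict(X) == y).mean()
        poly_acc = (fit_fda(X, y, "polynomial2").predict(X) == y).mean()
        assert poly_acc > 0.95 > linear_acc + 0.2

    def test_affine_trait_rescaling_leaves_assignments_unchanged(self, rng):
        Xdf, y = make_dataset(rng, n=50, p=3)
        model = fit_fda(Xdf, y)
        X2 = Xdf.copy()
        X2["t1"] = 1000.0 * X2["t1"] - 7.0
        model2 = fit_fda(X2, y)
        np.testing.assert_array_equal(model.predict(Xdf), model2.predict(X2))


class TestAssign:
    def test_class_mean_of_separated_classes_assigned_to_it(self, rng):
        Xdf, y = make_dataset(rng, n=40, p=3, sep=8.0)
        model = fit_fda(Xdf, y)
        mean_row = Xdf[y == "c0"].mean().to_frame().T
        assert model.predict(mean_row)[0] == "c0"

    def test_leave_one_out_near_monte_carlo_bayes_rate(self, rng):
        # 1-D separation mu=0 vs mu=2, unit variance: Bayes accuracy = Phi(1)
        n = 80
        y = np.array(["a", "b"] * (n // 2))
        X = pd.DataFrame(
            {"t0": rng.normal(size=n) + np.where(y == "b", 2.0, 0.0),
             "t1": rng.normal(size=n)}
        )
        # Monte-Carlo Bayes-rate oracle from the true generative model
        sim = np.random.default_rng(1).normal(size=200_000)
        bayes = (sim + 2.0 > 1.0).mean()  # optimal boundary at 1.0
        model = fit_fda(X, y)
        rates = assign(model, X, y, scheme="leave_one_out")
        overall = (rates["a"] + rates["b"]) / 200.0
        se = np.sqrt(bayes * (1 - bayes) / n)
        assert abs(overall - bayes) <= 4 * se + 0.05  # binomial CI + estimation slack

    def test_unknown_scheme_rejected(self, rng):
        Xdf, y = make_dataset(rng)
        model = fit_fda(Xdf, y)
        with pytest.raises(ValueError):
            assign(model, Xdf, y, scheme="bootstrap")

    def test_column_mismatch_rejected(self, rng):
        Xdf, y = make_dataset(rng)
        model = fit_fda(Xdf, y)
        with pytest.raises(ValueError, match="columns"):
            model.predict(Xdf.rename(columns={"t0": "z"}))


class TestCoefficientImportance:
    def test_sums_to_100(self, rng):
        Xdf, y = make_dataset(rng, n=60, p=5)
        imp = coefficient_importance(fit_fda(Xdf, y))
        assert imp.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_trait_model_gets_everything(self, rng):
        X = pd.DataFrame({"only": np.r_[rng.normal(0, 1, 15), rng.normal(3, 1, 15)]})
        y = np.array(["a"] * 15 + ["b"] * 15)
        imp = coefficient_importance(fit_fda(X, y))
        assert imp["only"] == pytest.approx(100.0)

    def test_exchange_symmetric_traits_split_evenly(self, rng):
        # duplicating each row with its two traits swapped makes the sample
        # exactly exchange-symmetric, so |coefficients| must be equal
        half = rng.normal(size=(30, 2)) + np.r_[np.zeros((15, 2)), np.full((15, 2), 2.0)]
        X = pd.DataFrame(np.vstack([half, half[:, ::-1]]), columns=["u", "v"])
        y = np.array((["a"] * 15 + ["b"] * 15) * 2)
        imp = coefficient_importance(fit_fda(X, y))
        assert imp["u"] == pytest.approx(50.0, abs=1e-6)
        assert imp["v"] == pytest.approx(50.0, abs=1e-6)

    def test_discriminating_trait_dominates(self, rng):
        n = 1000
        y = np.array(["a", "b"] * (n // 2))
        X = pd.DataFrame(
            {"signal": rng.normal(size=n) + np.where(y == "b", 5.0, 0.0),
             "noise1": rng.normal(size=n),
             "noise2": rng.normal(size=n)}
        )
        imp = coefficient_importance(fit_fda(X, y))
        assert imp["signal"] > 90.0
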