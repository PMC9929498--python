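"""PCA reduction and flexible discriminant analysis by optimal scoring.

Flexible discriminant analysis (FDA) recasts discriminant analysis as a
regression problem: class labels are encoded as indicator columns, assigned
*optimal scores*, and those scores are regressed on a (possibly expanded)
basis of the traits.  With the linear basis the discriminant variates span
the classical canonical space, so FDA assignments coincide exactly with
linear discriminant analysis (LDA); a degree-2 polynomial basis buys the
"flexible" non-linear boundaries, and a ridge penalty handles singular
within-class structure.

The fitted model classifies in the whitened canonical space: a point goes
to the class whose centroid is nearest in within-class Mahalanobis
distance, penalised by −2·log(prior).  Trait contributions are summarised
as the absolute standardised first-discriminant coefficients normalised to
sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["FDAModel", "pca_reduce", "fit_fda", "assign", "predict", "coefficient_importance"]


def _standardize(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = X.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = list(X.columns[sd <= 0])
        raise ValueError(f"constant trait columns cannot be standardized: {bad}")
    return (x - mu) / sd, mu, sd


def pca_reduce(X: pd.DataFrame, var_fraction: float = 0.9):
    """Principal components of the standardised trait table.

    Returns the smallest number of components whose cumulative explained
    variance reaches ``var_fraction``, as ``(scores, loadings, explained)``
    where ``scores`` is an n x k DataFrame (columns PC1..PCk), ``loadings``
    maps traits to components, and ``explained`` gives per-component
    explained-variance fractions for the retained components.
    """
    if not 0 < var_fraction <= 1:
        raise ValueError("var_fraction must be in (0, 1]")
    if len(X) < 2:
        raise ValueError("need at least 2 rows")
    z, _, _ = _standardize(X)
    # SVD of the centred standardised matrix gives eigenstructure directly
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    ev = s**2 / (len(X) - 1)
    frac = ev / ev.sum()
    k = int(np.searchsorted(np.cumsum(frac), var_fraction - 1e-12) + 1)
    k = min(k, len(frac))
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(z @ vt[:k].T, index=X.index, columns=cols)
    loadings = pd.DataFrame(vt[:k].T, index=X.columns, columns=cols)
    return scores, loadings, frac[:k]


def _expand(z: np.ndarray, names: Sequence[str], basis: str) -> tuple[np.ndarray, list[str]]:
    if basis == "linear":
        return z, list(names)
    if basis == "polynomial2":
        cols = [z]
        out_names = list(names)
        p = z.shape[1]
        for i in range(p):
            for j in range(i, p):
                cols.append((z[:, i] * z[:, j])[:, None])
                out_names.append(f"{names[i]}*{names[j]}" if i != j else f"{names[i]}^2")
        return np.hstack(cols), out_names
    raise ValueError(f"unknown basis {basis!r}")


@dataclass
class FDAModel:
    """A fitted flexible-discriminant model (see module docstring)."""

    basis: str
    classes_: np.ndarray
    columns: list[str]
    feature_names: list[str]
    mu: np.ndarray  # trait means used for standardisation
    sd: np.ndarray  # trait standard deviations
    directions: np.ndarray  # expanded-feature space -> whitened canonical space
    intercept: np.ndarray
    centroids: np.ndarray  # class centroids in canonical space
    priors: np.ndarray
    ridge: float = 0.0
    training_summary: dict = field(default_factory=dict)

    def _canonical(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.columns:
            raise ValueError(
                f"trait columns {list(X.columns)} do not match model columns {self.columns}"
            )
        z = (X.to_numpy(dtype=float) - self.mu) / self.sd
        zb, _ = _expand(z, self.columns, self.basis)
        return zb @ self.directions + self.intercept

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        v = self._canonical(X)
        d2 = ((v[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        score = d2 - 2.0 * np.log(self.priors)[None, :]
        return self.classes_[np.argmin(score, axis=1)]


def fit_fda(
    X: pd.DataFrame,
    labels: Sequence,
    basis: str = "linear",
    ridge: float = 0.0,
) -> FDAModel:
    """Fit FDA by optimal scoring of class indicators on basis-expanded traits.

    Steps: standardise traits, expand the basis, regress the class-indicator
    matrix on the expansion (optionally ridge-penalised), eigendecompose the
    fitted-score cross-product to obtain the optimal scores, and whiten the
    resulting discriminant variates in the pooled within-class metric so
    that nearest-centroid classification with priors reproduces LDA exactly
    for the linear basis.
    """
    y = np.asarray(labels)
    classes, yint = np.unique(y, return_inverse=True)
    J = len(classes)
    n = len(y)
    if J < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(yint, minlength=J)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows")

    z, mu, sd = _standardize(X)
    zb, feat_names = _expand(z, list(X.columns), basis)
    zb_mean = zb.mean(axis=0)
    zc = zb - zb_mean

    Y = np.zeros((n, J))
    Y[np.arange(n), yint] = 1.0

    G = zc.T @ zc + ridge * np.eye(zc.shape[1])
    try:
        B = linalg.solve(G, zc.T @ Y, assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - depends on data
        raise ValueError(
            "singular within-class structure; refit with ridge > 0"
        ) from exc
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"near-singular design (condition number {cond:.2e}); refit with ridge > 0"
        )

    # optimal scores: eigenvectors of D^{-1} Y' Yhat, dropping the trivial
    # constant score (eigenvalue 1)
    Yhat = zc @ B
    M = (Y.T @ Yhat) / n
    Dinv = np.diag(n / counts.astype(float))
    evals, evecs = np.linalg.eig(Dinv @ M)
    evals, evecs = evals.real, evecs.real
    order = np.argsort(evals)[::-1]
    keep = [i for i in order if evals[i] > 1e-10][: J - 1]
    theta = evecs[:, keep]

    A = B @ theta  # discriminant directions in expanded-feature space
    V = zc @ A  # raw variates

    # whiten in the pooled within-class metric
    Vw = V - Y @ (Dinv / n) @ (Y.T @ V)  # subtract class means
    W = (Vw.T @ Vw) / (n - J)
    ew, Uw = np.linalg.eigh(W)
    if ew.min() <= 1e-12 * max(ew.max(), 1.0):
        raise ValueError("degenerate discriminant variates; refit with ridge > 0")
    T = Uw @ np.diag(ew**-0.5) @ Uw.T
    directions = A @ T
    intercept = -zb_mean @ directions

    Vcan = zb @ directions + intercept
    centroids = np.vstack([Vcan[yint == j].mean(axis=0) for j in range(J)])
    priors = counts / n

    model = FDAModel(
        basis=basis,
        classes_=classes,
        columns=list(X.columns),
        feature_names=feat_names,
        mu=mu,
        sd=sd,
        directions=directions,
        intercept=intercept,
        centroids=centroids,
        priors=priors,
        ridge=ridge,
    )
    pred = model.predict(X)
    rates = {str(c): float((pred[y == c] == c).mean() * 100) for c in classes}
    model.training_summary = {"resubstitution_percent_correct": rates}
    return model


def predict(model: FDAModel, X: pd.DataFrame) -> np.ndarray:
    """Class assignment for each row of ``X``."""
    return model.predict(X)


def assign(
    model: FDAModel,
    X: pd.DataFrame,
    labels: Sequence,
    scheme: str = "resubstitution",
) -> pd.Series:
    """Per-class percentage of correct assignments.

    ``resubstitution`` scores the supplied model on (X, labels);
    ``leave_one_out`` refits the model n times, holding out one row each
    time.  The scheme is recorded in the result's name so reported rates
    are never ambiguous.
    """
    y = np.asarray(labels)
    if scheme == "resubstitution":
        pred = model.predict(X)
    elif scheme == "leave_one_out":
        pred = np.empty(len(X), dtype=object)
        for i in range(len(X)):
            keep = np.ones(len(X), dtype=bool)
            keep[i] = False
            m = fit_fda(X.iloc[keep], y[keep], basis=model.basis, ridge=model.ridge)
            pred[i] = m.predict(X.iloc[[i]])[0]
        pred = np.asarray(pred)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rates = {str(c): float((pred[y == c] == c).mean() * 100) for c in model.classes_}
    return pd.Series(rates, name=f"percent_correct[{scheme}]")


def coefficient_importance(model: FDAModel) -> pd.Series:
    """Trait contributions: |first-discriminant coefficients|, summing to 100%.

    Coefficients are on standardised traits (standardisation happens inside
    the fit), so magnitudes are comparable across traits with different
    units.
    """
    coefs = np.abs(model.directions[:, 0])
    total = coefs.sum()
    if total <= 0:
        raise ValueError("model has a null first discriminant")
    return pd.Series(100.0 * coefs / total, index=model.feature_names, name="importance_percent")
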