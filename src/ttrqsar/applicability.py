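"""Applicability domains and per-prediction reliability assessment.

Classification AD: structural check via the mean cosine similarity (cos α) to
the 3 nearest training compounds against a 95%-training-coverage threshold;
endpoint check via the posterior band (uncertain in (0.25, 0.75)); uncertainty
check via Shannon entropy against the maximum training entropy.

Regression AD: structural check via leverage against h* = 3(p+1)/n; response
check via the training response range; uncertainty check via the prediction
interval width against the maximum training width; response outliers flagged
at standardized residuals beyond ±2.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model_build import LDAModel, MLRModel, Scaler


@dataclass
class ADVerdict:
    """Component reliability flags for one prediction plus numeric evidence."""

    structural: str  # inside / outside
    endpoint: str  # certain / uncertain (classification), in_range / out_of_range (regression)
    uncertainty: str  # reliable / unreliable
    overall: str  # reliable / unreliable
    evidence: dict = field(default_factory=dict)

    @staticmethod
    def combine(structural_ok: bool, endpoint_ok: bool, uncertainty_ok: bool,
                endpoint_labels=("certain", "uncertain"), evidence=None) -> "ADVerdict":
        return ADVerdict(
            structural="inside" if structural_ok else "outside",
            endpoint=endpoint_labels[0] if endpoint_ok else endpoint_labels[1],
            uncertainty="reliable" if uncertainty_ok else "unreliable",
            overall="reliable" if (structural_ok and endpoint_ok and uncertainty_ok) else "unreliable",
            evidence=evidence or {},
        )


def cos_alpha(u, v) -> float:
    """Cosine similarity of two descriptor vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cos alpha undefined for a zero vector")
    return float(u @ v / (nu * nv))


def shannon_entropy(posteriors) -> float:
    """Shannon entropy (nats) of a class-posterior vector; 0*ln 0 = 0."""
    p = np.asarray(posteriors, dtype=float)
    if np.any(p < -1e-12) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("posteriors must be a probability vector")
    p = np.clip(p, 0.0, 1.0)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _knn_mean_cos(x: np.ndarray, train: np.ndarray, k: int) -> float:
    sims = train @ x / (np.linalg.norm(train, axis=1) * np.linalg.norm(x))
    top = np.sort(sims)[-k:]
    return float(top.mean())


@dataclass
class ClassificationAD:
    """Structural/endpoint/uncertainty domain of a classification model."""

    train_scaled: np.ndarray
    scaler: Optional[Scaler]
    k: int = 3
    coverage: float = 0.95
    threshold: float = 0.0
    max_entropy: float = math.log(2)
    posterior_band: tuple[float, float] = (0.25, 0.75)
    train_knn_cos: np.ndarray = field(default_factory=lambda: np.empty(0))

    def knn_cos(self, x_raw) -> float:
        x = np.asarray(x_raw, dtype=float)
        if self.scaler is not None:
            x = self.scaler.transform(x[None, :])[0]
        return _knn_mean_cos(x, self.train_scaled, self.k)


def fit_classification_ad(
    X_train,
    scaler: Optional[Scaler] = None,
    k: int = 3,
    coverage: float = 0.95,
    model=None,
) -> ClassificationAD:
    """Fit the cos-α k-NN structural domain on (auto-scaled) training vectors.

    For each training compound the mean cos α of its ``k`` most similar
    neighbors (self excluded) is computed; the threshold is the
    (1 - coverage) quantile of that distribution, so ``coverage`` of the
    training set sits at or above it.  A query whose k-NN mean cos α falls
    below the threshold is outside the structural domain.  Similarities are
    computed on raw descriptor vectors by default (descriptor values share a
    common, positive-leaning orientation, which is what makes training
    thresholds close to 1); pass a fitted ``scaler`` to compute them on
    autoscaled vectors instead.  The maximum training entropy is taken from
    ``model`` posteriors when given (ln 2 otherwise).
    """
    if isinstance(X_train, pd.DataFrame):
        X_train = X_train.to_numpy(dtype=float)
    X_train = np.asarray(X_train, dtype=float)
    n = len(X_train)
    if n <= k:
        raise ValueError("need more training compounds than k")
    xs = scaler.transform(X_train) if scaler is not None else X_train
    sims = np.empty(n)
    for i in range(n):
        others = np.delete(xs, i, axis=0)
        sims[i] = _knn_mean_cos(xs[i], others, k)
    threshold = float(np.quantile(sims, 1.0 - coverage))
    max_h = math.log(2)
    if model is not None:
        # fitted models scale internally from raw descriptors; frozen models
        # take raw descriptors directly
        post = model.posterior(X_train)
        max_h = float(max(shannon_entropy(p) for p in post))
    return ClassificationAD(
        train_scaled=xs,
        scaler=scaler,
        k=k,
        coverage=coverage,
        threshold=threshold,
        max_entropy=max_h,
        train_knn_cos=sims,
    )


def assess_classification(query, model, ad: ClassificationAD) -> ADVerdict:
    """Reliability verdict for one classification prediction.

    ``model`` is anything exposing ``posterior`` over the AD's descriptors (a
    fitted :class:`LDAModel` or a frozen published model).  Structural check:
    k-NN mean cos α at or above the threshold; endpoint check: maximum
    posterior at or above the upper band edge; uncertainty check: entropy at
    or below the maximum training entropy.
    """
    x = np.asarray(query, dtype=float)
    post = np.asarray(model.posterior(x[None, :]))[0]
    sim = ad.knn_cos(x)
    h = shannon_entropy(post)
    structural_ok = sim >= ad.threshold
    endpoint_ok = float(post.max()) >= ad.posterior_band[1]
    uncertainty_ok = h <= ad.max_entropy + 1e-12
    return ADVerdict.combine(
        structural_ok,
        endpoint_ok,
        uncertainty_ok,
        evidence={"knn_cos_alpha": sim, "posterior_max": float(post.max()), "entropy": h},
    )


# ---------------------------------------------------------------------------
# Regression AD


def h_star(p: int, n: int) -> float:
    """Leverage cutoff h* = 3(p + 1)/n."""
    return 3.0 * (p + 1) / n


def leverage(query, model: MLRModel) -> float:
    """Hat-matrix leverage h = x0' (X'X)^-1 x0 of an intercept-augmented query."""
    return float(model.leverage(np.atleast_2d(np.asarray(query, dtype=float)))[0])


def standardized_residuals(model: MLRModel, truth, predictions) -> np.ndarray:
    """Residuals in residual-SD units; |value| > 2.5 marks a response outlier."""
    truth = np.asarray(truth, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    return (truth - predictions) / model.sigma


def prediction_interval(query, model: MLRModel, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided (1 - alpha) prediction interval for a new observation:
    ŷ ± t_{1-alpha/2, n-p-1} * s * sqrt(1 + h)."""
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    x = np.atleast_2d(np.asarray(query, dtype=float))
    yhat = float(model.predict(x)[0])
    h = float(model.leverage(x)[0])
    t = stats.t.ppf(1 - alpha / 2, model.df_resid)
    half = t * model.sigma * math.sqrt(1.0 + h)
    return yhat - half, yhat + half


@dataclass
class RegressionAD:
    """Leverage/response/uncertainty domain of a regression model.

    Self-contained: carries the inverse design cross-product so query
    leverages and interval widths can be computed for any predictor (fitted
    or frozen equation) sharing the same descriptors.
    """

    h_star: float
    train_leverages: np.ndarray
    sigma: float
    max_pi_width: float
    y_range: tuple[float, float]
    xtx_inv: np.ndarray
    df_resid: int
    residual_bound: float = 2.5
    alpha: float = 0.05

    def leverage(self, query) -> float:
        x = np.concatenate([[1.0], np.asarray(query, dtype=float).ravel()])
        return float(x @ self.xtx_inv @ x)

    def pi_width(self, query) -> float:
        t = stats.t.ppf(1 - self.alpha / 2, self.df_resid)
        return 2 * t * self.sigma * math.sqrt(1.0 + self.leverage(query))


def fit_regression_ad(
    model: MLRModel, X_train, alpha: float = 0.05, residual_bound: float = 2.5
) -> RegressionAD:
    """Collect AD statistics (h*, training leverages, maximum training
    prediction-interval width, response range) from a fitted OLS model."""
    levs = model.leverage(X_train)
    t = stats.t.ppf(1 - alpha / 2, model.df_resid)
    widths = 2 * t * model.sigma * np.sqrt(1.0 + levs)
    return RegressionAD(
        h_star=h_star(model.p, model.n),
        train_leverages=np.asarray(levs),
        sigma=model.sigma,
        max_pi_width=float(widths.max()),
        y_range=model.y_range,
        xtx_inv=model.xtx_inv,
        df_resid=model.df_resid,
        residual_bound=residual_bound,
        alpha=alpha,
    )


def assess_regression(query, model, ad: RegressionAD) -> ADVerdict:
    """Reliability verdict for one regression prediction.

    ``model`` provides the prediction (fitted :class:`MLRModel` or a frozen
    published equation); leverages and interval widths come from the AD's
    stored design statistics.  Structural check: h <= h*; response check:
    prediction within the training response range; uncertainty check:
    prediction-interval width within the training maximum.
    """
    x = np.atleast_2d(np.asarray(query, dtype=float))
    yhat = float(np.asarray(model.predict(x))[0])
    h = ad.leverage(x[0])
    width = ad.pi_width(x[0])
    structural_ok = h <= ad.h_star
    in_range = ad.y_range[0] <= yhat <= ad.y_range[1]
    uncertainty_ok = width <= ad.max_pi_width + 1e-12
    return ADVerdict.combine(
        structural_ok,
        in_range,
        uncertainty_ok,
        endpoint_labels=("in_range", "out_of_range"),
        evidence={"leverage": h, "h_star": ad.h_star, "prediction": yhat, "pi_width": width},
    )
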