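"""Model development: structure-ranked splitting, LDA and OLS fits, step-up
variable selection with bootstrap overfitting control, randomization and
Y-scrambling validation, and the fitting/predictivity metrics.

LDA and OLS are implemented natively (numpy linear algebra) so that the
scoring equations, posteriors, standard errors and hat-matrix quantities are
available in exactly the form the applicability-domain machinery needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import softmax

logger = logging.getLogger("ttrqsar")


# ---------------------------------------------------------------------------
# Scaling and splitting


@dataclass
class Scaler:
    """Column autoscaler (training mean / SD, SD with ddof=1)."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Scaler":
        std = x.std(axis=0, ddof=1)
        std = np.where(std == 0.0, 1.0, std)
        return cls(mean=x.mean(axis=0), std=std)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.std


def _pc1_scores(x: np.ndarray) -> np.ndarray:
    """First principal component scores of autoscaled data, sign-fixed."""
    xs = Scaler.fit(x).transform(x)
    xs = xs - xs.mean(axis=0)
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    pc1 = vt[0]
    # deterministic sign: largest-|loading| component positive
    j = int(np.argmax(np.abs(pc1)))
    if pc1[j] < 0:
        pc1 = -pc1
    return xs @ pc1


def split_by_structure(
    matrix: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    labels: Optional[Sequence[str]] = None,
) -> tuple[list, list]:
    """Structure-ranked train/test split.

    Within each stratum (each activity class if ``labels`` is given, the
    whole set otherwise) the descriptors are autoscaled, compounds are ranked
    by their first-principal-component score, and every k-th compound along
    the ranking (k = round(1/(1 - train_fraction)), i.e. ranks 3, 6, 9, ...
    for a 2/3 split) goes to the test set.  Ties in PC1 score are broken by
    input order.  Deterministic; both sets span the PC1 range.
    """
    k = int(round(1.0 / (1.0 - train_fraction)))
    if k < 2:
        raise ValueError("train_fraction too small")
    ids = list(matrix.index)
    if labels is None:
        strata = {None: ids}
    else:
        labels = np.asarray(labels)
        strata = {c: [i for i, lab in zip(ids, labels) if lab == c] for c in np.unique(labels)}
    train, test = [], []
    for members in strata.values():
        if len(members) < 3:
            raise ValueError("need at least 3 compounds per stratum")
        x = matrix.loc[members].to_numpy(dtype=float)
        if np.all(x.std(axis=0) == 0.0):
            raise ValueError("constant descriptor matrix: PCA undefined")
        scores = _pc1_scores(x)
        order = np.argsort(scores, kind="stable")
        for rank, idx in enumerate(order, start=1):
            (test if rank % k == 0 else train).append(members[idx])
    return train, test


# ---------------------------------------------------------------------------
# LDA


@dataclass
class LDAModel:
    """Two-class linear discriminant with pooled within-class covariance.

    Per-class linear score g_k(x) = x' S^-1 mu_k - 0.5 mu_k' S^-1 mu_k +
    ln(pi_k) on autoscaled descriptors; posterior = softmax of the scores.
    """

    descriptor_names: list[str]
    classes: list[str]
    means: np.ndarray  # (K, p) scaled space
    pooled_cov: np.ndarray
    priors: np.ndarray
    coef: np.ndarray  # (K, p) scaled space
    intercept: np.ndarray  # (K,)
    scaler: Optional[Scaler]
    training_ids: list = field(default_factory=list)
    tie_class: str = "A"

    def _prepare(self, x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            x = x[self.descriptor_names].to_numpy(dtype=float)
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.scaler.transform(x) if self.scaler is not None else x

    def scores(self, x) -> np.ndarray:
        return self._prepare(x) @ self.coef.T + self.intercept

    def posterior(self, x) -> np.ndarray:
        return softmax(self.scores(x), axis=1)

    def predict(self, x) -> np.ndarray:
        s = self.scores(x)
        best = np.argmax(s, axis=1)
        # exact score ties go to the precautionary class
        if self.tie_class in self.classes:
            tie_idx = self.classes.index(self.tie_class)
            ties = np.isclose(s.max(axis=1), s[:, tie_idx])
            best = np.where(ties, tie_idx, best)
        return np.array([self.classes[i] for i in best])


def fit_lda(
    X,
    y: Sequence[str],
    priors: Optional[Sequence[float]] = None,
    autoscale: bool = True,
    descriptor_names: Optional[list[str]] = None,
    training_ids: Optional[list] = None,
) -> LDAModel:
    """Canonical two-class LDA; empirical priors unless ``priors`` is given."""
    if isinstance(X, pd.DataFrame):
        descriptor_names = descriptor_names or list(X.columns)
        training_ids = training_ids if training_ids is not None else list(X.index)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n, p = X.shape
    scaler = Scaler.fit(X) if autoscale else None
    xs = scaler.transform(X) if scaler is not None else X
    means, counts = [], []
    scatter = np.zeros((p, p))
    for c in classes:
        xc = xs[y == c]
        mu = xc.mean(axis=0)
        means.append(mu)
        counts.append(len(xc))
        d = xc - mu
        scatter += d.T @ d
    means = np.asarray(means)
    pooled = scatter / (n - len(classes))
    try:
        cov_inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; filter correlated/constant descriptors first"
        ) from exc
    pri = (
        np.asarray(counts, dtype=float) / n
        if priors is None
        else np.asarray(priors, dtype=float)
    )
    coef = means @ cov_inv
    intercept = -0.5 * np.einsum("kp,kp->k", coef, means) + np.log(pri)
    return LDAModel(
        descriptor_names=descriptor_names or [f"x{j}" for j in range(p)],
        classes=classes,
        means=means,
        pooled_cov=pooled,
        priors=pri,
        coef=coef,
        intercept=intercept,
        scaler=scaler,
        training_ids=training_ids or [],
    )


# ---------------------------------------------------------------------------
# OLS


@dataclass
class MLRModel:
    """OLS multiple linear regression on raw descriptor values.

    Stores the inverse cross-product of the intercept-augmented design (for
    leverages and prediction intervals) and the training response range.
    """

    descriptor_names: list[str]
    coef: np.ndarray  # (p+1,) intercept first
    se: np.ndarray
    sigma: float  # residual SD, df = n - p - 1
    xtx_inv: np.ndarray  # ((p+1), (p+1))
    y_range: tuple[float, float]
    n: int
    p: int
    training_ids: list = field(default_factory=list)

    def _design(self, x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            x = x[self.descriptor_names].to_numpy(dtype=float)
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.column_stack([np.ones(len(x)), x])

    def predict(self, x) -> np.ndarray:
        return self._design(x) @ self.coef

    def leverage(self, x) -> np.ndarray:
        d = self._design(x)
        return np.einsum("ij,jk,ik->i", d, self.xtx_inv, d)

    @property
    def df_resid(self) -> int:
        return self.n - self.p - 1


def fit_ols(X, y, descriptor_names: Optional[list[str]] = None,
            training_ids: Optional[list] = None) -> MLRModel:
    """Ordinary least squares with coefficient standard errors."""
    if isinstance(X, pd.DataFrame):
        descriptor_names = descriptor_names or list(X.columns)
        training_ids = training_ids if training_ids is not None else list(X.index)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    d = np.column_stack([np.ones(n), X])
    xtx = d.T @ d
    if np.linalg.matrix_rank(xtx) < p + 1:
        raise ValueError("rank-deficient design matrix")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ d.T @ y
    resid = y - d @ coef
    dof = n - p - 1
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 * np.diag(xtx_inv))
    return MLRModel(
        descriptor_names=descriptor_names or [f"x{j}" for j in range(p)],
        coef=coef,
        se=se,
        sigma=math.sqrt(s2),
        xtx_inv=xtx_inv,
        y_range=(float(y.min()), float(y.max())),
        n=n,
        p=p,
        training_ids=training_ids or [],
    )


# ---------------------------------------------------------------------------
# Criteria


def r_squared(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0 or np.allclose(y, y.mean()):
        logger.warning("zero response variance: R^2 undefined, reported as 0")
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / tss


def mae(y, yhat) -> float:
    return float(np.mean(np.abs(np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float))))


def _training_criterion(X: pd.DataFrame, y, subset: tuple, algorithm: str) -> float:
    xs = X[list(subset)]
    if algorithm == "lda":
        model = fit_lda(xs, y)
        return float(np.mean(model.predict(xs) != np.asarray(y)))  # MR, lower better
    model = fit_ols(xs, y)
    return r_squared(y, model.predict(xs))  # R^2, higher better


def _higher_is_better(algorithm: str) -> bool:
    return algorithm != "lda"


# ---------------------------------------------------------------------------
# Step-up selection


@dataclass
class SelectionTrace:
    """Populations of retained models at each size, plus bootstrap estimates."""

    algorithm: str
    criterion: str  # "MR" or "R2"
    higher_is_better: bool
    populations: dict[int, list[tuple[tuple[str, ...], float]]]
    bootstrap: dict[int, tuple[float, float]] = field(default_factory=dict)

    def best(self, size: int) -> tuple[tuple[str, ...], float]:
        return self.populations[size][0]


def step_up_select(
    X: pd.DataFrame,
    y,
    algorithm: str = "lda",
    beam: Optional[int] = 25,
    max_size: int = 3,
) -> SelectionTrace:
    """Beam-style forward (step-up) variable subset selection.

    The size-1 population is the best ``beam`` single-descriptor models by the
    training criterion (MR for LDA, R^2 for OLS); each size-k population is
    the best ``beam`` of all subsets formed by adding one new descriptor to a
    retained size-(k-1) subset, duplicates merged.  ``beam=None`` retains all
    candidates (exhaustive at every size).  Deterministic: ties are broken by
    descriptor-name order.
    """
    names = list(X.columns)
    if max_size >= len(names) + 1:
        raise ValueError("max_size must be below the number of descriptors + 1")
    hib = _higher_is_better(algorithm)
    sign = -1.0 if hib else 1.0

    def ranked(cands: set[tuple[str, ...]]) -> list[tuple[tuple[str, ...], float]]:
        scored = [(s, _training_criterion(X, y, s, algorithm)) for s in sorted(cands)]
        scored.sort(key=lambda t: (sign * t[1], t[0]))
        return scored if beam is None else scored[:beam]

    populations: dict[int, list] = {}
    current = {(n,) for n in names}
    populations[1] = ranked(current)
    for size in range(2, max_size + 1):
        cands = {
            tuple(sorted(set(subset) | {n}))
            for subset, _ in populations[size - 1]
            for n in names
            if n not in subset
        }
        populations[size] = ranked(cands)
    return SelectionTrace(
        algorithm=algorithm,
        criterion="R2" if hib else "MR",
        higher_is_better=hib,
        populations=populations,
    )


# ---------------------------------------------------------------------------
# Bootstrap, knee, randomization, Y-scrambling


def _one_bootstrap(X, y, subset, algorithm, B, rng) -> float:
    """One leave-one-out bootstrap pass: out-of-bag error averaged per compound."""
    xs = X[list(subset)].to_numpy(dtype=float)
    y = np.asarray(y)
    n = len(y)
    err_sum = np.zeros(n)
    err_cnt = np.zeros(n)
    for _ in range(B):
        for _retry in range(100):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size == 0:
                continue
            if algorithm == "lda" and len(np.unique(y[idx])) < 2:
                logger.debug("bootstrap resample missing a class; redrawing")
                continue
            break
        else:
            raise RuntimeError("could not draw a valid bootstrap resample")
        if algorithm == "lda":
            model = fit_lda(xs[idx], y[idx])
            pred = model.predict(xs[oob])
            errs = (pred != y[oob]).astype(float)
        else:
            model = fit_ols(xs[idx], y[idx].astype(float))
            errs = np.abs(model.predict(xs[oob]) - y[oob].astype(float))
        err_sum[oob] += errs
        err_cnt[oob] += 1
    covered = err_cnt > 0
    return float(np.mean(err_sum[covered] / err_cnt[covered]))


def loo_bootstrap(
    X: pd.DataFrame,
    y,
    subset: Sequence[str],
    algorithm: str = "lda",
    B: int = 100,
    seed: int = 0,
    repeats: int = 5,
) -> tuple[float, float]:
    """Leave-one-out bootstrap error (MR for LDA, MAE for OLS).

    Each compound's error is averaged over the resamples in which it was
    out-of-bag; the estimate is the mean over compounds.  The whole procedure
    is repeated ``repeats`` times with derived seeds and the spread is the SD
    of the repeat estimates.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    rng = np.random.default_rng(seed)
    estimates = [
        _one_bootstrap(X, y, tuple(subset), algorithm, B, rng) for _ in range(repeats)
    ]
    spread = float(np.std(estimates, ddof=1)) if repeats > 1 else 0.0
    return float(np.mean(estimates)), spread


def overfit_knee(bootstrap_errors: dict[int, float], tol: float = 0.005) -> int:
    """Suggested model size: smallest k whose successor fails to improve the
    bootstrap error by more than ``tol`` (flattening or increase).  Advisory."""
    sizes = sorted(bootstrap_errors)
    for k in sizes[:-1]:
        if bootstrap_errors[k] - bootstrap_errors[k + 1] <= tol:
            return k
    return sizes[-1]


def _randomize_columns(X: pd.DataFrame, mode: str, rng) -> pd.DataFrame:
    out = {}
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if mode == "range":
            out[name] = rng.uniform(lo, hi, size=len(col))
        elif mode == "nature":
            uniq = np.unique(col)
            if uniq.size <= 2:
                # binary: Bernoulli at the observed frequency
                p1 = float(np.mean(col == uniq[-1]))
                out[name] = np.where(rng.random(len(col)) < p1, uniq[-1], uniq[0])
            elif np.allclose(col, np.round(col)):
                out[name] = rng.integers(int(lo), int(hi) + 1, size=len(col)).astype(float)
            else:
                out[name] = rng.uniform(lo, hi, size=len(col))
        else:
            raise ValueError(f"unknown randomization mode {mode!r}")
    return pd.DataFrame(out, index=X.index)


@dataclass
class RandomizationResult:
    empirical_fraction: float
    normal_tail_probability: float
    run_criteria: np.ndarray


def randomization_probability(
    X: pd.DataFrame,
    y,
    algorithm: str,
    subset_size: int,
    runs: int = 100,
    mode: str = "range",
    real_criterion: Optional[float] = None,
    seed: int = 0,
    beam: int = 25,
) -> RandomizationResult:
    """Probability of a coincidental descriptor/response relationship.

    The step-up selection is rerun ``runs`` times on descriptor columns
    randomized within their observed ranges (``mode='range'``) or respecting
    their detected nature — binary, integer, continuous (``mode='nature'``).
    Returns the empirical fraction of runs whose best criterion beats the real
    model's, and a tail probability from a normal fit to the run criteria
    (the headline number, resolving below 1/runs).
    """
    if runs < 10:
        raise ValueError("runs must be >= 10")
    if real_criterion is None:
        trace = step_up_select(X, y, algorithm, beam=beam, max_size=subset_size)
        real_criterion = trace.best(subset_size)[1]
    hib = _higher_is_better(algorithm)
    rng = np.random.default_rng(seed)
    crits = np.empty(runs)
    for r in range(runs):
        xr = _randomize_columns(X, mode, rng)
        trace = step_up_select(xr, y, algorithm, beam=beam, max_size=subset_size)
        crits[r] = trace.best(subset_size)[1]
    if hib:
        emp = float(np.mean(crits >= real_criterion))
    else:
        emp = float(np.mean(crits <= real_criterion))
    mu, sd = float(crits.mean()), float(crits.std(ddof=1))
    if sd == 0.0:
        tail = float(emp)
    else:
        z = (real_criterion - mu) / sd
        tail = float(stats.norm.sf(z)) if hib else float(stats.norm.cdf(z))
    return RandomizationResult(emp, tail, crits)


def y_scramble(
    X: pd.DataFrame, y, subset: Sequence[str], iters: int = 50, seed: int = 0
) -> float:
    """Mean training R^2 over ``iters`` random permutations of the response
    (descriptors fixed).  Values near zero indicate no chance correlation."""
    if iters < 2:
        raise ValueError("iters must be >= 2")
    xs = X[list(subset)]
    y = np.asarray(y, dtype=float)
    if len(y) == len(subset) + 1:
        logger.warning("n = p + 1: scrambled fits interpolate, R2_YS = 1")
    rng = np.random.default_rng(seed)
    r2s = []
    for _ in range(iters):
        yp = rng.permutation(y)
        model = fit_ols(xs, yp)
        r2s.append(r_squared(yp, model.predict(xs)))
    return float(np.mean(r2s))


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class ClassificationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    mr: float
    sn: float
    sp: float
    precision: float
    auc: Optional[float] = None
    roc: Optional[tuple[np.ndarray, np.ndarray]] = None


def auc_mann_whitney(truth, scores, positive: str = "A") -> float:
    """ROC AUC via the rank (Mann-Whitney) statistic; ties rank-averaged."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    pos = truth == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve_points(truth, scores, positive: str = "A") -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points over all score thresholds, for plotting."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    pos = (truth[order] == positive).astype(float)
    tpr = np.concatenate([[0.0], np.cumsum(pos) / max(pos.sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(1 - pos) / max((1 - pos).sum(), 1)])
    return fpr, tpr


def classification_metrics(
    truth, predictions, scores=None, positive: str = "A"
) -> ClassificationMetrics:
    """Confusion counts and ACC/MR/SN/SP/P (+AUC if posterior scores given).

    The active class is the positive one.  With a single-class truth SN or SP
    is undefined and reported as NaN with a warning.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if len(truth) != len(predictions):
        raise ValueError("truth and prediction lengths differ")
    pos_t = truth == positive
    pos_p = predictions == positive
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    n = len(truth)

    def _ratio(num, den, label):
        if den == 0:
            logger.warning("%s undefined (zero denominator); reported as NaN", label)
            return float("nan")
        return num / den

    return ClassificationMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        acc=(tp + tn) / n,
        mr=(fp + fn) / n,
        sn=_ratio(tp, tp + fn, "sensitivity"),
        sp=_ratio(tn, tn + fp, "specificity"),
        precision=_ratio(tp, tp + fp, "precision"),
        auc=None if scores is None else auc_mann_whitney(truth, scores, positive),
        roc=None if scores is None else roc_curve_points(truth, scores, positive),
    )


@dataclass
class RegressionMetrics:
    r2: float
    mae_train: float
    q2_loo: Optional[float] = None
    mae_test: Optional[float] = None
    q2_f3: Optional[float] = None
    r2_ys: Optional[float] = None


def q2_loo(X: pd.DataFrame, y) -> float:
    """Leave-one-out cross-validated R^2: each compound predicted by the
    model refit without it; Q2 = 1 - PRESS / TSS."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_ols(X.iloc[keep], y[keep])
        press += float((model.predict(X.iloc[[i]])[0] - y[i]) ** 2)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        logger.warning("zero response variance: Q2_LOO undefined, NaN")
        return float("nan")
    return 1.0 - press / tss


def q2_f3(y_train, y_test, yhat_test) -> float:
    """External predictivity Q2_F3 = 1 - [PRESS_test/n_test] / [TSS_train/n_train]."""
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    yhat_test = np.asarray(yhat_test, dtype=float)
    press = float(np.sum((y_test - yhat_test) ** 2)) / len(y_test)
    tss = float(np.sum((y_train - y_train.mean()) ** 2)) / len(y_train)
    if tss == 0.0:
        logger.warning("zero training variance: Q2_F3 undefined, NaN")
        return float("nan")
    return 1.0 - press / tss


def regression_metrics(
    X_train: pd.DataFrame,
    y_train,
    model: MLRModel,
    X_test: Optional[pd.DataFrame] = None,
    y_test=None,
    loo: bool = True,
) -> RegressionMetrics:
    """Training fit (R^2, MAE, Q2_LOO) and external (MAE, Q2_F3) metrics."""
    yhat = model.predict(X_train)
    out = RegressionMetrics(
        r2=r_squared(y_train, yhat),
        mae_train=mae(y_train, yhat),
        q2_loo=q2_loo(X_train[model.descriptor_names], y_train) if loo else None,
    )
    if X_test is not None and y_test is not None:
        yhat_t = model.predict(X_test)
        out.mae_test = mae(y_test, yhat_t)
        out.q2_f3 = q2_f3(y_train, y_test, yhat_t)
    return out
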