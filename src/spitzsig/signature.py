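"""Stability-LASSO signature discovery and per-sample malignancy scoring.

The procedure repeats {random stratified 10-fold CV split -> lambda with the
smallest held-out binomial deviance -> full-data refit at that lambda ->
record the nonzero genes and coefficients} many times; genes selected in at
least half the repetitions form the signature, and the coefficients averaged
over all repetitions are the signature weights.  Samples are scored by the
weighted sum of their normalized log2 expression over the signature genes,
min-max transformed to [0, 1], and called low/high at a fixed cut.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lasso import _cd_path_numba, _cd_path_python
from .exceptions import ParameterError
from .io_normalize import CountCohort, WeightedExpression

logger = logging.getLogger(__name__)

DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 0.01
CD_TOL = 1e-7
DEFAULT_SCORE_CUT = 0.4

_PROB_EPS = 1e-9


@dataclass
class LassoFit:
    """Regularization path (input-scale coefficients) plus optional CV results."""

    lambda_path: np.ndarray  # descending
    coef_path: np.ndarray  # genes x n_lambda, input scale
    intercept_path: np.ndarray
    feature_names: list[str]
    cv_dev: np.ndarray | None = None
    lambda_star: float | None = None
    lambda_star_index: int | None = None

    @property
    def cv_deviance(self) -> np.ndarray | None:
        return self.cv_dev


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ParameterError("X must be samples x genes and y one label per sample")
    if not np.all(np.isfinite(X)):
        raise ParameterError("X contains non-finite values")
    classes = np.unique(y)
    if classes.size != 2 or not np.all(np.isin(classes, (0.0, 1.0))):
        raise ParameterError("y must contain both classes, coded 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ParameterError("each class needs at least 2 samples")
    return X, y


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    xs = np.where(xs > 0, xs, 1.0)  # constant columns stay all-zero, coef 0
    return (X - xm) / xs, xm, xs


def lasso_logistic_path(
    X,
    y,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    family: str = "binomial",
    feature_names: list[str] | None = None,
    lambda_path: np.ndarray | None = None,
    debug: bool = False,
) -> LassoFit:
    """L1-penalized path by cyclic coordinate descent with warm starts.

    Columns are standardized internally; coefficients are reported on the
    input scale.  ``family="gaussian"`` switches to squared loss (used by the
    closed-form oracle checks).  ``debug=True`` runs the assertion-carrying
    reference implementation.
    """
    if family not in ("binomial", "gaussian"):
        raise ParameterError(f"unknown family {family!r}")
    if family == "binomial":
        X, y = _validate_xy(X, y)
    else:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    Xs, xm, xs = _standardize(X)

    if lambda_path is None:
        lambda_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
        lambda_max = max(lambda_max, 1e-10)
        if n_lambda < 1:
            raise ParameterError("n_lambda must be >= 1")
        lambdas = np.exp(
            np.linspace(
                np.log(lambda_max), np.log(lambda_max * lambda_min_ratio), n_lambda
            )
        )
    else:
        lambdas = np.asarray(lambda_path, dtype=float)
        if np.any(np.diff(lambdas) > 0):
            raise ParameterError("lambda_path must be non-increasing")

    kernel = _cd_path_python if debug else _cd_path_numba
    coefs_std, b0_std = kernel(
        np.asfortranarray(Xs), np.ascontiguousarray(y), lambdas, family == "gaussian", CD_TOL
    )
    coefs = coefs_std / xs[None, :]
    intercepts = b0_std - coefs @ xm
    return LassoFit(
        lambda_path=lambdas,
        coef_path=coefs.T.copy(),
        intercept_path=intercepts,
        feature_names=list(feature_names),
    )


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal shuffled class members round-robin into n_folds test sets."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, sample in enumerate(idx):
            folds[i % n_folds].append(int(sample))
    return [np.array(sorted(f), dtype=int) for f in folds]


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    """-2 * mean Bernoulli log-likelihood of labels under predicted probabilities."""
    prob = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(-2.0 * np.mean(y * np.log(prob) + (1.0 - y) * np.log(1.0 - prob)))


def cv_deviance(
    X, y, fit: LassoFit, n_folds: int = 10, seed: int = 0
) -> LassoFit:
    """Fill in the mean held-out binomial deviance per lambda and lambda_star.

    Folds are stratified by class; lambda_star is the grid value with the
    smallest mean deviance (ties resolved toward the larger lambda).
    """
    X, y = _validate_xy(X, y)
    n = y.size
    lambdas = fit.lambda_path
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        folds = _stratified_folds(y, n_folds, rng)
        ok = True
        for test_idx in folds:
            train = np.setdiff1d(np.arange(n), test_idx)
            if np.unique(y[train]).size < 2:
                ok = False
                break
        if ok:
            break
        logger.warning("single-class training fold; re-drawing the CV split")
    else:
        raise ParameterError("could not build two-class training folds")

    dev = np.zeros((len(folds), lambdas.size))
    for fi, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        sub = lasso_logistic_path(
            X[train], y[train], lambda_path=lambdas, feature_names=fit.feature_names
        )
        eta = sub.intercept_path[None, :] + X[test_idx] @ sub.coef_path
        prob = 1.0 / (1.0 + np.exp(-eta))
        prob = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
        yt = y[test_idx][:, None]
        dev[fi] = -2.0 * np.mean(yt * np.log(prob) + (1 - yt) * np.log(1 - prob), axis=0)
    cv_dev = dev.mean(axis=0)
    star = int(np.argmin(cv_dev))  # first minimum = largest lambda on a descending grid
    return LassoFit(
        lambda_path=lambdas,
        coef_path=fit.coef_path,
        intercept_path=fit.intercept_path,
        feature_names=fit.feature_names,
        cv_dev=cv_dev,
        lambda_star=float(lambdas[star]),
        lambda_star_index=star,
    )


@dataclass
class SignatureModel:
    """Selection frequencies and averaged coefficients from repeated CV-LASSO."""

    stats: pd.DataFrame  # index gene, columns: selection_count, mean_coef
    n_reps: int
    selection_threshold: int

    @property
    def signature_genes(self) -> list[str]:
        s = self.stats
        keep = (s["selection_count"] >= self.selection_threshold) & (
            s["mean_coef"] != 0.0
        )
        return list(s.index[keep])

    @property
    def weights(self) -> pd.Series:
        return self.stats.loc[self.signature_genes, "mean_coef"]


def _rep_seed(master_seed: int, rep: int) -> int:
    """Counter-derived per-repetition seed (any repetition is re-runnable alone)."""
    return int(np.random.SeedSequence([int(master_seed), int(rep)]).generate_state(1)[0])


def stability_select(
    X,
    y,
    n_reps: int = 500,
    threshold: int = 250,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = DEFAULT_N_LAMBDA,
    feature_names: list[str] | None = None,
    average_selected_only: bool = False,
) -> SignatureModel:
    """Repeat CV-split -> lambda_star -> full-data coefficients, n_reps times.

    ``mean_coef`` averages over all repetitions, zeros included (set
    ``average_selected_only`` to divide by the selection count instead).
    """
    if n_reps < threshold:
        raise ParameterError(f"n_reps ({n_reps}) must be >= threshold ({threshold})")
    X, y = _validate_xy(X, y)
    full = lasso_logistic_path(X, y, n_lambda=n_lambda, feature_names=feature_names)
    p = X.shape[1]
    counts = np.zeros(p, dtype=np.int64)
    coef_sum = np.zeros(p)
    for rep in range(n_reps):
        rep_fit = cv_deviance(X, y, full, n_folds=n_folds, seed=_rep_seed(seed, rep))
        coefs = full.coef_path[:, rep_fit.lambda_star_index]
        nz = coefs != 0.0
        counts += nz
        coef_sum += coefs
        logger.debug(
            "rep %d: lambda_star=%.4g, %d genes selected",
            rep,
            rep_fit.lambda_star,
            int(nz.sum()),
        )
    denom = np.where(counts > 0, counts, 1) if average_selected_only else n_reps
    mean_coef = coef_sum / denom
    stats = pd.DataFrame(
        {"selection_count": counts, "mean_coef": mean_coef},
        index=full.feature_names,
    )
    model = SignatureModel(stats=stats, n_reps=n_reps, selection_threshold=threshold)
    dropped = [
        g
        for g in stats.index[stats["selection_count"] >= threshold]
        if g not in model.signature_genes
    ]
    if dropped:
        warnings.warn(f"genes selected often but averaging to 0 dropped: {dropped}")
    return model


@dataclass
class ScoreTable:
    """Per-sample weighted-sum score, [0,1] transform and low/high call."""

    table: pd.DataFrame  # columns: group, raw_score, score01, call
    cut: float = DEFAULT_SCORE_CUT


def score_samples(
    model: SignatureModel,
    expr: WeightedExpression,
    cohort: CountCohort,
    cut: float = DEFAULT_SCORE_CUT,
) -> ScoreTable:
    """Weighted sum of normalized log2 expression over the signature genes.

    Scores are min-max transformed over the scored cohort; ``score01`` above
    the cut is called high (a score exactly at the cut is low).
    """
    genes = model.signature_genes
    if not genes:
        raise ParameterError("signature is empty; nothing to score")
    missing = [g for g in genes if g not in expr.logexp.index]
    if missing:
        raise ParameterError(f"signature gene(s) missing from expression: {missing}")
    weights = model.weights
    raw = weights.to_numpy() @ expr.logexp.loc[genes].to_numpy()
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        score01 = (raw - lo) / (hi - lo)
    else:
        warnings.warn("all raw scores identical; score01 set to 0")
        score01 = np.zeros_like(raw)
    call = np.where(score01 > cut, "high", "low")
    table = pd.DataFrame(
        {
            "group": cohort.group.reindex(expr.logexp.columns).to_numpy(),
            "raw_score": raw,
            "score01": score01,
            "call": call,
        },
        index=expr.logexp.columns,
    )
    return ScoreTable(table=table, cut=cut)
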