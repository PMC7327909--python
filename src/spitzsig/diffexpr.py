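"""Precision-weighted two-group contrasts with empirical-Bayes moderation.

Each contrast is a weighted least-squares fit of the normalized log2
expression on a two-group design (the two groups' samples only), followed by
shrinkage of the residual variances toward a scaled inverse-chi-square prior
fitted across genes by moment matching on the log variances.  The moderated
t gains the prior degrees of freedom; p-values are two-sided and q-values
are Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import InsufficientReplicationError, ParameterError
from .io_normalize import CountCohort, WeightedExpression

#: degrees of freedom used in place of an infinite prior
_MAX_DF = 1e9


@dataclass
class ContrastTable:
    """Per-gene results of one two-group moderated contrast."""

    table: pd.DataFrame  # columns: logFC, ave_expr, t_mod, p, q, df_total
    group1: str
    group2: str
    s2_prior: float
    df_prior: float
    df_residual: float

    def __len__(self) -> int:
        return len(self.table)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    Ties are handled by a stable sort on p (then input position).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p must be a non-empty 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Returns (s2_prior, df_prior); df_prior is inf when the observed spread of
    log variances is no larger than expected from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return float(np.mean(s2[ok])) if ok.any() else 1.0, np.inf
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = np.exp(
            emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        )
    else:
        df_prior = np.inf
        s2_prior = np.exp(emean)
    return float(s2_prior), float(df_prior)


def squeeze_var(s2: np.ndarray, df: float, s2_prior: float, df_prior: float) -> np.ndarray:
    """Posterior variances (df_prior*s2_prior + df*s2) / (df_prior + df)."""
    if np.isinf(df_prior):
        return np.full_like(np.asarray(s2, float), s2_prior)
    return (df_prior * s2_prior + df * s2) / (df_prior + df)


def fit_contrast(
    expr: WeightedExpression,
    cohort: CountCohort,
    group1: str,
    group2: str,
    df_prior_override: float | None = None,
) -> ContrastTable:
    """Moderated two-group contrast (group2 minus group1) on the two groups.

    ``df_prior_override=0`` disables moderation, reducing t_mod to the
    ordinary weighted two-sample t-statistic.
    """
    mask1 = (cohort.group == group1).to_numpy()
    mask2 = (cohort.group == group2).to_numpy()
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicationError(
            f"need >=2 samples per group, got {group1}:{n1}, {group2}:{n2}"
        )
    sel = mask1 | mask2
    y = expr.logexp.to_numpy()[:, sel]
    w = expr.weights.to_numpy()[:, sel]
    in2 = mask2[sel]

    w1, w2 = w[:, ~in2], w[:, in2]
    y1, y2 = y[:, ~in2], y[:, in2]
    sw1 = w1.sum(axis=1)
    sw2 = w2.sum(axis=1)
    m1 = (w1 * y1).sum(axis=1) / sw1
    m2 = (w2 * y2).sum(axis=1) / sw2
    logfc = m2 - m1
    ssr = (w1 * (y1 - m1[:, None]) ** 2).sum(axis=1) + (
        w2 * (y2 - m2[:, None]) ** 2
    ).sum(axis=1)
    df_res = float(n1 + n2 - 2)
    s2 = ssr / df_res
    stdev_unscaled = np.sqrt(1.0 / sw1 + 1.0 / sw2)

    if df_prior_override is not None:
        if df_prior_override < 0:
            raise ParameterError("df_prior_override must be >= 0")
        df_prior = float(df_prior_override)
        s2_prior = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
        s2_post = squeeze_var(s2, df_res, s2_prior, df_prior) if df_prior else s2
    else:
        s2_prior, df_prior = fit_f_dist(s2, df_res)
        s2_post = squeeze_var(s2, df_res, s2_prior, df_prior)

    df_total = df_res + min(df_prior, _MAX_DF)
    se = stdev_unscaled * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # keep zero-variance genes in the denominator with p = 1
    degenerate = (s2 <= 0) & (np.abs(logfc) < 1e-12)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = adjust_bh(p)
    ave = y.mean(axis=1)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "ave_expr": ave,
            "t_mod": t,
            "p": p,
            "q": q,
            "df_total": df_total,
        },
        index=expr.logexp.index,
    )
    return ContrastTable(
        table=table,
        group1=group1,
        group2=group2,
        s2_prior=s2_prior,
        df_prior=df_prior,
        df_residual=df_res,
    )


def significant_genes(
    table: ContrastTable, p_cut: float = 0.05, q_cut: float = 0.25
) -> tuple[list[str], int, int]:
    """Genes with p < p_cut and q <= q_cut; returns (genes, n_up, n_down)."""
    if len(table) == 0:
        raise ParameterError("contrast table is empty")
    t = table.table
    hit = t[(t["p"] < p_cut) & (t["q"] <= q_cut)]
    n_up = int((hit["logFC"] > 0).sum())
    n_down = int((hit["logFC"] < 0).sum())
    return list(hit.index), n_up, n_down


def scale_center(
    expr: WeightedExpression, genes: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Row-standardize (mean 0, sd 1); zero-variance rows become zeros, flagged."""
    mat = expr.logexp if genes is None else expr.logexp.loc[genes]
    arr = mat.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] <= 0
    sd[flat] = 1.0
    out = (arr - mean) / sd
    out[flat] = 0.0
    return (
        pd.DataFrame(out, index=mat.index, columns=mat.columns),
        list(mat.index[flat]),
    )
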