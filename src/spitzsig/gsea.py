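"""Competitive gene-set testing with inter-gene correlation correction.

Per-gene moderated t statistics are converted to normal-equivalent z scores;
each set is compared to the non-member genes with a two-sample t whose
member variance is inflated by VIF = 1 + (m - 1) * rho_bar, rho_bar being
the mean pairwise correlation of the member genes' residuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh, fit_contrast
from .exceptions import ParameterError
from .io_normalize import CountCohort, GeneSetCollection, WeightedExpression

#: keep the variance-inflation factor strictly positive
_RHO_EPS = 1e-6


def zscore_t(t: np.ndarray, df: np.ndarray | float) -> np.ndarray:
    """Normal-equivalent z for t statistics (tail-stable)."""
    t = np.asarray(t, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), t.shape)
    z = np.empty_like(t)
    neg = t <= 0
    with np.errstate(divide="ignore"):
        log_lower = stats.t.logcdf(t[neg], df[neg])
        log_upper = stats.t.logsf(t[~neg], df[~neg])
    z[neg] = _norm_quantile_from_logp(log_lower, lower=True)
    z[~neg] = _norm_quantile_from_logp(log_upper, lower=False)
    return z


def _norm_quantile_from_logp(logp: np.ndarray, lower: bool) -> np.ndarray:
    q = np.exp(logp)
    out = stats.norm.ppf(q) if lower else stats.norm.isf(q)
    # fall back to asymptotic tail for underflowed probabilities
    tiny = q <= 0
    if np.any(tiny):
        x = np.sqrt(-2.0 * logp[tiny] - np.log(-2.0 * logp[tiny]) - np.log(2.0 * np.pi))
        out[tiny] = -x if lower else x
    return out


def estimate_rho(residuals: np.ndarray) -> float:
    """Mean pairwise Pearson correlation of the rows (member-gene residuals)."""
    m = residuals.shape[0]
    if m < 2:
        return 0.0
    sd = residuals.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        return 0.0
    r = np.corrcoef(residuals[keep])
    idx = np.triu_indices_from(r, k=1)
    return float(np.mean(r[idx]))


def _camera_pvalue(
    z: np.ndarray, member: np.ndarray, rho_bar: float, df_camera: float
) -> tuple[float, float, str]:
    """Two-sample member vs non-member test with variance inflation.

    Returns (p, two_sample_t, direction).
    """
    g = z.size
    m = int(member.sum())
    m2 = g - m
    if m < 2 or m2 < 1:
        raise ParameterError("set must have >=2 members and >=1 non-member")
    rho_floor = -1.0 / (m - 1) + _RHO_EPS
    rho_bar = max(rho_bar, rho_floor)
    vif = 1.0 + (m - 1) * rho_bar
    mean_all = z.mean()
    var_all = z.var(ddof=1)
    mean_in = z[member].mean()
    delta = g / m2 * (mean_in - mean_all)  # = mean_in - mean_out
    var_pooled = ((g - 1) * var_all - delta**2 * m * m2 / g) / (g - 2)
    var_pooled = max(var_pooled, 1e-300)
    tstat = delta / np.sqrt(var_pooled * (vif / m + 1.0 / m2))
    p = 2.0 * stats.t.sf(abs(tstat), df_camera)
    direction = "Up" if delta >= 0 else "Down"
    return float(min(p, 1.0)), float(tstat), direction


def camera_test(
    expr: WeightedExpression,
    cohort: CountCohort,
    contrast: tuple[str, str],
    sets: GeneSetCollection,
    fixed_rho: float | None = None,
) -> pd.DataFrame:
    """Competitive enrichment of each gene set for one two-group contrast.

    Gene identifiers are matched case-insensitively; sets with fewer than two
    panel members are skipped with a warning.  ``fixed_rho`` bypasses the
    per-set residual-correlation estimate.
    """
    if len(sets) == 0:
        raise ParameterError("gene-set collection is empty")
    group1, group2 = contrast
    fit = fit_contrast(expr, cohort, group1, group2)
    t = fit.table["t_mod"].to_numpy()
    df_total = fit.table["df_total"].to_numpy()
    z = zscore_t(t, df_total)
    g = z.size

    gene_upper = pd.Index([str(s).upper() for s in expr.logexp.index])
    pos = {sym: i for i, sym in enumerate(gene_upper)}

    # residuals after removing the two groups' means (for rho estimation)
    sel = ((cohort.group == group1) | (cohort.group == group2)).to_numpy()
    y = expr.logexp.to_numpy()[:, sel]
    grp2 = (cohort.group == group2).to_numpy()[sel]
    resid = np.empty_like(y)
    resid[:, ~grp2] = y[:, ~grp2] - y[:, ~grp2].mean(axis=1, keepdims=True)
    resid[:, grp2] = y[:, grp2] - y[:, grp2].mean(axis=1, keepdims=True)

    df_camera = min(fit.df_residual, g - 2)
    rows = []
    for name, members in sets.sets.items():
        idx = sorted({pos[m.upper()] for m in members if m.upper() in pos})
        m = len(idx)
        if m < 2 or g - m < 1:
            warnings.warn(
                f"set {name!r} has {m} genes on the panel; skipped", stacklevel=2
            )
            continue
        member = np.zeros(g, dtype=bool)
        member[idx] = True
        rho = fixed_rho if fixed_rho is not None else estimate_rho(resid[idx])
        rho = max(rho, -1.0 / (m - 1) + _RHO_EPS)
        p, _, direction = _camera_pvalue(z, member, rho, df_camera)
        rows.append(
            {
                "set_name": name,
                "n_genes": m,
                "direction": direction,
                "rho_bar": rho,
                "vif": 1.0 + (m - 1) * rho,
                "p": max(p, np.finfo(float).tiny),
            }
        )
    if not rows:
        raise ParameterError("no gene set had >=2 members on the panel")
    out = pd.DataFrame(rows).set_index("set_name")
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out


def rank_pathways(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k sets by q (ties by p, then name), with -log10(q) attached."""
    if k <= 0:
        raise ParameterError("k must be positive")
    if len(results) == 0:
        raise ParameterError("results are empty")
    ranked = (
        results.reset_index()
        .sort_values(by=["q", "p", "set_name"], kind="stable")
        .head(k)
        .set_index("set_name")
    )
    ranked["neglog10_q"] = -np.log10(np.maximum(ranked["q"], 1e-300))
    return ranked
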