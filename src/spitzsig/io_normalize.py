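"""Input parsing, library-size normalization, precision weights and MDS.

The count matrix is genes x samples with integer entries.  Normalization is
log2-CPM against the per-sample total count (library size); precision weights
come from a lowess fit of the mean--sqrt-standard-deviation relationship of
the log-counts, evaluated at each observation's fitted count size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .exceptions import FormatError, ParameterError

logger = logging.getLogger(__name__)

GROUPS = ("SN", "AST", "MST")

#: log2-CPM pseudo-count offsets (counts, library size)
COUNT_OFFSET = 0.5
LIB_OFFSET = 1.0

#: lowess settings for the mean-variance trend
LOWESS_FRAC = 0.5
LOWESS_IT = 3

#: floor on the predicted sqrt-standard-deviation so weights stay finite
MIN_TREND_SD = 1e-2

#: number of top differing genes used per sample pair in MDS distances
MDS_TOP_GENES = 500


@dataclass
class CountCohort:
    """Raw counts plus gene roles and sample group labels.

    ``counts`` is genes x samples (integer), ``gene_role`` maps each gene id
    to ``endogenous`` or ``housekeeping`` and ``group`` maps each sample id
    to one of SN / AST / MST.  ``gene_truth`` optionally carries simulation
    ground truth (planted effects) and is ignored by the analysis stages.
    """

    counts: pd.DataFrame
    group: pd.Series
    gene_role: pd.Series
    gene_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene identifiers: {dups[:5]}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("count matrix contains non-numeric entries")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            g, s = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise FormatError(
                f"count for gene {counts.index[g]!r}, sample "
                f"{counts.columns[s]!r} is not a non-negative integer: {arr[g, s]!r}"
            )
        self.counts = counts.astype(np.int64)
        missing = counts.columns.difference(self.group.index)
        if len(missing):
            raise FormatError(f"samples without a group label: {list(missing)[:5]}")
        extra = self.group.index.difference(counts.columns)
        if len(extra):
            raise FormatError(f"sample sheet rows absent from counts: {list(extra)[:5]}")
        self.group = self.group.reindex(counts.columns)
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        self.gene_role = self.gene_role.reindex(counts.index).fillna("endogenous")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_size(self) -> pd.Series:
        """Per-sample total counts (always the live column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class WeightedExpression:
    """log2-scale normalized expression with per-observation precision weights."""

    logexp: pd.DataFrame
    weights: pd.DataFrame
    trend: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ParameterError("precision weights must be positive and finite")
        if not np.all(np.isfinite(self.logexp.to_numpy())):
            raise ParameterError("logexp must be finite everywhere")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 50 Hallmark collections)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = None
    df.columns.name = None
    return df


def read_counts(
    counts_path: str | Path,
    samples_path: str | Path,
    genes_path: str | Path | None = None,
) -> CountCohort:
    """Read a genes x samples count table plus its sample sheet.

    The sample sheet must label every sample in the counts header (and no
    others).  ``genes_path`` optionally supplies per-gene roles
    (endogenous / housekeeping) and ground-truth columns from the simulator.
    """
    counts_path = Path(counts_path)
    samples_path = Path(samples_path)
    counts = _read_table(counts_path)
    for col in counts.columns:
        if not pd.api.types.is_numeric_dtype(counts[col]):
            bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"non-numeric count for gene {gene!r}, sample {col!r} in {counts_path}"
            )
    sheet = _read_table(samples_path)
    if "group" not in sheet.columns:
        raise FormatError(f"sample sheet {samples_path} lacks a 'group' column")
    group = sheet["group"].astype(str)

    gene_role = pd.Series("endogenous", index=counts.index, name="role")
    gene_truth = None
    if genes_path is not None:
        genes = _read_table(Path(genes_path))
        if "role" in genes.columns:
            gene_role = genes["role"].astype(str)
        truth_cols = [c for c in genes.columns if c != "role"]
        if truth_cols:
            gene_truth = genes[truth_cols]
    cohort = CountCohort(counts=counts, group=group, gene_role=gene_role, gene_truth=gene_truth)
    logger.info(
        "read %d genes x %d samples from %s", cohort.n_genes, cohort.n_samples, counts_path
    )
    return cohort


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [f for f in fields[2:] if f]
            sets[name] = members
    if not sets:
        warnings.warn(f"GMT file {path} contains no gene sets", stacklevel=2)
    return GeneSetCollection(sets=sets, source=str(path))


def _group_design(group: pd.Series) -> np.ndarray:
    """One-hot group-means design matrix (samples x n_groups present)."""
    levels = [g for g in GROUPS if g in set(group)]
    if not levels:  # labels outside the standard trio: use observed levels
        levels = sorted(set(group))
    return np.column_stack([(group == g).to_numpy(float) for g in levels])


def _make_trend(x: np.ndarray, y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Lowess y~x, returned as a clamped linear interpolant."""
    fitted = sm_lowess(y, x, frac=LOWESS_FRAC, it=LOWESS_IT, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    # collapse duplicate abscissae for np.interp
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.zeros_like(ux)
    cnt = np.zeros_like(ux)
    np.add.at(uy, inv, ys)
    np.add.at(cnt, inv, 1.0)
    uy /= cnt
    uy = np.maximum(uy, MIN_TREND_SD)

    def trend(v: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(v, dtype=float), ux, uy)

    return trend


def normalize_voom(cohort: CountCohort) -> WeightedExpression:
    """Library-size log2-CPM with lowess mean-variance precision weights.

    logexp[g, j] = log2((counts[g, j] + 0.5) / (lib[j] + 1) * 1e6).  Residual
    standard deviations from a group-means fit are lowess-smoothed against
    average log2 count size; the inverse fourth power of the predicted
    sqrt-sd at each observation's fitted count size is its weight.
    """
    if cohort.n_samples < 2:
        raise ParameterError("normalization requires at least 2 samples")
    lib = cohort.library_size.to_numpy(dtype=float)
    if np.any(lib <= 0):
        bad = cohort.sample_ids[lib <= 0][0]
        raise ParameterError(f"sample {bad!r} has zero total counts")

    counts = cohort.counts.to_numpy(dtype=float)
    logcpm = np.log2((counts + COUNT_OFFSET) / (lib + LIB_OFFSET) * 1e6)

    design = _group_design(cohort.group)
    # per-gene weighted-free least squares on the group-means design
    nsamp = counts.shape[1]
    dof = nsamp - design.shape[1]
    # group means: counts projected on one-hot design
    gsize = design.sum(axis=0)
    group_means = (logcpm @ design) / gsize  # genes x n_groups
    fitted = group_means @ design.T
    resid = logcpm - fitted
    if dof > 0:
        sigma = np.sqrt((resid**2).sum(axis=1) / dof)
    else:
        sigma = np.zeros(counts.shape[0])

    # mean log2 count size per gene (shift log-CPM back to the count scale)
    mean_lib_term = np.mean(np.log2(lib + LIB_OFFSET))
    sx = logcpm.mean(axis=1) + mean_lib_term - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = _make_trend(sx, sy)

    # each observation's fitted log2 count size
    fitted_logcount = fitted + (np.log2(lib + LIB_OFFSET) - np.log2(1e6))[None, :]
    pred_sd = trend(fitted_logcount)
    weights = 1.0 / pred_sd**4

    return WeightedExpression(
        logexp=pd.DataFrame(logcpm, index=cohort.gene_ids, columns=cohort.sample_ids),
        weights=pd.DataFrame(weights, index=cohort.gene_ids, columns=cohort.sample_ids),
        trend=trend,
    )


def _pairwise_distances(logexp: np.ndarray, top: int) -> np.ndarray:
    n = logexp.shape[1]
    ngenes = logexp.shape[0]
    k = min(top, ngenes)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = (logexp[:, i] - logexp[:, j]) ** 2
            if k < ngenes:
                d2 = np.partition(d2, ngenes - k)[ngenes - k :]
            dist[i, j] = dist[j, i] = np.sqrt(d2.mean())
    return dist


def mds_coordinates(expr: WeightedExpression, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of pairwise sample distances.

    The distance between two samples is the root-mean-square log2 difference
    over their top ``MDS_TOP_GENES`` most different genes (all genes if the
    panel is smaller).
    """
    n = expr.logexp.shape[1]
    if k >= n:
        raise ParameterError(f"k={k} must be < number of samples ({n})")
    if k < 1:
        raise ParameterError("k must be >= 1")
    dist = _pairwise_distances(expr.logexp.to_numpy(), MDS_TOP_GENES)
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.maximum(evals[order], 0.0)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    # deterministic sign: largest-magnitude loading positive per axis
    for a in range(k):
        col = coords[:, a]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    return pd.DataFrame(
        coords, index=expr.logexp.columns, columns=[f"dim{i + 1}" for i in range(k)]
    )
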