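"""Negative-binomial synthetic cohorts with planted effects.

Generates NanoString-like count matrices (three groups, log-normal library
sizes, NB gene counts with variance mu + phi*mu^2) carrying known
ground truth: a block of two-group differentially expressed genes and a
block of signature genes whose group means are ordered across SN, AST, MST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io_normalize import CountCohort, read_counts


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated cohort; defaults mirror the study design."""

    n_per_group: tuple[int, int, int] = (27, 10, 14)
    n_genes: int = 770
    n_housekeeping: int = 40
    n_de_genes: int = 40
    de_logfc: float = 1.0
    n_signature_genes: int = 6
    signature_step: float = 1.0
    nb_dispersion: float = 0.1
    libsize_log_mean: float = math.log(292_412.0)  # median total ~= 3e5
    libsize_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 0 for n in self.n_per_group):
            raise ParameterError("n_per_group must be three non-negative counts")
        if sum(self.n_per_group) < 2:
            raise ParameterError("cohort needs at least 2 samples")
        for name in ("n_genes", "n_housekeeping", "n_de_genes", "n_signature_genes"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        if self.n_housekeeping + self.n_de_genes + self.n_signature_genes > self.n_genes:
            raise ParameterError(
                "n_housekeeping + n_de_genes + n_signature_genes exceeds n_genes"
            )
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if self.libsize_log_sd < 0:
            raise ParameterError("libsize_log_sd must be >= 0")


def generate_cohort(config: SyntheticConfig) -> CountCohort:
    """Simulate a cohort with planted DE and signature genes.

    DE genes shift the MST mean by ``de_logfc`` log2 units relative to
    SN/AST, with alternating sign across the planted genes.  Signature genes
    step their mean by ``signature_step`` per class along SN -> AST -> MST,
    again with alternating sign, so both coefficient signs are exercised and
    the AST group sits between SN and MST by construction.  Ground truth is
    attached as ``cohort.gene_truth``.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    n_sn, n_ast, n_mst = config.n_per_group
    n = n_sn + n_ast + n_mst

    sample_ids = (
        [f"SN{i + 1}" for i in range(n_sn)]
        + [f"AST{i + 1}" for i in range(n_ast)]
        + [f"MST{i + 1}" for i in range(n_mst)]
    )
    group = pd.Series(
        ["SN"] * n_sn + ["AST"] * n_ast + ["MST"] * n_mst, index=sample_ids, name="group"
    )
    class_idx = np.repeat([0, 1, 2], [n_sn, n_ast, n_mst])  # SN=0, AST=1, MST=2

    gene_ids = [f"G{i + 1:04d}" for i in range(g)]
    perm = rng.permutation(g)
    hk_idx = perm[: config.n_housekeeping]
    de_idx = perm[config.n_housekeeping : config.n_housekeeping + config.n_de_genes]
    sig_lo = config.n_housekeeping + config.n_de_genes
    sig_idx = perm[sig_lo : sig_lo + config.n_signature_genes]

    role = np.full(g, "endogenous", dtype=object)
    role[hk_idx] = "housekeeping"

    # relative abundances: log-normal across genes, normalized to sum 1
    abund = rng.lognormal(mean=0.0, sigma=1.2, size=g)
    abund /= abund.sum()

    # per-gene, per-class log2 effects
    effect = np.zeros((g, 3))
    de_sign = np.where(np.arange(config.n_de_genes) % 2 == 0, 1.0, -1.0)
    effect[de_idx, 2] = de_sign * config.de_logfc
    sig_sign = np.where(np.arange(config.n_signature_genes) % 2 == 0, 1.0, -1.0)
    for step, cls in ((1.0, 1), (2.0, 2)):
        effect[sig_idx, cls] = sig_sign * config.signature_step * step

    libsize = np.exp(
        rng.normal(config.libsize_log_mean, config.libsize_log_sd, size=n)
    )
    mu = abund[:, None] * np.exp2(effect[:, class_idx]) * libsize[None, :]
    mu = np.maximum(mu, 1e-12)

    # NB(mean mu, variance mu + phi*mu^2): size r = 1/phi, p = r/(r+mu)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    true_logfc = np.zeros(g)  # MST vs SN, log2
    true_logfc[de_idx] = de_sign * config.de_logfc
    true_logfc[sig_idx] = sig_sign * config.signature_step * 2.0
    is_de = np.zeros(g, bool)
    is_de[de_idx] = True
    is_sig = np.zeros(g, bool)
    is_sig[sig_idx] = True
    truth = pd.DataFrame(
        {"is_de": is_de, "is_signature": is_sig, "true_logfc_mst_vs_sn": true_logfc},
        index=gene_ids,
    )

    return CountCohort(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        group=group,
        gene_role=pd.Series(role, index=gene_ids, name="role"),
        gene_truth=truth,
    )


def write_fixture(cohort: CountCohort, directory: str | Path) -> dict[str, Path]:
    """Write counts.tsv / samples.tsv / genes.tsv; round-trips via read_counts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "genes": directory / "genes.tsv",
    }
    cohort.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    cohort.group.rename_axis("sample_id").to_frame().to_csv(paths["samples"], sep="\t")
    genes = cohort.gene_role.rename_axis("gene_id").to_frame()
    if cohort.gene_truth is not None:
        genes = genes.join(cohort.gene_truth)
    genes.to_csv(paths["genes"], sep="\t")
    return paths


def read_fixture(directory: str | Path) -> CountCohort:
    """Inverse of :func:`write_fixture`."""
    directory = Path(directory)
    return read_counts(
        directory / "counts.tsv", directory / "samples.tsv", directory / "genes.tsv"
    )
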