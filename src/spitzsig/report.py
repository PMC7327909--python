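"""Pipeline orchestration: normalize -> DE contrasts -> GSEA -> signature -> scores.

Every artifact is a TSV written with fixed float formatting so a rerun with
the same config and seed is bit-identical; a manifest records input/output
hashes, the master seed and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import fit_contrast, significant_genes, scale_center
from .exceptions import ParameterError, PipelineStageError
from .gsea import camera_test, rank_pathways
from .io_normalize import mds_coordinates, normalize_voom, read_counts, read_gmt
from .signature import ScoreTable, score_samples, stability_select

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

DEFAULT_CONTRASTS = [("SN", "MST"), ("SN", "AST"), ("AST", "MST")]


@dataclass
class PipelineConfig:
    counts: str
    samples: str
    outdir: str
    genes: str | None = None
    gmt: str | None = None
    p_cut: float = 0.05
    q_cut: float = 0.25
    gsea_q: float = 0.05
    score_cut: float = 0.4
    reps: int = 500
    threshold: int = 250
    folds: int = 10
    n_lambda: int = 100
    seed: int = 0
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_CONTRASTS]
    )
    train_contrast: tuple[str, str] = ("SN", "MST")

    def __post_init__(self) -> None:
        for name in ("p_cut", "q_cut", "gsea_q", "score_cut"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if self.reps < self.threshold:
            raise ParameterError("reps must be >= threshold")
        for name in ("counts", "samples"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ParameterError(f"{name} file not found: {path}")
        self.contrasts = [tuple(c) for c in self.contrasts]
        self.train_contrast = tuple(self.train_contrast)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "id") -> Path:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)
    return path


def summarize_scores(scores: ScoreTable) -> pd.DataFrame:
    """Per-group mean/min/max of score01 plus low/high counts at the cut."""
    t = scores.table
    if t.empty:
        raise ParameterError("score table is empty")
    rows = []
    for group, sub in t.groupby("group", sort=False):
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "mean": sub["score01"].mean(),
                "min": sub["score01"].min(),
                "max": sub["score01"].max(),
                "n_low": int((sub["call"] == "low").sum()),
                "n_high": int((sub["call"] == "high").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write artifacts plus a manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    report: dict = {"seed": config.seed, "version": __version__, "contrasts": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage("read")
        cohort = read_counts(config.counts, config.samples, config.genes)
    except Exception as exc:
        raise PipelineStageError("read", str(exc)) from exc

    try:
        stage("normalize")
        expr = normalize_voom(cohort)
        outputs["normalized"] = _write_tsv(expr.logexp, outdir / "normalized.tsv", "gene_id")
        outputs["weights"] = _write_tsv(expr.weights, outdir / "weights.tsv", "gene_id")
        k = min(2, cohort.n_samples - 1)
        mds = mds_coordinates(expr, k=k)
        outputs["mds"] = _write_tsv(mds, outdir / "mds.tsv", "sample_id")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("normalize", str(exc)) from exc

    sets = None
    if config.gmt is not None:
        try:
            stage("gsea-input")
            sets = read_gmt(config.gmt)
        except Exception as exc:
            raise PipelineStageError("gsea", str(exc)) from exc

    for g1, g2 in config.contrasts:
        key = f"{g1}_vs_{g2}"
        try:
            stage(f"de:{key}")
            fit = fit_contrast(expr, cohort, g1, g2)
            genes, n_up, n_down = significant_genes(fit, config.p_cut, config.q_cut)
            tab = fit.table.copy()
            tab["significant"] = tab.index.isin(genes)
            outputs[f"de_{key}"] = _write_tsv(tab, outdir / f"de_{key}.tsv", "gene_id")
            volcano = pd.DataFrame(
                {
                    "logFC": tab["logFC"],
                    "neglog10_p": -np.log10(tab["p"]),
                    "significant": tab["significant"],
                }
            )
            outputs[f"volcano_{key}"] = _write_tsv(
                volcano, outdir / f"volcano_{key}.tsv", "gene_id"
            )
            report["contrasts"][key] = {
                "n_significant": len(genes),
                "n_up": n_up,
                "n_down": n_down,
                "s2_prior": fit.s2_prior,
                "df_prior": fit.df_prior,
            }
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(f"de:{key}", str(exc)) from exc

        if sets is not None:
            try:
                stage(f"gsea:{key}")
                res = camera_test(expr, cohort, (g1, g2), sets)
                outputs[f"gsea_{key}"] = _write_tsv(
                    res, outdir / f"gsea_{key}.tsv", "set_name"
                )
                top = rank_pathways(res, k=10)
                outputs[f"gsea_top_{key}"] = _write_tsv(
                    top, outdir / f"gsea_top_{key}.tsv", "set_name"
                )
                report["contrasts"][key]["n_gsea_significant"] = int(
                    (res["q"] <= config.gsea_q).sum()
                )
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(f"gsea:{key}", str(exc)) from exc

    try:
        stage("signature")
        g1, g2 = config.train_contrast
        mask = cohort.group.isin([g1, g2]).to_numpy()
        X = expr.logexp.to_numpy().T[mask]
        y = (cohort.group[mask] == g2).to_numpy(float)
        model = stability_select(
            X,
            y,
            n_reps=config.reps,
            threshold=config.threshold,
            n_folds=config.folds,
            seed=config.seed,
            n_lambda=config.n_lambda,
            feature_names=list(expr.logexp.index),
        )
        outputs["signature"] = _write_tsv(model.stats, outdir / "signature.tsv", "gene_id")
        scores = score_samples(model, expr, cohort, cut=config.score_cut)
        outputs["scores"] = _write_tsv(scores.table, outdir / "scores.tsv", "sample_id")
        summary = summarize_scores(scores)
        outputs["score_summary"] = _write_tsv(
            summary, outdir / "score_summary.tsv", "group"
        )
        if model.signature_genes:
            heat, _flagged = scale_center(expr, model.signature_genes)
            outputs["signature_heatmap"] = _write_tsv(
                heat, outdir / "signature_heatmap.tsv", "gene_id"
            )
        report["signature"] = {
            "genes": model.signature_genes,
            "weights": {g: float(w) for g, w in model.weights.items()},
            "score_summary": summary.to_dict(orient="index"),
        }
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("signature", str(exc)) from exc

    inputs = {"counts": config.counts, "samples": config.samples}
    if config.genes:
        inputs["genes"] = config.genes
    if config.gmt:
        inputs["gmt"] = config.gmt
    manifest = {
        "seed": config.seed,
        "version": __version__,
        "inputs": {k: _sha256(Path(v)) for k, v in inputs.items()},
        "outputs": {k: _sha256(p) for k, p in sorted(outputs.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
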