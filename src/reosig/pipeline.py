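"""End-to-end discovery and evaluation workflow.

``discover`` runs the whole training path on in-memory objects:
stable-pair detection per phenotype group, reversal-pair intersection,
ternary encoding, mRMR ranking, IFS prefix selection, and a final SVM fit
on all training samples with the selected signature. ``evaluate`` applies
a fitted signature model to a new matrix (genes absent from the matrix
encode -1, so prediction always proceeds) and reports metrics when labels
are supplied.

``run_discovery`` / ``run_evaluate`` are the file-based entry points used
by the CLI: they read the TSV inputs, write every intermediate artifact
under an output directory, and record a manifest (config, seed, versions,
stage counts) that makes any reported number reproducible from config +
seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .features import IFSResult, RankedFeatures, ifs_select, mrmr_rank
from .io import (
    ExpressionMatrix,
    SampleLabels,
    read_expression,
    read_labels,
    write_labels,
)
from .metrics import MetricsReport, compute_metrics, confusion, micro_average, roc_auc
from .reo import REOPairSet, REOProfile, encode_profile, find_reversal_pairs, find_stable_pairs
from .svm import SignatureModel, SvmConfig, grid_search, predict, train

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see the CLI)."""

    train_matrix: str
    train_labels: str
    out_dir: str
    threshold: float = 0.95
    ifs_folds: int = 5
    ifs_step: int = 1
    seed: int = 0
    svm_C: float | None = 0.125
    svm_gamma: float | None = 0.5
    grid_search: bool = False
    dialect: str = "tsv"

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0.5, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class DiscoveryResult:
    stable_pos: REOPairSet
    stable_neg: REOPairSet
    reversal: REOPairSet
    profile: REOProfile
    ranked: RankedFeatures
    ifs: IFSResult
    model: SignatureModel
    train_metrics: MetricsReport


def discover(
    m: ExpressionMatrix,
    labels: SampleLabels,
    threshold: float = 0.95,
    ifs_folds: int = 5,
    ifs_step: int = 1,
    seed: int = 0,
    svm_cfg: SvmConfig | None = None,
    use_grid_search: bool = False,
) -> DiscoveryResult:
    """Full signature discovery on one training cohort.

    Raises with stage context when a stage produces nothing to continue
    with (e.g. no reversal pairs at the requested stability threshold).
    """
    aligned = labels.subset(m.sample_ids)
    if aligned.n_pos == 0 or aligned.n_neg == 0:
        raise ValueError("training requires samples from both classes")
    pos_ids = [s for s, l in zip(aligned.sample_ids, aligned.labels) if l]
    neg_ids = [s for s, l in zip(aligned.sample_ids, aligned.labels) if not l]
    m_pos = _subset_samples(m, pos_ids)
    m_neg = _subset_samples(m, neg_ids)

    stable_pos = find_stable_pairs(m_pos, threshold=threshold)
    logger.info("stage=stable_pairs group=positive n=%d", len(stable_pos))
    stable_neg = find_stable_pairs(m_neg, threshold=threshold)
    logger.info("stage=stable_pairs group=negative n=%d", len(stable_neg))
    reversal = find_reversal_pairs(stable_pos, stable_neg)
    logger.info("stage=reversal_pairs n=%d", len(reversal))
    if len(reversal) == 0:
        raise RuntimeError(
            f"no reversal pairs at stability threshold {threshold}; "
            "lower the threshold or provide more consistent data"
        )
    profile = encode_profile(m, reversal)
    ranked = mrmr_rank(profile, aligned)
    logger.info("stage=mrmr n_ranked=%d", len(ranked))

    if use_grid_search:
        svm_cfg = grid_search(
            profile.restrict(ranked.pair_ids), aligned, folds=ifs_folds, seed=seed
        )
        logger.info("stage=grid_search C=%g gamma=%g", svm_cfg.C, svm_cfg.gamma)
    svm_cfg = svm_cfg or SvmConfig()

    ifs = ifs_select(
        ranked, profile, aligned, folds=ifs_folds, step=ifs_step, seed=seed, cfg=svm_cfg
    )
    logger.info(
        "stage=ifs chosen_k=%d peak_cv_accuracy=%.4f", ifs.chosen_k, ifs.peak_accuracy
    )
    model = train(profile.restrict(ifs.signature), aligned, svm_cfg)
    pred, scores = predict(model, profile)
    report = compute_metrics(confusion(pred, aligned))
    _, report.auc = roc_auc(scores, aligned.subset(pred.sample_ids))
    return DiscoveryResult(
        stable_pos=stable_pos,
        stable_neg=stable_neg,
        reversal=reversal,
        profile=profile,
        ranked=ranked,
        ifs=ifs,
        model=model,
        train_metrics=report,
    )


def evaluate(
    model: SignatureModel,
    m: ExpressionMatrix,
    labels: SampleLabels | None = None,
) -> tuple[SampleLabels, np.ndarray, MetricsReport | None]:
    """Apply a fitted signature model to a new expression matrix.

    The matrix is encoded against the model's signature; pairs whose genes
    are absent encode -1 everywhere (prediction still proceeds, with an
    error only if none of the signature's genes is present). Returns
    predictions, decision scores, and a metrics report when labels are
    given.
    """
    sig_genes = {g for pid in model.signature for g in pid.split("|")}
    present = sig_genes & set(m.gene_ids)
    if not present:
        raise ValueError("none of the signature's genes are present in the matrix")
    profile = _encode_signature(m, model.signature)
    pred, scores = predict(model, profile)
    report = None
    if labels is not None:
        truth = labels.subset(pred.sample_ids)
        report = compute_metrics(confusion(pred, truth))
        if truth.n_pos > 0 and truth.n_neg > 0:
            _, report.auc = roc_auc(scores, truth)
    return pred, scores, report


def _encode_signature(m: ExpressionMatrix, signature: list[str]) -> REOProfile:
    """Ternary-encode a matrix directly against oriented pair-id strings."""
    idx = m.gene_index()
    out = np.empty((len(signature), m.n_samples), dtype=np.int8)
    for r, pid in enumerate(signature):
        a, b = pid.split("|")
        ia, ib = idx.get(a), idx.get(b)
        if ia is None or ib is None:
            out[r] = -1
            continue
        va, vb = m.values[ia], m.values[ib]
        miss = np.isnan(va) | np.isnan(vb)
        with np.errstate(invalid="ignore"):
            gt = va > vb
        row = np.zeros(m.n_samples, dtype=np.int8)
        row[gt] = 1
        row[miss] = -1
        out[r] = row
    return REOProfile(list(signature), list(m.sample_ids), out)


def pool_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Micro-average several evaluation reports (summed confusion counts)."""
    return micro_average([r.counts for r in reports])


def run_discovery(cfg: PipelineConfig) -> DiscoveryResult:
    """File-based discovery: read inputs, run, write artifacts + manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = read_expression(cfg.train_matrix, dialect=cfg.dialect)
    labels = read_labels(cfg.train_labels)
    svm_cfg = None
    if cfg.svm_C is not None and cfg.svm_gamma is not None:
        svm_cfg = SvmConfig(C=cfg.svm_C, gamma=cfg.svm_gamma)
    res = discover(
        m,
        labels,
        threshold=cfg.threshold,
        ifs_folds=cfg.ifs_folds,
        ifs_step=cfg.ifs_step,
        seed=cfg.seed,
        svm_cfg=svm_cfg,
        use_grid_search=cfg.grid_search,
    )
    res.stable_pos.write_tsv(out / "stable_pairs_pos.tsv")
    res.stable_neg.write_tsv(out / "stable_pairs_neg.tsv")
    res.reversal.write_tsv(out / "reversal_pairs.tsv")
    res.profile.write_tsv(out / "reo_profile.tsv")
    res.ranked.write_tsv(out / "mrmr_ranking.tsv")
    res.ifs.write_tsv(out / "ifs_curve.tsv")
    res.ifs.plot(out / "ifs_curve.png")
    res.model.save(out / "model.json")
    res.train_metrics.save(out / "train_metrics.json")
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "versions": {"reosig": __version__, "python": platform.python_version()},
        "counts": {
            "stable_pairs_pos": len(res.stable_pos),
            "stable_pairs_neg": len(res.stable_neg),
            "reversal_pairs": len(res.reversal),
            "signature_size": len(res.ifs.signature),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return res


def run_evaluate(
    model_path: str | Path,
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    out_dir: str | Path | None = None,
    dialect: str = "tsv",
) -> tuple[SampleLabels, np.ndarray, MetricsReport | None]:
    """File-based evaluation of a saved model on a new matrix."""
    model = SignatureModel.load(model_path)
    m = read_expression(matrix_path, dialect=dialect)
    labels = read_labels(labels_path) if labels_path else None
    pred, scores, report = evaluate(model, m, labels)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(
            {
                "sample_id": pred.sample_ids,
                "predicted_label": pred.as_names(),
                "decision_score": scores,
            }
        ).to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.10g")
        if report is not None:
            report.save(out / "metrics.json")
            if report.auc is not None:
                truth = labels.subset(pred.sample_ids)
                points, _ = roc_auc(scores, truth)
                points.to_csv(out / "roc_points.tsv", sep="\t", index=False,
                              float_format="%.10g")
    return pred, scores, report


def _subset_samples(m: ExpressionMatrix, sample_ids: list[str]) -> ExpressionMatrix:
    idx = {s: j for j, s in enumerate(m.sample_ids)}
    cols = [idx[s] for s in sample_ids]
    return ExpressionMatrix(list(m.gene_ids), list(sample_ids), m.values[:, cols])
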