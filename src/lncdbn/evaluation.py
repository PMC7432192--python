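"""Negative sampling, per-cancer cross-validation, AUC/AUPR, and reporting.

Only positive lncRNA-cancer associations are recorded, so each per-cancer
binary problem is completed by sampling presumed negatives uniformly from the
lncRNAs not known to be associated with that cancer (1:1 by default).
Each cancer is then evaluated by stratified k-fold cross-validation: train on
k-1 folds of positives + sampled negatives, score the held-out fold, and
compute AUC (Mann-Whitney concordance, ties half-credited) and AUPR (step
precision-recall curve, no interpolation) from held-out scores only.

Summaries come in two labelled flavours that are never substituted for one
another: ``pooled`` (metrics on the concatenation of held-out scores) and
``macro`` (mean of per-cancer metrics). All randomness fans out from one
experiment seed via :func:`lncdbn._seeds.derive_seed`, so the three methods
consume byte-identical folds and negatives and any sub-result can be
reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from ._seeds import derive_seed
from . import cnn as cnn_mod
from . import dbn as dbn_mod
from .baselines import fit_pca, pca_encode
from .data_io import StudyDataset, write_predictions
from .features import build_raw_features, select_frequent_genes

logger = logging.getLogger(__name__)

METHODS = ("dbn-cnn", "pca-cnn", "dbn-dnn")


class MetricError(ValueError):
    pass


class SamplingError(ValueError):
    pass


class SplitError(ValueError):
    pass


@dataclass
class CVSpec:
    """Cross-validation and negative-sampling settings."""

    k: int = 10
    stratified: bool = True
    experiment_seed: int = 0
    negative_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be positive")


@dataclass
class PipelineConfig:
    """Feature, encoder and classifier settings shared by all methods."""

    panel_threshold: int = 5
    scaling: str = "minmax_per_tissue"
    dbn_layer_sizes: tuple[int, ...] = (32, 13)
    dbn_learning_rate: float = 0.1
    dbn_epochs: int = 100
    dbn_cd_steps: int = 1
    dbn_batch_size: int = 16
    dbn_per_fold: bool = False
    clf_optimizer: str = "adam"
    clf_learning_rate: float = 1e-3
    clf_epochs: int = 200
    clf_batch_size: int | None = None
    dnn_hidden_sizes: tuple[int, ...] = (64, 32)
    pca_components: int = 13
    pca_global: bool = False


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability a uniformly random positive outscores a uniformly
    random negative, with tied scores counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("roc_auc needs both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve.

    Thresholds sweep the distinct scores in descending order with ties
    grouped; the area is sum over thresholds of (recall step) x precision,
    with no interpolation of precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise MetricError("pr_auc needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where a tie group of scores ends
    distinct = np.nonzero(np.diff(s))[0]
    ends = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[ends].astype(float)
    n_at = (ends + 1).astype(float)
    recall = tp / n_pos
    precision = tp / n_at
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(threshold, fpr, tpr) along the descending-score sweep, ties grouped."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    ends = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[ends].astype(float)
    fp = (ends + 1) - tp
    n_pos = max(labels.sum(), 1)
    n_neg = max((1 - labels).sum(), 1)
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[ends]],
            "fpr": np.r_[0.0, fp / n_neg],
            "tpr": np.r_[0.0, tp / n_pos],
        }
    )


def pr_curve_points(scores, labels) -> pd.DataFrame:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    ends = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[ends].astype(float)
    n_at = (ends + 1).astype(float)
    n_pos = max(labels.sum(), 1)
    return pd.DataFrame(
        {
            "threshold": s[ends],
            "recall": tp / n_pos,
            "precision": tp / n_at,
        }
    )


# ---------------------------------------------------------------------------
# negative sampling and fold splitting
# ---------------------------------------------------------------------------

def sample_negatives(
    dataset: StudyDataset, cancer: str, ratio: float, seed: int
) -> list[str]:
    """Uniform sample (without replacement) of presumed-negative lncRNAs.

    Candidates are every dataset lncRNA not known-associated with this
    cancer — including positives of other cancers, matching the per-cancer
    one-vs-rest framing. Sample size is round(ratio x positives).
    """
    positives = dataset.associations[cancer]
    candidates = sorted(set(dataset.lncrna_ids) - positives)
    size = int(round(ratio * len(positives)))
    if size > len(candidates):
        raise SamplingError(
            f"need {size} negatives for {cancer!r} but only "
            f"{len(candidates)} non-associated lncRNAs available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=size, replace=False)
    return sorted(candidates[i] for i in chosen)


def kfold_split(
    ids: Sequence[str],
    labels: Sequence[int],
    spec: CVSpec,
    seed: int | None = None,
) -> np.ndarray:
    """Assign each sample to one of k test folds (stratified by default)."""
    labels = np.asarray(labels).astype(int)
    n = len(ids)
    if n < spec.k:
        raise SplitError(f"cannot split {n} samples into {spec.k} folds")
    seed = spec.experiment_seed if seed is None else seed
    if spec.stratified:
        counts = np.bincount(labels, minlength=2)
        if counts.min() < spec.k:
            raise SplitError(
                f"stratified split needs >= {spec.k} samples per class, "
                f"got {counts.tolist()}"
            )
        splitter = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=spec.k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
        assignment[test_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# shared feature context
# ---------------------------------------------------------------------------

@dataclass
class FeatureContext:
    """Features computed once per dataset and shared across cancers/methods.

    The gene panel and the DBN are fit once on the full dataset (the DBN is
    unsupervised, and the panel mirrors the global 45-gene selection); the
    per-training-fold alternatives are available via
    ``PipelineConfig.dbn_per_fold`` / absence of ``pca_global``.
    """

    ids: list[str]
    id_to_row: dict[str, int]
    gene_matrix: np.ndarray
    expr_matrix: np.ndarray
    panel_size: int
    dbn_model: dbn_mod.DBNModel | None = None
    dbn_codes: np.ndarray | None = None


def build_feature_context(
    dataset: StudyDataset,
    config: PipelineConfig,
    experiment_seed: int,
    need_dbn: bool = True,
) -> FeatureContext:
    panel = select_frequent_genes(dataset.target_genes, config.panel_threshold)
    gene_matrix, expr_matrix, ids = build_raw_features(dataset, panel, config.scaling)
    ctx = FeatureContext(
        ids=ids,
        id_to_row={l: i for i, l in enumerate(ids)},
        gene_matrix=gene_matrix,
        expr_matrix=expr_matrix,
        panel_size=len(panel),
    )
    if need_dbn and not config.dbn_per_fold:
        ctx.dbn_model = _train_dbn(gene_matrix, config, derive_seed(experiment_seed, "dbn"))
        ctx.dbn_codes = dbn_mod.dbn_encode(gene_matrix, ctx.dbn_model)
        _check_code_width(ctx.dbn_codes, expr_matrix)
    return ctx


def _train_dbn(gene_matrix, config: PipelineConfig, seed: int) -> dbn_mod.DBNModel:
    tc = dbn_mod.TrainingConfig(
        learning_rate=config.dbn_learning_rate,
        epochs=config.dbn_epochs,
        cd_steps=config.dbn_cd_steps,
        batch_size=config.dbn_batch_size,
        seed=seed,
    )
    return dbn_mod.dbn_train(gene_matrix, config.dbn_layer_sizes, tc)


def _check_code_width(codes: np.ndarray, expr_matrix: np.ndarray) -> None:
    if codes.shape[1] != expr_matrix.shape[1]:
        raise dbn_mod.ShapeError(
            f"encoder output width {codes.shape[1]} does not match the "
            f"{expr_matrix.shape[1]}-tissue expression row; set matching "
            "dbn_layer_sizes"
        )


def _tensors_from(codes: np.ndarray, expr: np.ndarray) -> np.ndarray:
    _check_code_width(codes, expr)
    return np.stack([codes, expr], axis=1)  # (n, 2, 13)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CancerResult:
    cancer: str
    method: str
    sample_ids: list[str]
    labels: np.ndarray
    fold_assignment: np.ndarray
    held_out_scores: np.ndarray
    fold_auc: list[float]
    fold_aupr: list[float]

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.held_out_scores, self.labels)

    @property
    def pooled_aupr(self) -> float:
        return pr_auc(self.held_out_scores, self.labels)


def _fit_and_score(
    method: str,
    train_feats: np.ndarray,
    train_labels: np.ndarray,
    test_feats: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> np.ndarray:
    common = dict(
        optimizer=config.clf_optimizer,
        learning_rate=config.clf_learning_rate,
        epochs=config.clf_epochs,
        batch_size=config.clf_batch_size,
        seed=seed,
    )
    if method in ("dbn-cnn", "pca-cnn"):
        net = cnn_mod.build_cnn(cnn_mod.CNNConfig(seed=seed))
        clf = cnn_mod.train_classifier(
            net, train_feats, train_labels,
            architecture="cnn", input_shape=(2, 13), **common,
        )
    elif method == "dbn-dnn":
        n_in = train_feats.shape[1]
        net = cnn_mod.build_dnn(
            cnn_mod.DNNConfig(hidden_sizes=config.dnn_hidden_sizes,
                              input_dim=n_in, seed=seed)
        )
        clf = cnn_mod.train_classifier(
            net, train_feats, train_labels,
            architecture="dnn", input_shape=(n_in,), **common,
        )
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return clf.score(test_feats)


def _method_features(
    method: str,
    ctx: FeatureContext,
    rows: np.ndarray,
    train_rows: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> np.ndarray:
    """Per-fold feature tensors for the sampled lncRNAs (rows into ctx)."""
    expr = ctx.expr_matrix[rows]
    if method == "pca-cnn":
        fit_rows = rows if config.pca_global else train_rows
        # a panel narrower than the requested dimension caps the component
        # count; the missing code coordinates are zero-padded
        n_comp = min(config.pca_components, ctx.gene_matrix.shape[1])
        transform = fit_pca(ctx.gene_matrix[fit_rows], n_comp)
        codes = pca_encode(ctx.gene_matrix[rows], transform)
        if codes.shape[1] < expr.shape[1]:
            pad = np.zeros((codes.shape[0], expr.shape[1] - codes.shape[1]))
            codes = np.hstack([codes, pad])
        return _tensors_from(codes, expr)
    if config.dbn_per_fold:
        model = _train_dbn(ctx.gene_matrix[train_rows], config, seed)
        codes = dbn_mod.dbn_encode(ctx.gene_matrix[rows], model)
    else:
        codes = ctx.dbn_codes[rows]
    if method == "dbn-cnn":
        return _tensors_from(codes, expr)
    if method == "dbn-dnn":
        return np.hstack([codes, expr])  # flattened 26-dim input
    raise ValueError(f"unknown method {method!r}")


def cross_validate_cancer(
    dataset: StudyDataset,
    cancer: str,
    method: str,
    spec: CVSpec,
    config: PipelineConfig | None = None,
    context: FeatureContext | None = None,
) -> CancerResult:
    """Stratified k-fold CV of one method on one cancer.

    Folds and negatives depend only on (dataset, cancer, experiment seed) —
    not on the method — so different methods under one seed are compared on
    byte-identical splits.
    """
    if cancer not in dataset.associations:
        raise KeyError(f"cancer {cancer!r} not in the retained cohort")
    config = config or PipelineConfig()
    if context is None:
        context = build_feature_context(
            dataset, config, spec.experiment_seed, need_dbn=method != "pca-cnn"
        )
    positives = sorted(dataset.associations[cancer])
    negatives = sample_negatives(
        dataset, cancer, spec.negative_ratio,
        derive_seed(spec.experiment_seed, "neg", cancer),
    )
    sample_ids = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    assignment = kfold_split(
        sample_ids, labels, spec, derive_seed(spec.experiment_seed, "fold", cancer)
    )
    rows = np.array([context.id_to_row[l] for l in sample_ids])

    held_out = np.full(len(sample_ids), np.nan)
    fold_auc: list[float] = []
    fold_aupr: list[float] = []
    for fold in range(spec.k):
        test_mask = assignment == fold
        train_idx = np.nonzero(~test_mask)[0]
        test_idx = np.nonzero(test_mask)[0]
        seed = derive_seed(spec.experiment_seed, "clf", method, cancer, fold)
        feats = _method_features(
            method, context, rows, rows[train_idx], config, seed
        )
        scores = _fit_and_score(
            method, feats[train_idx], labels[train_idx], feats[test_idx],
            config, seed,
        )
        held_out[test_idx] = scores
        fold_auc.append(roc_auc(scores, labels[test_idx]))
        fold_aupr.append(pr_auc(scores, labels[test_idx]))
    assert not np.any(np.isnan(held_out))
    return CancerResult(
        cancer=cancer,
        method=method,
        sample_ids=sample_ids,
        labels=labels,
        fold_assignment=assignment,
        held_out_scores=held_out,
        fold_auc=fold_auc,
        fold_aupr=fold_aupr,
    )


# ---------------------------------------------------------------------------
# full evaluation and reporting
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    results: list[CancerResult]
    spec: CVSpec
    config: PipelineConfig
    methods: list[str] = field(default_factory=list)

    def for_method(self, method: str) -> list[CancerResult]:
        return [r for r in self.results if r.method == method]

    def pooled_scores(self, method: str) -> tuple[np.ndarray, np.ndarray]:
        rs = self.for_method(method)
        scores = np.concatenate([r.held_out_scores for r in rs])
        labels = np.concatenate([r.labels for r in rs])
        return scores, labels

    def pooled_auc(self, method: str) -> float:
        return roc_auc(*self.pooled_scores(method))

    def pooled_aupr(self, method: str) -> float:
        return pr_auc(*self.pooled_scores(method))

    def macro_auc(self, method: str) -> float:
        return float(np.mean([r.pooled_auc for r in self.for_method(method)]))

    def macro_aupr(self, method: str) -> float:
        return float(np.mean([r.pooled_aupr for r in self.for_method(method)]))

    def per_cancer_table(self) -> pd.DataFrame:
        rows = [
            {
                "cancer": r.cancer,
                "method": r.method,
                "auc": r.pooled_auc,
                "aupr": r.pooled_aupr,
                "n_positives": int(r.labels.sum()),
                "n_negatives": int((1 - r.labels).sum()),
                "summary_type": "per_cancer_pooled",
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out: dict = {
            "settings": {
                "k": self.spec.k,
                "stratified": self.spec.stratified,
                "experiment_seed": self.spec.experiment_seed,
                "negative_ratio": self.spec.negative_ratio,
                "auc_ties": "half_credit_mann_whitney",
                "aupr_curve": "step_no_interpolation",
            },
            "methods": {},
        }
        for m in self.methods:
            out["methods"][m] = {
                "pooled": {
                    "summary_type": "pooled",
                    "auc": round(self.pooled_auc(m), 6),
                    "aupr": round(self.pooled_aupr(m), 6),
                },
                "macro": {
                    "summary_type": "macro",
                    "auc": round(self.macro_auc(m), 6),
                    "aupr": round(self.macro_aupr(m), 6),
                },
            }
        return out

    def write_report(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_cancer_table().to_csv(
            outdir / "per_cancer_metrics.tsv", sep="\t", index=False
        )
        roc_frames, pr_frames = [], []
        for m in self.methods:
            scores, labels = self.pooled_scores(m)
            rc = roc_curve_points(scores, labels)
            rc.insert(0, "method", m)
            roc_frames.append(rc)
            pc = pr_curve_points(scores, labels)
            pc.insert(0, "method", m)
            pr_frames.append(pc)
        pd.concat(roc_frames).to_csv(outdir / "pooled_roc.tsv", sep="\t", index=False)
        pd.concat(pr_frames).to_csv(outdir / "pooled_pr.tsv", sep="\t", index=False)
        with open(outdir / "summary.yaml", "w") as fh:
            yaml.safe_dump(self.summary(), fh, sort_keys=False)


def evaluate_all(
    dataset: StudyDataset,
    methods: Sequence[str] = ("dbn-cnn",),
    spec: CVSpec | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> EvalResult:
    """Cross-validate every retained cancer with every requested method."""
    spec = spec or CVSpec()
    config = config or PipelineConfig()
    if not dataset.associations:
        raise ValueError("dataset retains no cancers")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; choose from {METHODS}")
    need_dbn = any(m != "pca-cnn" for m in methods)
    context = build_feature_context(dataset, config, spec.experiment_seed, need_dbn)
    results = []
    for method in methods:
        for cancer in sorted(dataset.associations):
            logger.info("cross-validating %s on %s", method, cancer)
            results.append(
                cross_validate_cancer(dataset, cancer, method, spec, config, context)
            )
    out = EvalResult(results=results, spec=spec, config=config, methods=list(methods))
    if outdir is not None:
        out.write_report(outdir)
    return out


def rank_candidates(
    dataset: StudyDataset,
    cancer: str,
    method: str = "dbn-cnn",
    spec: CVSpec | None = None,
    config: PipelineConfig | None = None,
    outpath: str | Path | None = None,
) -> list[tuple[str, str, float, bool]]:
    """Score every lncRNA not known-associated with ``cancer``.

    The classifier is trained once on all known positives plus sampled
    negatives; the returned ranking covers the n - n_positives remaining
    lncRNAs, sorted by descending score.
    """
    spec = spec or CVSpec()
    config = config or PipelineConfig()
    context = build_feature_context(
        dataset, config, spec.experiment_seed, need_dbn=method != "pca-cnn"
    )
    positives = sorted(dataset.associations[cancer])
    negatives = sample_negatives(
        dataset, cancer, spec.negative_ratio,
        derive_seed(spec.experiment_seed, "neg", cancer),
    )
    train_ids = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    train_rows = np.array([context.id_to_row[l] for l in train_ids])
    candidates = [l for l in context.ids if l not in set(positives)]
    cand_rows = np.array([context.id_to_row[l] for l in candidates])
    seed = derive_seed(spec.experiment_seed, "rank", method, cancer)

    all_rows = np.concatenate([train_rows, cand_rows])
    feats = _method_features(method, context, all_rows, train_rows, config, seed)
    train_feats = feats[: len(train_rows)]
    cand_feats = feats[len(train_rows):]
    scores = _fit_and_score(method, train_feats, labels, cand_feats, config, seed)
    ranking = sorted(
        [(cancer, l, float(np.clip(s, 0.0, 1.0)), False)
         for l, s in zip(candidates, scores)],
        key=lambda r: (r[0], -r[2], r[1]),
    )
    if outpath is not None:
        write_predictions(outpath, ranking)
    return ranking
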