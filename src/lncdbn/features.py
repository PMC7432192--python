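"""Raw per-lncRNA features: the binary target-gene vector and the tissue profile.

The gene feature keeps only "frequent" target genes — those targeted by
strictly more than ``threshold`` distinct lncRNAs (threshold 5 yields the
45-gene panel on the full curated target table). Each lncRNA is then encoded
as a 0/1 membership vector over that panel. The expression feature is the
13-tissue profile, optionally min-max scaled per tissue so its coordinates
live on the same (0,1) scale as the sigmoid codes it is later stacked with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data_io import ExpressionTable, StudyDataset, TargetGeneTable

logger = logging.getLogger(__name__)

Scaling = Literal["none", "minmax_per_tissue"]


class PanelError(ValueError):
    """No gene survives the frequency filter at the requested threshold."""


@dataclass(frozen=True)
class GenePanel:
    """Ordered feature-gene panel selected by the frequency filter."""

    gene_symbols: tuple[str, ...]
    threshold: int

    def __len__(self) -> int:
        return len(self.gene_symbols)

    def index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_symbols)}


def select_frequent_genes(targets: TargetGeneTable, threshold: int = 5) -> GenePanel:
    """Select genes targeted by strictly more than ``threshold`` distinct lncRNAs.

    The panel order is (descending lncRNA count, gene symbol) — deterministic,
    and recorded with the panel because feature positions depend on it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    counts = targets.lncrna_counts_per_gene()
    kept = [(g, c) for g, c in counts.items() if c > threshold]
    if not kept:
        raise PanelError(
            f"no gene is targeted by more than {threshold} lncRNAs; "
            "lower the threshold"
        )
    kept.sort(key=lambda gc: (-gc[1], gc[0]))
    logger.info(
        "gene panel: %d of %d genes pass count > %d", len(kept), len(counts), threshold
    )
    return GenePanel(tuple(g for g, _ in kept), threshold)


def encode_target_gene_feature(
    lncrna_id: str, targets: TargetGeneTable, panel: GenePanel
) -> np.ndarray:
    """Binary membership vector of ``lncrna_id`` over the panel genes."""
    if len(panel) == 0:
        raise PanelError("empty gene panel")
    if lncrna_id not in targets.lncrna_ids:
        logger.warning(
            "lncRNA %s has no target-gene records; encoding as all-zero", lncrna_id
        )
        return np.zeros(len(panel))
    targeted = {g for l, g in targets.records if l == lncrna_id}
    return np.array([1.0 if g in targeted else 0.0 for g in panel.gene_symbols])


def minmax_scale_columns(values: np.ndarray) -> np.ndarray:
    """Map each column independently to [0, 1]; constant columns map to 0."""
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    out = np.zeros_like(values, dtype=float)
    nz = span > 0
    out[:, nz] = (values[:, nz] - lo[nz]) / span[nz]
    return out


def encode_expression_feature(
    lncrna_id: str, expr: ExpressionTable, scaling: Scaling = "minmax_per_tissue"
) -> np.ndarray:
    """Length-13 expression vector in the table's tissue order."""
    if scaling == "none":
        return expr.row(lncrna_id).copy()
    if scaling == "minmax_per_tissue":
        expr.row(lncrna_id)  # raises KeyError for unknown ids
        i = expr.lncrna_ids.index(lncrna_id)
        return minmax_scale_columns(expr.values)[i]
    raise ValueError(f"unknown scaling mode {scaling!r}")


def build_raw_features(
    dataset: StudyDataset,
    panel: GenePanel,
    scaling: Scaling = "minmax_per_tissue",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Gene and expression feature matrices for every lncRNA in the dataset.

    Returns ``(gene_matrix, expr_matrix, id_index)`` where row ``i`` of both
    matrices corresponds to ``id_index[i]``. Purely a function of its inputs:
    repeated calls are bitwise identical.
    """
    ids = list(dataset.lncrna_ids)
    if not ids:
        return np.zeros((0, len(panel))), np.zeros((0, 13)), ids
    by_lnc: dict[str, set[str]] = {}
    for l, g in dataset.target_genes.records:
        by_lnc.setdefault(l, set()).add(g)
    gene_matrix = np.zeros((len(ids), len(panel)))
    for i, lnc in enumerate(ids):
        targeted = by_lnc.get(lnc, set())
        for j, g in enumerate(panel.gene_symbols):
            if g in targeted:
                gene_matrix[i, j] = 1.0
    expr = dataset.expression.restricted_to(ids)
    expr_matrix = expr.values.copy()
    if scaling == "minmax_per_tissue":
        expr_matrix = minmax_scale_columns(expr_matrix)
    elif scaling != "none":
        raise ValueError(f"unknown scaling mode {scaling!r}")
    return gene_matrix, expr_matrix, ids
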