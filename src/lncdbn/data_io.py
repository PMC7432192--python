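"""Readers, writers and cohort assembly for the three study tables.

Three tab-separated inputs drive the pipeline:

* an lncRNA-disease association table (LncRNADisease-style),
* an lncRNA -> target-gene table (LncRNA2Target-style),
* an lncRNA x 13-tissue expression table (NONCODE-style).

Column names are configurable; the defaults below are the package's own
schema. ``assemble_dataset`` intersects the three tables and keeps only
cancers with strictly more than ``min_positives`` associated lncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default 13-tissue panel. Tissue order is fixed at load time and preserved
#: everywhere downstream; feature positions are meaningless without it.
DEFAULT_TISSUES: tuple[str, ...] = (
    "adipose",
    "adrenal",
    "breast",
    "colon",
    "heart",
    "kidney",
    "liver",
    "lung",
    "lymph_node",
    "ovary",
    "prostate",
    "testis",
    "thyroid",
)


class FormatError(ValueError):
    """A required column is missing or a value violates the table contract."""


class AssemblyError(ValueError):
    """The three tables cannot be joined into a usable study cohort."""


def _normalize_disease(name: str) -> str:
    return str(name).strip().casefold()


@dataclass
class AssociationTable:
    """Known (lncRNA, disease) association pairs.

    Disease names are case-folded and trimmed before any grouping;
    duplicate pairs are dropped at load time.
    """

    records: list[tuple[str, str]]
    provenance: str = ""

    @property
    def lncrna_ids(self) -> set[str]:
        return {lnc for lnc, _ in self.records}

    def positives_by_disease(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for lnc, disease in self.records:
            out.setdefault(disease, set()).add(lnc)
        return out


@dataclass
class TargetGeneTable:
    """(lncRNA, target gene) pairs from knockdown/overexpression evidence."""

    records: list[tuple[str, str]]

    @property
    def lncrna_ids(self) -> set[str]:
        return {lnc for lnc, _ in self.records}

    def lncrna_counts_per_gene(self) -> dict[str, int]:
        """Distinct-lncRNA count per gene; this count drives the gene panel filter."""
        genes: dict[str, set[str]] = {}
        for lnc, gene in self.records:
            genes.setdefault(gene, set()).add(lnc)
        return {g: len(s) for g, s in genes.items()}

    def restricted_to(self, ids: Iterable[str]) -> "TargetGeneTable":
        keep = set(ids)
        return TargetGeneTable([(l, g) for l, g in self.records if l in keep])


@dataclass
class ExpressionTable:
    """Per-lncRNA expression across an ordered panel of 13 tissues."""

    lncrna_ids: list[str]
    tissue_names: list[str]
    values: np.ndarray  # (n_lncrna, 13), finite, >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lncrna_ids), len(self.tissue_names)):
            raise FormatError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.lncrna_ids)} ids x {len(self.tissue_names)} tissues"
            )
        if len(self.tissue_names) != 13:
            raise FormatError(
                f"expected 13 tissue columns, got {len(self.tissue_names)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        if np.any(self.values < 0):
            raise FormatError("expression values must be non-negative")

    def row(self, lncrna_id: str) -> np.ndarray:
        try:
            i = self.lncrna_ids.index(lncrna_id)
        except ValueError as exc:
            raise KeyError(f"lncRNA {lncrna_id!r} not in expression table") from exc
        return self.values[i]

    def restricted_to(self, ids: Sequence[str]) -> "ExpressionTable":
        index = {l: i for i, l in enumerate(self.lncrna_ids)}
        rows = [index[l] for l in ids]
        return ExpressionTable(list(ids), list(self.tissue_names), self.values[rows])


@dataclass
class StudyDataset:
    """Aligned cohort: ids common to all three tables, per-cancer positives."""

    lncrna_ids: list[str]
    associations: dict[str, set[str]]
    target_genes: TargetGeneTable
    expression: ExpressionTable
    min_positives: int = 20
    per_cancer_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_association_table(
    path: str | Path,
    lncrna_col: str = "lncrna",
    disease_col: str = "disease",
    provenance: str = "",
) -> AssociationTable:
    """Load and deduplicate an lncRNA-disease association TSV."""
    df = _read_tsv(path, [lncrna_col, disease_col])
    raw = len(df)
    records: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lnc, disease in zip(df[lncrna_col], df[disease_col]):
        rec = (str(lnc).strip(), _normalize_disease(disease))
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    if raw == 0:
        logger.warning("association table %s is empty", path)
    logger.info(
        "read %d association rows from %s, kept %d after dedup", raw, path, len(records)
    )
    return AssociationTable(records, provenance or str(path))


def read_target_gene_table(
    path: str | Path,
    lncrna_col: str = "lncrna",
    gene_col: str = "gene",
) -> TargetGeneTable:
    """Load and deduplicate an lncRNA -> target-gene TSV."""
    df = _read_tsv(path, [lncrna_col, gene_col])
    raw = len(df)
    records: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lnc, gene in zip(df[lncrna_col], df[gene_col]):
        rec = (str(lnc).strip(), str(gene).strip())
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    logger.info(
        "read %d target-gene rows from %s, kept %d after dedup", raw, path, len(records)
    )
    return TargetGeneTable(records)


def read_expression_table(
    path: str | Path,
    tissue_columns: Sequence[str] | None = None,
    lncrna_col: str = "lncrna",
) -> ExpressionTable:
    """Load a 13-tissue expression TSV.

    Exactly the 13 requested tissue columns must resolve in the header;
    extra columns are ignored. Rows with any missing tissue value are
    dropped and counted.
    """
    tissues = list(tissue_columns if tissue_columns is not None else DEFAULT_TISSUES)
    if len(tissues) != 13:
        raise FormatError(f"exactly 13 tissue columns required, got {len(tissues)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [t for t in tissues if t not in df.columns]
    if missing or lncrna_col not in df.columns:
        raise FormatError(
            f"{path}: could not resolve columns; missing {missing or [lncrna_col]}, "
            f"found {list(df.columns)}"
        )
    sub = df[[lncrna_col] + tissues].copy()
    for t in tissues:
        sub[t] = pd.to_numeric(sub[t], errors="coerce")
    before = len(sub)
    sub = sub.dropna(subset=tissues)
    dropped = before - len(sub)
    if dropped:
        logger.info("dropped %d expression rows with missing values", dropped)
    ids = [str(x).strip() for x in sub[lncrna_col]]
    return ExpressionTable(ids, tissues, sub[tissues].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def write_association_table(path: str | Path, table: AssociationTable) -> None:
    pd.DataFrame(table.records, columns=["lncrna", "disease"]).to_csv(
        path, sep="\t", index=False
    )


def write_target_gene_table(path: str | Path, table: TargetGeneTable) -> None:
    pd.DataFrame(table.records, columns=["lncrna", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def write_expression_table(path: str | Path, table: ExpressionTable) -> None:
    df = pd.DataFrame(table.values, columns=table.tissue_names)
    df.insert(0, "lncrna", table.lncrna_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_predictions(
    path: str | Path,
    ranking: Iterable[tuple[str, str, float, bool]],
) -> None:
    """Write a (cancer, lncrna, score, known_flag) ranking as TSV.

    Rows are sorted by cancer, then descending score, with ties broken by
    lncRNA id so the output is stable.
    """
    rows = list(ranking)
    for _, _, score, _ in rows:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score {score} outside [0, 1]")
    rows.sort(key=lambda r: (r[0], -r[2], r[1]))
    df = pd.DataFrame(rows, columns=["cancer", "lncrna", "score", "known"])
    df["known"] = df["known"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path: str | Path) -> list[tuple[str, str, float, bool]]:
    df = pd.read_csv(path, sep="\t", dtype={"cancer": str, "lncrna": str})
    return [
        (str(c), str(l), float(s), bool(k))
        for c, l, s, k in zip(df["cancer"], df["lncrna"], df["score"], df["known"])
    ]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    assoc: AssociationTable,
    targets: TargetGeneTable,
    expr: ExpressionTable,
    min_positives: int = 20,
    cancer_whitelist: Sequence[str] | None = None,
    require_targets: bool = True,
) -> StudyDataset:
    """Intersect the three tables and apply the cancer cohort filter.

    lncRNAs must be present in the expression table and the association
    universe; by default they must also have at least one target-gene record
    (``require_targets=False`` keeps them with an all-zero gene vector).
    A cancer is kept iff strictly more than ``min_positives`` of its
    associated lncRNAs survive the intersection.
    """
    if min_positives < 1:
        raise ValueError("min_positives must be >= 1")
    expr_ids = set(expr.lncrna_ids)
    assoc_ids = assoc.lncrna_ids
    ids = expr_ids & assoc_ids
    if require_targets:
        ids &= targets.lncrna_ids
    if not ids:
        raise AssemblyError(
            "empty lncRNA intersection: "
            f"expression={len(expr_ids)}, associations={len(assoc_ids)}, "
            f"targets={len(targets.lncrna_ids)}"
        )
    lncrna_ids = sorted(ids)

    whitelist = (
        {_normalize_disease(c) for c in cancer_whitelist}
        if cancer_whitelist is not None
        else None
    )
    associations: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for cancer, pos in sorted(assoc.positives_by_disease().items()):
        surviving = pos & ids
        counts[cancer] = len(surviving)
        if whitelist is not None and cancer not in whitelist:
            continue
        if len(surviving) > min_positives:  # strict: "more than" min_positives
            associations[cancer] = surviving
    logger.info(
        "assembled dataset: %d lncRNAs, %d/%d cancers kept (min_positives=%d)",
        len(lncrna_ids),
        len(associations),
        len(counts),
        min_positives,
    )
    return StudyDataset(
        lncrna_ids=lncrna_ids,
        associations=associations,
        target_genes=targets.restricted_to(lncrna_ids),
        expression=expr.restricted_to(lncrna_ids),
        min_positives=min_positives,
        per_cancer_counts=counts,
    )
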