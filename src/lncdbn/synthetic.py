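"""Seeded generator of association / target-gene / expression fixtures.

The generator emulates the three real inputs with planted, tunable signal so
every pipeline stage is testable without database downloads:

* a pool of lncRNAs and genes, of which ``n_panel_genes`` are "popular"
  enough (background targeting probability ``p_bg`` over hundreds of
  lncRNAs) to pass the frequency filter and form the feature panel;
* per cancer, a designated subset of panel genes is cancer-linked;
  associated lncRNAs target each with probability ``p_in`` (others with
  ``p_bg``), planting signal in the gene feature;
* expression is log-normal per tissue; associated lncRNAs get a mean shift
  of ``expr_shift`` baseline standard deviations in ``n_shift_tissues``
  designated tissues, planting signal in the expression feature;
* every lncRNA with no planted cancer association is attached to small
  filler diseases (each below the cohort threshold) so it enters the
  association universe as a negative candidate without creating a spurious
  cancer cohort.

Truth labels are returned out-of-band so the emitted TSVs stay
byte-compatible with the real-data readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_io import (
    DEFAULT_TISSUES,
    AssociationTable,
    ExpressionTable,
    TargetGeneTable,
    write_association_table,
    write_expression_table,
    write_target_gene_table,
)


class SpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Study-generation parameters; defaults give one clearly learnable cancer."""

    n_lncrna: int = 300
    n_genes: int = 200
    n_panel_genes: int = 45
    n_tissues: int = 13
    cancers: tuple[tuple[str, int], ...] = (("cancer_1", 60),)
    n_linked_genes: int = 15
    p_in: float = 0.6
    p_bg: float = 0.1
    p_offpanel: float = 0.005
    expr_shift: float = 2.0
    n_shift_tissues: int = 3
    expr_meanlog: float = 1.0
    expr_sdlog: float = 1.0
    filler_disease_size: int = 15
    seed: int = 0
    tissue_names: tuple[str, ...] = field(default=DEFAULT_TISSUES)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg <= self.p_in <= 1.0):
            raise SpecError("need 0 <= p_bg <= p_in <= 1")
        if self.n_panel_genes > self.n_genes:
            raise SpecError("n_panel_genes cannot exceed n_genes")
        if self.n_linked_genes > self.n_panel_genes:
            raise SpecError("n_linked_genes cannot exceed n_panel_genes")
        if self.n_shift_tissues > self.n_tissues:
            raise SpecError("n_shift_tissues cannot exceed n_tissues")
        if len(self.tissue_names) != self.n_tissues:
            raise SpecError("tissue_names length must equal n_tissues")
        if any(n > self.n_lncrna for _, n in self.cancers):
            raise SpecError("a cancer cannot have more positives than lncRNAs")


def generate_synthetic_study(
    spec: SyntheticSpec,
) -> tuple[AssociationTable, TargetGeneTable, ExpressionTable, dict[str, set[str]]]:
    """Generate the three tables plus out-of-band truth labels.

    Deterministic per ``spec.seed``: same spec, bitwise-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    lncrnas = [f"LNC{i:05d}" for i in range(spec.n_lncrna)]
    genes = [f"GENE{j:04d}" for j in range(spec.n_genes)]
    panel_genes = genes[: spec.n_panel_genes]
    offpanel_genes = genes[spec.n_panel_genes :]

    # truth: which lncRNAs belong to which cancer
    truth: dict[str, set[str]] = {}
    for name, n_pos in spec.cancers:
        pos = rng.choice(spec.n_lncrna, size=n_pos, replace=False)
        truth[name] = {lncrnas[i] for i in sorted(pos)}

    # cancer-linked panel genes and shifted tissues per cancer
    linked_genes: dict[str, set[str]] = {}
    shifted_tissues: dict[str, np.ndarray] = {}
    for name, _ in spec.cancers:
        gsel = rng.choice(spec.n_panel_genes, size=spec.n_linked_genes, replace=False)
        linked_genes[name] = {panel_genes[j] for j in sorted(gsel)}
        shifted_tissues[name] = np.sort(
            rng.choice(spec.n_tissues, size=spec.n_shift_tissues, replace=False)
        )

    # ---- target-gene table ------------------------------------------------
    target_records: list[tuple[str, str]] = []
    for lnc in lncrnas:
        my_cancers = [c for c in truth if lnc in truth[c]]
        hot = set().union(*(linked_genes[c] for c in my_cancers)) if my_cancers else set()
        for g in panel_genes:
            p = spec.p_in if g in hot else spec.p_bg
            if rng.random() < p:
                target_records.append((lnc, g))
        for g in offpanel_genes:
            if rng.random() < spec.p_offpanel:
                target_records.append((lnc, g))

    # ---- expression table -------------------------------------------------
    base = rng.lognormal(
        mean=spec.expr_meanlog, sigma=spec.expr_sdlog,
        size=(spec.n_lncrna, spec.n_tissues),
    )
    sdlog2 = spec.expr_sdlog**2
    baseline_sd = float(
        np.sqrt((np.exp(sdlog2) - 1.0) * np.exp(2 * spec.expr_meanlog + sdlog2))
    )
    for name, _ in spec.cancers:
        rows = [i for i, lnc in enumerate(lncrnas) if lnc in truth[name]]
        cols = shifted_tissues[name]
        base[np.ix_(rows, cols)] += spec.expr_shift * baseline_sd
    expr = ExpressionTable(list(lncrnas), list(spec.tissue_names), base)

    # ---- association table ------------------------------------------------
    assoc_records: list[tuple[str, str]] = []
    for name, _ in spec.cancers:
        for lnc in sorted(truth[name]):
            assoc_records.append((lnc, name))
    unassigned = [l for l in lncrnas if not any(l in s for s in truth.values())]
    for i, lnc in enumerate(unassigned):
        filler = f"condition_{i // spec.filler_disease_size:03d}"
        assoc_records.append((lnc, filler))
    assoc = AssociationTable(assoc_records, provenance=f"synthetic(seed={spec.seed})")

    return assoc, TargetGeneTable(target_records), expr, truth


def permute_labels(assoc: AssociationTable, seed: int) -> AssociationTable:
    """Null control: permute lncRNA ids against disease names.

    Per-disease record counts are preserved. Permutations producing a
    duplicate (lncRNA, disease) pair are rejected and redrawn (up to a
    bounded number of attempts), so the table invariant holds.
    """
    if not assoc.records:
        raise ValueError("cannot permute an empty association table")
    lncs = [l for l, _ in assoc.records]
    diseases = [d for _, d in assoc.records]
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        perm = rng.permutation(len(lncs))
        shuffled = [lncs[i] for i in perm]
        records = list(zip(shuffled, diseases))
        if len(set(records)) == len(records):
            return AssociationTable(
                records, provenance=f"{assoc.provenance}|permuted(seed={seed})"
            )
    raise RuntimeError("could not find a duplicate-free label permutation")


def write_synthetic_study(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the three TSVs plus truth.yaml; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assoc, targets, expr, truth = generate_synthetic_study(spec)
    paths = {
        "associations": outdir / "associations.tsv",
        "target_genes": outdir / "target_genes.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.yaml",
    }
    write_association_table(paths["associations"], assoc)
    write_target_gene_table(paths["target_genes"], targets)
    write_expression_table(paths["expression"], expr)
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(
            {c: sorted(ids) for c, ids in truth.items()}, fh, sort_keys=True
        )
    return paths


def load_spec(path: str | Path) -> SyntheticSpec:
    """Read a SyntheticSpec from YAML (keys match the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "cancers" in raw:
        raw["cancers"] = tuple((str(n), int(k)) for n, k in raw["cancers"])
    if "tissue_names" in raw:
        raw["tissue_names"] = tuple(raw["tissue_names"])
    return SyntheticSpec(**raw)
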