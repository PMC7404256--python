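"""Differential expression plumbing: logFC tables and concordant genes.

The pipeline needs, per disease, the genes whose expression responds
both to the disease state (tumor vs normal) and to the drug
perturbation (treated vs untreated cell line).  Moderated statistics
are out of scope here; a plain difference of group means on the log2
scale stands in for the fold-change fit, and concordance is the
direction-agnostic rule: a gene qualifies when it is differentially
expressed (|logFC| above threshold) in both tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DifferentialTable",
    "ExpressionMatrix",
    "log_fold_change",
    "select_concordant_genes",
    "read_differential_table",
    "write_differential_table",
    "read_expression_matrix",
]

CASE = "case"
CONTROL = "control"


@dataclass
class DifferentialTable:
    """Mapping gene -> signed log2 fold-change for one condition."""

    entries: dict[str, float]
    condition_label: str = "condition"

    def __post_init__(self) -> None:
        for gene, lfc in self.entries.items():
            if not math.isfinite(lfc):
                raise ValueError(f"non-finite logFC for gene {gene!r}: {lfc!r}")

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def __getitem__(self, gene: str) -> float:
        return self.entries[gene]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2 expression values with case/control labels."""

    values: pd.DataFrame  # genes x samples
    labels: pd.Series  # sample -> "case" | "control"
    name: str = "expression"

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = self.labels[self.labels.isna()].index.tolist()
            raise ValueError(f"samples without labels: {missing}")
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be 'case' or 'control', got {sorted(bad)}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def condition_samples(self, condition: str) -> list[str]:
        if condition not in (CASE, CONTROL):
            raise ValueError(f"condition must be 'case' or 'control', got {condition!r}")
        return [s for s in self.values.columns if self.labels[s] == condition]


def log_fold_change(expr: ExpressionMatrix) -> DifferentialTable:
    """Per-gene mean(case) - mean(control) on the log2 scale."""
    cases = expr.condition_samples(CASE)
    controls = expr.condition_samples(CONTROL)
    if not cases or not controls:
        raise ValueError("need at least one case and one control sample")
    lfc = expr.values[cases].mean(axis=1) - expr.values[controls].mean(axis=1)
    return DifferentialTable(
        {str(g): float(v) for g, v in lfc.items()}, condition_label=expr.name
    )


def select_concordant_genes(
    disease: DifferentialTable,
    drug: DifferentialTable,
    min_abs_logfc: float = 0.0,
    require_opposite_sign: bool = False,
) -> set[str]:
    """Genes differentially expressed in both the disease and the drug table.

    A gene is selected when |logFC| > ``min_abs_logfc`` (strict) in the
    disease table AND it is present with |logFC| > ``min_abs_logfc`` in
    the drug table.  Direction is not compared by default; with
    ``require_opposite_sign`` the drug response must additionally have
    the opposite sign to the disease change (the reversal hypothesis).
    Genes absent from either table are never selected.
    """
    if min_abs_logfc < 0:
        raise ValueError("min_abs_logfc must be non-negative")
    out: set[str] = set()
    for gene, d_lfc in disease.entries.items():
        if abs(d_lfc) <= min_abs_logfc:
            continue
        g_lfc = drug.entries.get(gene)
        if g_lfc is None or abs(g_lfc) <= min_abs_logfc:
            continue
        if require_opposite_sign and d_lfc * g_lfc >= 0:
            continue
        out.add(gene)
    return out


# -- file formats -----------------------------------------------------


def read_differential_table(
    path: str | Path, condition_label: str | None = None
) -> DifferentialTable:
    """Two-column TSV: gene-id, logFC; optional header auto-detected."""
    path = Path(path)
    entries: dict[str, float] = {}
    first = True
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        if first:
            first = False
            try:
                float(parts[1])
            except ValueError:
                continue  # header
        entries[parts[0]] = float(parts[1])
    return DifferentialTable(
        entries, condition_label=condition_label or path.stem
    )


def write_differential_table(table: DifferentialTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(table.entries):
            fh.write(f"{gene}\t{table.entries[gene]!r}\n")


def read_expression_matrix(
    values_path: str | Path, labels_path: str | Path, name: str | None = None
) -> ExpressionMatrix:
    """TSV with gene rows / sample columns plus a two-column labels TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    labels_df = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample", "label"], dtype=str
    )
    if labels_df.iloc[0]["label"] not in (CASE, CONTROL):
        labels_df = labels_df.iloc[1:]  # header row
    labels = pd.Series(
        labels_df["label"].values, index=labels_df["sample"].values
    )
    return ExpressionMatrix(values, labels, name=name or Path(values_path).stem)
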