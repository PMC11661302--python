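"""Depth-matched benchmarking preprocessing.

Three steps make libraries of different sequencing depth comparable before
any quality comparison: keep the top-N cells by total UMIs (matching the
targeted cell recovery), thin sequencing reads at the molecule level so the
mean (or median) reads per cell matches a reference sample, and drop
low-quality cells by percentile rules on genes detected, total UMIs and
mitochondrial fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, MoleculeTable, ValidationError

QC_METRICS = ("genes_detected", "total_umis", "mito_fraction")


@dataclass
class QCRule:
    """Percentile rule on a per-cell QC metric.

    A cell violates the rule when its metric is strictly below the
    ``lower_percentile`` threshold or strictly above the ``upper_percentile``
    threshold (thresholds are computed on the input matrix with linear
    interpolation between order statistics). ``mito_gene_prefix`` is used
    only by the ``mito_fraction`` metric.
    """

    metric: Literal["genes_detected", "total_umis", "mito_fraction"]
    lower_percentile: float | None = None
    upper_percentile: float | None = None
    mito_gene_prefix: tuple[str, ...] = ("MT-", "mt-")

    def __post_init__(self) -> None:
        if self.metric not in QC_METRICS:
            raise ValidationError(f"unknown QC metric {self.metric!r}")
        for p in (self.lower_percentile, self.upper_percentile):
            if p is not None and not (0 <= p <= 100):
                raise ValidationError(f"percentile {p} outside [0, 100]")
        if (
            self.lower_percentile is not None
            and self.upper_percentile is not None
            and not self.lower_percentile < self.upper_percentile
        ):
            raise ValidationError("lower_percentile must be < upper_percentile")
        if isinstance(self.mito_gene_prefix, str):
            self.mito_gene_prefix = (self.mito_gene_prefix,)


def select_top_cells(matrix: CountMatrix, n: int) -> CountMatrix:
    """Keep the min(n, #cells) cells with the largest total UMI count.

    Ties at the cutoff resolve by input order (stable sort); the retained
    cells keep their original relative order.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if matrix.n_cells == 0:
        raise ValidationError("cannot select cells from an empty matrix")
    totals = matrix.cell_totals()
    order = np.argsort(-totals, kind="stable")
    keep = np.sort(order[: min(n, matrix.n_cells)])
    return matrix.subset_cells(keep)


def downsample_reads(
    molecules: MoleculeTable,
    target_mean_reads_per_cell: float,
    seed: int,
    cells: Sequence[str] | None = None,
    features: Sequence[str] | None = None,
    statistic: Literal["mean", "median"] = "mean",
) -> CountMatrix:
    """Thin reads to a target depth and rebuild the UMI matrix.

    Each read is retained independently with probability
    ``p = target / current`` where ``current`` is the chosen reads-per-cell
    statistic of the input table; a UMI survives iff at least one of its
    reads survives, so a molecule with ``r`` reads survives with probability
    ``1 - (1 - p)^r``. Survival is simulated with one uniform per molecule
    against that probability, which couples outcomes across targets for a
    fixed seed: lowering the target can only remove UMIs, never add them.

    A target at or above the current depth leaves counts unchanged (with a
    warning). ``cells``/``features`` fix the output axes (defaulting to the
    sorted identifiers present in the table).
    """
    if target_mean_reads_per_cell <= 0:
        raise ValidationError("target reads per cell must be > 0")
    if len(molecules) == 0:
        raise ValidationError("molecule table is empty")
    if statistic == "mean":
        current = molecules.mean_reads_per_cell()
    elif statistic == "median":
        current = molecules.median_reads_per_cell()
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")
    p = target_mean_reads_per_cell / current
    if p >= 1.0:
        if p > 1.0:
            warnings.warn(
                f"target {target_mean_reads_per_cell} >= current {statistic} "
                f"{current:.3f}; no downsampling applied",
                stacklevel=2,
            )
        return molecules.to_umi_matrix(cells=cells, features=features)

    reads = molecules.records["reads"].to_numpy()
    rng = np.random.default_rng(seed)
    u = rng.random(len(reads))
    survive_prob = 1.0 - (1.0 - p) ** reads
    kept = molecules.records.loc[u < survive_prob]
    if cells is None:
        cells = sorted(molecules.records["cell"].unique())
    if features is None:
        features = sorted(molecules.records["feature"].unique())
    kept_table = MoleculeTable(
        records=kept if len(kept) else pd.DataFrame(columns=list(MoleculeTable.COLUMNS))
    )
    return kept_table.to_umi_matrix(cells=cells, features=features)


def qc_metrics(matrix: CountMatrix, mito_gene_prefix: Sequence[str] = ("MT-", "mt-")) -> pd.DataFrame:
    """Per-cell QC metrics: genes detected, total UMIs, mitochondrial fraction."""
    totals = matrix.cell_totals().astype(float)
    mito_cols = [
        j for j, f in enumerate(matrix.features)
        if any(f.startswith(pref) for pref in mito_gene_prefix)
    ]
    if mito_cols:
        mito = np.asarray(matrix.counts[:, mito_cols].sum(axis=1)).ravel().astype(float)
    else:
        mito = np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    return pd.DataFrame(
        {
            "genes_detected": matrix.genes_detected().astype(float),
            "total_umis": totals,
            "mito_fraction": frac,
        },
        index=matrix.cells,
    )


def qc_filter(matrix: CountMatrix, rules: list[QCRule]) -> tuple[CountMatrix, dict]:
    """Remove cells that violate any rule; return the kept matrix and a report.

    Percentile thresholds are computed on the input matrix before any
    removal; a cell is removed when it violates one or more rules. The
    report records the thresholds, per-rule removal counts and the
    percentile/strictness conventions used.
    """
    if matrix.n_cells == 0:
        raise ValidationError("cannot QC-filter an empty matrix")
    metrics = qc_metrics(
        matrix,
        mito_gene_prefix=next(
            (r.mito_gene_prefix for r in rules if r.metric == "mito_fraction"),
            ("MT-", "mt-"),
        ),
    )
    removed = np.zeros(matrix.n_cells, dtype=bool)
    report_rules = []
    for rule in rules:
        values = metrics[rule.metric].to_numpy()
        lo = hi = None
        viol = np.zeros(matrix.n_cells, dtype=bool)
        if rule.lower_percentile is not None:
            lo = float(np.percentile(values, rule.lower_percentile))
            viol |= values < lo
        if rule.upper_percentile is not None:
            hi = float(np.percentile(values, rule.upper_percentile))
            viol |= values > hi
        removed |= viol
        report_rules.append(
            {
                "metric": rule.metric,
                "lower_percentile": rule.lower_percentile,
                "upper_percentile": rule.upper_percentile,
                "lower_threshold": lo,
                "upper_threshold": hi,
                "n_violating": int(viol.sum()),
            }
        )
    kept_idx = np.flatnonzero(~removed)
    report = {
        "n_input_cells": matrix.n_cells,
        "n_removed": int(removed.sum()),
        "n_kept": int(kept_idx.size),
        "percentile_definition": "linear interpolation between order statistics (numpy.percentile default)",
        "violation": "strict: value < lower threshold or value > upper threshold",
        "rules": report_rules,
    }
    return matrix.subset_cells(kept_idx), report
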