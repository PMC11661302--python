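"""Transcription-factor bound-target sets intersected with differential expression.

Condition-specific bound-gene sets are built by set algebra on ChIP-seq
bound lists: the union of the lists bound under the condition of interest,
minus the union of control / knockout lists. Differential expression between
two cell groups uses the Wilcoxon rank-sum test per gene (exact enumeration
for small groups, normal approximation with tie correction otherwise) with
log2 fold changes on back-transformed normalized means, BH adjustment within
the comparison, and the joint gate FDR < 0.05 and |log2FC| > log2(1.5) in at
least one time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix, ValidationError
from .correlate import bh_adjust

EXACT_MAX_GROUP = 8


@dataclass
class BoundSetSpec:
    """Named include/exclude gene sets for bound-set construction."""

    include_sets: dict[str, set[str]]
    exclude_sets: dict[str, set[str]] = field(default_factory=dict)
    mode: Literal["union", "intersection"] = "union"

    def __post_init__(self) -> None:
        overlap = set(self.include_sets) & set(self.exclude_sets)
        if overlap:
            raise ValidationError(f"set names appear on both sides: {sorted(overlap)}")
        for name, genes in {**self.include_sets, **self.exclude_sets}.items():
            if any(not isinstance(g, str) or not g for g in genes):
                raise ValidationError(f"set {name!r} contains empty or non-string symbols")


def build_bound_set(spec: BoundSetSpec, case_fold: bool = False) -> set[str]:
    """(union or intersection of include sets) minus the union of exclude sets.

    Symbol matching is case-sensitive unless ``case_fold`` is set.
    """
    if not spec.include_sets:
        raise ValidationError("at least one include set is required")

    def norm(genes: set[str]) -> set[str]:
        return {g.casefold() for g in genes} if case_fold else set(genes)

    included = [norm(s) for s in spec.include_sets.values()]
    if spec.mode == "union":
        bound = set().union(*included)
    elif spec.mode == "intersection":
        bound = set.intersection(*included)
    else:
        raise ValidationError(f"unknown mode {spec.mode!r}")
    if not bound:
        warnings.warn("include sets produce an empty bound set", stacklevel=2)
        return set()
    for s in spec.exclude_sets.values():
        bound -= norm(s)
    return bound


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments.

    Uses the symmetric deviation |W - E[W]| of group a's rank sum over every
    C(n_a + n_b, n_a) assignment of the pooled (midrank-tied) values.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    expected = n_a * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - expected)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - expected) >= dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_de(
    values: NormalizedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudo: float = 1.0,
    group_a_label: str = "a",
    group_b_label: str = "b",
    time_point: str | None = None,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum differential expression between two groups.

    Fold change is computed on back-transformed means: values are treated as
    ln(1 + x)-scale, so m = mean(expm1(value)) per group and
    log2FC = log2((m_a + pseudo) / (m_b + pseudo)). Exact enumeration is used
    when both groups have at most 8 cells, otherwise the normal approximation
    with tie and continuity correction. BH spans the genes of this comparison.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("both groups need at least 3 cells")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    cell_pos = {c: i for i, c in enumerate(values.cells)}
    missing = [c for c in group_a + group_b if c not in cell_pos]
    if missing:
        raise ValidationError(f"cells not in matrix: {missing[:5]}")
    ia = np.array([cell_pos[c] for c in group_a])
    ib = np.array([cell_pos[c] for c in group_b])
    va = values.values[ia]
    vb = values.values[ib]

    m_a = np.expm1(va).mean(axis=0)
    m_b = np.expm1(vb).mean(axis=0)
    log2_fc = np.log2((m_a + pseudo) / (m_b + pseudo))

    if len(group_a) <= EXACT_MAX_GROUP and len(group_b) <= EXACT_MAX_GROUP:
        p = np.array([_exact_ranksum_p(va[:, j], vb[:, j]) for j in range(va.shape[1])])
    else:
        res = stats.mannwhitneyu(va, vb, alternative="two-sided",
                                 method="asymptotic", axis=0)
        p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": values.features,
            "group_a": group_a_label,
            "group_b": group_b_label,
            "log2_fc": log2_fc,
            "p": p,
            "fdr": fdr,
            "time_point": time_point,
        }
    )


def intersect_targets(
    bound: set[str],
    de: Mapping[str, pd.DataFrame],
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict DE results to bound genes and gate them into a target table.

    A gene is differentially expressed when some time point has
    fdr < ``fdr_threshold`` and |log2_fc| > log2(``fc_threshold``). The
    per-gene direction comes from the sign of log2_fc at the most
    significant qualifying time point; genes qualifying in opposite
    directions at different time points carry ``direction_conflict``.

    Returns ``(targets, counts)``: one row per bound gene, and per-time-point
    up/down counts among bound genes.
    """
    if fdr_threshold <= 0 or fc_threshold <= 0:
        raise ValidationError("thresholds must be > 0")
    lfc_gate = np.log2(fc_threshold)

    per_tp = {}
    for tp, frame in de.items():
        f = frame.set_index("gene")
        qual = (f["fdr"] < fdr_threshold) & (f["log2_fc"].abs() > lfc_gate)
        per_tp[tp] = pd.DataFrame(
            {"qualifies": qual, "log2_fc": f["log2_fc"], "fdr": f["fdr"]}
        )

    rows = []
    counts = {tp: {"up": 0, "down": 0} for tp in de}
    for gene in sorted(bound):
        best_tp, best_fdr = None, np.inf
        dirs = set()
        directions_by_tp = {}
        for tp, f in per_tp.items():
            if gene in f.index and bool(f.loc[gene, "qualifies"]):
                d = "up" if f.loc[gene, "log2_fc"] > 0 else "down"
                dirs.add(d)
                directions_by_tp[tp] = d
                counts[tp][d] += 1
                if f.loc[gene, "fdr"] < best_fdr:
                    best_fdr, best_tp = float(f.loc[gene, "fdr"]), tp
        de_any = best_tp is not None
        rows.append(
            {
                "gene": gene,
                "bound": True,
                "de_any_timepoint": de_any,
                "direction": directions_by_tp.get(best_tp, "none") if de_any else "none",
                "best_time_point": best_tp,
                "direction_conflict": len(dirs) > 1,
            }
        )
    targets = pd.DataFrame(
        rows,
        columns=["gene", "bound", "de_any_timepoint", "direction",
                 "best_time_point", "direction_conflict"],
    )
    counts_frame = pd.DataFrame(
        [{"time_point": tp, "n_up": c["up"], "n_down": c["down"]} for tp, c in counts.items()]
    )
    return targets, counts_frame
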