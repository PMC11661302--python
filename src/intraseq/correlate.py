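"""Cell-type-level RNA-protein concordance.

For each antibody, normalized protein values are averaged per cell type and
correlated (Pearson) against the per-type averages of the encoding gene's
normalized RNA. Two-sided p-values come from the exact t transform
t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom, where n is
the number of cell types; Benjamini-Hochberg adjustment is applied across
all antibody/gene pairs in the run, and each pair is classified as
significantly positive (FDR < 0.05, r > 0), negative (FDR < 0.05, r < 0) or
minimal otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix, PanelManifest, ValidationError

CLASS_POSITIVE = "significant_positive"
CLASS_NEGATIVE = "negative"
CLASS_MINIMAL = "minimal"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j),
    clipped to 1. Equal inputs receive equal adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def celltype_means(values: NormalizedMatrix, labels: pd.Series | dict) -> pd.DataFrame:
    """Arithmetic mean of normalized values per cell type.

    ``labels`` maps every cell in ``values`` to a type; the result has one
    row per type (sorted by name) and one column per feature.
    """
    labels = pd.Series(labels)
    missing = [c for c in values.cells if c not in labels.index]
    if missing:
        raise ValidationError(f"unlabeled cells: {missing[:5]}")
    frame = values.to_frame()
    groups = labels.reindex(values.cells)
    means = frame.groupby(groups.to_numpy()).mean()
    return means.sort_index()


def pearson_with_t_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and the two-sided p-value from the t transform with n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValidationError("zero variance")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def rna_protein_correlation(
    rna_means: pd.DataFrame,
    adt_means: pd.DataFrame,
    manifest: PanelManifest,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-antibody correlation records across cell-type means.

    Antibodies whose encoding gene is absent from ``rna_means`` are reported
    with ``skipped = True``; zero-variance pairs are flagged ``degenerate``
    with undefined r and no concordance class. BH adjustment spans all
    non-degenerate pairs in the call.
    """
    shared = sorted(set(rna_means.index) & set(adt_means.index))
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared cell types, found {len(shared)}")
    rna_means = rna_means.loc[shared]
    adt_means = adt_means.loc[shared]

    rows = []
    for _, entry in manifest.entries.iterrows():
        ab, gene, klass = entry["antibody"], entry["encoding_gene"], entry["target_class"]
        rec = {
            "antibody": ab, "gene": gene, "target_class": klass,
            "r": np.nan, "p": np.nan, "fdr": np.nan,
            "n_types": len(shared), "concordance_class": None,
            "degenerate": False, "skipped": False,
        }
        if ab not in adt_means.columns or gene not in rna_means.columns:
            rec["skipped"] = True
            rows.append(rec)
            continue
        x = rna_means[gene].to_numpy()
        y = adt_means[ab].to_numpy()
        try:
            r, p = pearson_with_t_pvalue(x, y)
        except ValidationError:
            rec["degenerate"] = True
            rows.append(rec)
            continue
        rec["r"], rec["p"] = r, p
        rows.append(rec)

    records = pd.DataFrame(rows)
    testable = records["p"].notna()
    if testable.any():
        records.loc[testable, "fdr"] = bh_adjust(records.loc[testable, "p"].to_numpy())
        sig = testable & (records["fdr"] < fdr_threshold)
        records.loc[testable, "concordance_class"] = CLASS_MINIMAL
        records.loc[sig & (records["r"] > 0), "concordance_class"] = CLASS_POSITIVE
        records.loc[sig & (records["r"] < 0), "concordance_class"] = CLASS_NEGATIVE
    return records
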