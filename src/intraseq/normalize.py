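"""Normalization of RNA, ADT and PTM-ratio channels.

RNA UMI counts are log-normalized per cell with a scale factor of 10,000:
``ln(1 + count / cell_total * scale)``. ADT counts are transformed with the
centered log-ratio (CLR) across cells: for each antibody,
``ln(count + 1) - mean_cells ln(count + 1)``, i.e. the log deviation from
that antibody's geometric mean over cells. For PTM antibodies with a
measured total-protein partner, the per-cell ratio
``(ptm + 1) / (total + 1)`` is formed first and then CLR-transformed across
cells, which shrinks extreme ratios. Natural log throughout; the method and
its parameters are recorded on the output for auditability.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    CountMatrix,
    NormalizedMatrix,
    PanelManifest,
    ValidationError,
)


def lognormalize_rna(matrix: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Per-cell library-size normalization followed by log1p."""
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be > 0")
    totals = matrix.cell_totals().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cells with zero total UMIs (remove in QC first): "
            f"{[matrix.cells[i] for i in zero[:5]]}"
        )
    dense = matrix.dense().astype(float)
    values = np.log1p(dense / totals[:, None] * scale_factor)
    return NormalizedMatrix(
        cells=list(matrix.cells),
        features=list(matrix.features),
        values=values,
        method="rna_lognorm",
        parameters={"scale_factor": scale_factor, "log_base": "e"},
    )


def clr_across_cells(matrix: CountMatrix, pseudo_count: float = 1.0) -> NormalizedMatrix:
    """Centered log-ratio per feature across cells.

    value(c, f) = ln(count + pseudo) - mean over cells of ln(count + pseudo);
    each feature's values sum to zero across cells.
    """
    if pseudo_count <= 0:
        raise ValidationError("pseudo_count must be > 0")
    if matrix.n_cells == 0:
        raise ValidationError("cannot CLR-transform an empty matrix")
    logs = np.log(matrix.dense().astype(float) + pseudo_count)
    values = logs - logs.mean(axis=0, keepdims=True)
    return NormalizedMatrix(
        cells=list(matrix.cells),
        features=list(matrix.features),
        values=values,
        method="adt_clr",
        parameters={"pseudo_count": pseudo_count, "log_base": "e",
                    "formula": "ln(count + pc) centered per feature across cells"},
    )


def ptm_ratio(
    adt: CountMatrix, manifest: PanelManifest, pseudo_count: float = 1.0
) -> NormalizedMatrix:
    """PTM-to-total-protein ratio, CLR-transformed across cells.

    For each PTM antibody with partner total-protein antibody,
    ratio(c) = (ptm_count + pc) / (total_count + pc); the output is the
    across-cells CLR of these strictly positive ratios (no second
    pseudo-count inside the CLR), one column per PTM antibody.
    """
    if pseudo_count <= 0:
        raise ValidationError("pseudo_count must be > 0")
    if adt.n_cells == 0:
        raise ValidationError("cannot compute PTM ratios on an empty matrix")
    pairs = manifest.ptm_pairs()
    if not pairs:
        raise ValidationError("panel has no PTM antibodies")
    missing = [ab for pair in pairs for ab in pair if ab not in adt.features]
    if missing:
        raise ValidationError(f"antibodies missing from ADT matrix: {sorted(set(missing))}")
    dense = adt.dense().astype(float)
    cols = []
    for ptm_ab, total_ab in pairs:
        num = dense[:, adt.feature_index(ptm_ab)] + pseudo_count
        den = dense[:, adt.feature_index(total_ab)] + pseudo_count
        log_ratio = np.log(num / den)
        cols.append(log_ratio - log_ratio.mean())
    values = np.column_stack(cols)
    return NormalizedMatrix(
        cells=list(adt.cells),
        features=[p for p, _ in pairs],
        values=values,
        method="ptm_ratio_clr",
        parameters={"pseudo_count": pseudo_count, "log_base": "e",
                    "formula": "CLR across cells of (ptm + pc)/(total + pc)"},
    )
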