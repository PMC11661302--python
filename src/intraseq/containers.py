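"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of data around: sparse UMI count matrices
tagged with a modality (``RNA`` or ``ADT``), per-molecule read-count tables
that allow read-level thinning, and the antibody panel manifest that maps
each antibody to its encoding gene and, for PTM antibodies, to the matching
total-protein antibody.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

RNA = "RNA"
ADT = "ADT"

SURFACE = "surface"
INTRACELLULAR = "intracellular"
PTM = "PTM"

_TARGET_CLASSES = (SURFACE, INTRACELLULAR, PTM)


class ValidationError(ValueError):
    """Raised when an input violates a container or operation contract."""


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        seen, dups = set(), set()
        for n in names:
            if n in seen:
                dups.add(n)
            seen.add(n)
        raise ValidationError(f"duplicate {what} identifiers: {sorted(dups)[:5]}")


@dataclass
class CountMatrix:
    """Sparse cell-by-feature matrix of non-negative integer UMI counts.

    Parameters
    ----------
    cells
        Ordered cell barcodes (rows).
    features
        Ordered feature names (columns): gene symbols for RNA, antibody
        names for ADT.
    counts
        ``(n_cells, n_features)`` matrix; any scipy sparse type or a dense
        array is accepted and stored as CSR.
    modality
        ``"RNA"`` or ``"ADT"``.
    """

    cells: list[str]
    features: list[str]
    counts: sp.csr_matrix
    modality: str = RNA

    def __post_init__(self) -> None:
        self.cells = [str(c) for c in self.cells]
        self.features = [str(f) for f in self.features]
        _check_unique(self.cells, "cell")
        _check_unique(self.features, "feature")
        if self.modality not in (RNA, ADT):
            raise ValidationError(f"unknown modality {self.modality!r}")
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.cells), len(self.features)):
            raise ValidationError(
                f"counts shape {m.shape} does not match "
                f"({len(self.cells)} cells, {len(self.features)} features)"
            )
        if m.nnz:
            data = m.data
            if np.any(data < 0):
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts must be integral")
        self.counts = m.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of features with a nonzero count per cell."""
        return np.diff(self.counts.indptr)

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        """New matrix keeping rows ``index`` in the given order."""
        index = np.asarray(index)
        return CountMatrix(
            cells=[self.cells[i] for i in index],
            features=list(self.features),
            counts=self.counts[index],
            modality=self.modality,
        )

    def feature_index(self, name: str) -> int:
        try:
            return self.features.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in matrix") from None

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.cells == other.cells
            and self.features == other.features
            and self.modality == other.modality
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class MoleculeTable:
    """Per-molecule records: (cell, feature, umi, reads).

    ``reads`` is the number of sequencing reads supporting the UMI; every
    observed molecule has at least one read. (cell, feature, umi) triples
    are unique.
    """

    records: pd.DataFrame

    COLUMNS = ("cell", "feature", "umi", "reads")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"molecule table missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if len(df):
            reads = df["reads"].to_numpy()
            if np.any(reads < 1):
                raise ValidationError("molecule reads must be >= 1")
            if df.duplicated(subset=["cell", "feature", "umi"]).any():
                raise ValidationError("(cell, feature, umi) triples must be unique")
        df["reads"] = df["reads"].astype(np.int64)
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def total_reads(self) -> int:
        return int(self.records["reads"].sum())

    def n_cells(self) -> int:
        return self.records["cell"].nunique()

    def mean_reads_per_cell(self) -> float:
        n = self.n_cells()
        if n == 0:
            raise ValidationError("empty molecule table has no mean reads per cell")
        return self.total_reads() / n

    def median_reads_per_cell(self) -> float:
        per_cell = self.records.groupby("cell", sort=False)["reads"].sum()
        if per_cell.empty:
            raise ValidationError("empty molecule table has no median reads per cell")
        return float(per_cell.median())

    def to_umi_matrix(
        self,
        cells: Sequence[str] | None = None,
        features: Sequence[str] | None = None,
        modality: str = RNA,
    ) -> CountMatrix:
        """Rebuild the UMI count matrix by counting molecules per (cell, feature).

        When ``cells``/``features`` are omitted the sorted unique identifiers
        present in the table are used.
        """
        df = self.records
        if cells is None:
            cells = sorted(df["cell"].unique())
        if features is None:
            features = sorted(df["feature"].unique())
        cells = list(cells)
        features = list(features)
        ci = {c: i for i, c in enumerate(cells)}
        fi = {f: i for i, f in enumerate(features)}
        if len(df):
            rows = df["cell"].map(ci)
            cols = df["feature"].map(fi)
            if rows.isna().any() or cols.isna().any():
                raise ValidationError("molecule table contains cells/features outside the given universe")
            mat = sp.coo_matrix(
                (np.ones(len(df), dtype=np.int64), (rows.to_numpy(int), cols.to_numpy(int))),
                shape=(len(cells), len(features)),
            ).tocsr()
        else:
            mat = sp.csr_matrix((len(cells), len(features)), dtype=np.int64)
        return CountMatrix(cells=cells, features=features, counts=mat, modality=modality)

    def equals(self, other: "MoleculeTable") -> bool:
        key = ["cell", "feature", "umi"]
        a = self.records.sort_values(key).reset_index(drop=True)
        b = other.records.sort_values(key).reset_index(drop=True)
        return a.equals(b)


@dataclass
class PanelManifest:
    """Antibody panel: antibody -> encoding gene, target class, PTM pairing.

    ``target_class`` is one of ``surface``, ``intracellular`` or ``PTM``;
    a PTM antibody must name the panel antibody that measures the matching
    total (unmodified) protein in ``total_partner``.
    """

    entries: pd.DataFrame

    COLUMNS = ("antibody", "encoding_gene", "target_class", "total_partner")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"panel manifest missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["total_partner"] = df["total_partner"].where(pd.notna(df["total_partner"]), None)
        df["total_partner"] = df["total_partner"].replace("", None)
        _check_unique(list(df["antibody"]), "antibody")
        bad = ~df["target_class"].isin(_TARGET_CLASSES)
        if bad.any():
            raise ValidationError(
                f"unknown target_class values: {sorted(df.loc[bad, 'target_class'].unique())}"
            )
        names = set(df["antibody"])
        cls = dict(zip(df["antibody"], df["target_class"]))
        for _, row in df.iterrows():
            if row["target_class"] == PTM:
                partner = row["total_partner"]
                if partner is None:
                    raise ValidationError(f"PTM antibody {row['antibody']!r} lacks a total_partner")
                if partner not in names:
                    raise ValidationError(
                        f"total_partner {partner!r} of {row['antibody']!r} is not in the panel"
                    )
                if cls[partner] == PTM:
                    raise ValidationError(
                        f"total_partner {partner!r} of {row['antibody']!r} must not itself be a PTM antibody"
                    )
            elif row["total_partner"] is not None:
                raise ValidationError(
                    f"non-PTM antibody {row['antibody']!r} must not declare a total_partner"
                )
        self.entries = df

    @property
    def antibodies(self) -> list[str]:
        return list(self.entries["antibody"])

    def ptm_pairs(self) -> list[tuple[str, str]]:
        """(PTM antibody, total-protein partner antibody) pairs."""
        ptm = self.entries[self.entries["target_class"] == PTM]
        return list(zip(ptm["antibody"], ptm["total_partner"]))

    def encoding_gene(self, antibody: str) -> str:
        row = self.entries[self.entries["antibody"] == antibody]
        if row.empty:
            raise KeyError(antibody)
        return str(row["encoding_gene"].iloc[0])

    def target_class(self, antibody: str) -> str:
        row = self.entries[self.entries["antibody"] == antibody]
        if row.empty:
            raise KeyError(antibody)
        return str(row["target_class"].iloc[0])

    def equals(self, other: "PanelManifest") -> bool:
        return self.entries.equals(other.entries)


@dataclass
class NormalizedMatrix:
    """Dense real-valued cell-by-feature matrix with a record of how it was made.

    ``method`` is one of ``rna_lognorm``, ``adt_clr`` or ``ptm_ratio_clr``;
    ``parameters`` stores the scale factor / pseudo-count and the log base so
    downstream output is auditable.
    """

    cells: list[str]
    features: list[str]
    values: np.ndarray
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = [str(c) for c in self.cells]
        self.features = [str(f) for f in self.features]
        _check_unique(self.cells, "cell")
        _check_unique(self.features, "feature")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.cells), len(self.features)):
            raise ValidationError(
                f"values shape {v.shape} does not match "
                f"({len(self.cells)} cells, {len(self.features)} features)"
            )
        if v.size and not np.all(np.isfinite(v)):
            raise ValidationError("normalized values must be finite")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.features)

    def feature_values(self, name: str) -> np.ndarray:
        try:
            j = self.features.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in matrix") from None
        return self.values[:, j]
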