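"""Readers and writers for the on-disk formats the pipeline exchanges.

Count matrices travel as Matrix Market triplets with companion
``barcodes.tsv`` / ``features.tsv`` name files (one identifier per line),
the layout emitted by the common droplet pipelines, except matrices here
are stored cells-by-features. Molecule tables, panel manifests and cell
annotations are plain CSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import CountMatrix, MoleculeTable, PanelManifest, ValidationError


def write_count_matrix(matrix: CountMatrix, directory: str | os.PathLike, prefix: str = "") -> list[Path]:
    """Write ``<prefix>matrix.mtx`` + ``<prefix>barcodes.tsv`` + ``<prefix>features.tsv``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    try:
        mtx = d / f"{prefix}matrix.mtx"
        mmwrite(str(mtx), matrix.counts.tocoo(), field="integer")
        paths.append(mtx)
        bc = d / f"{prefix}barcodes.tsv"
        bc.write_text("".join(f"{c}\n" for c in matrix.cells))
        paths.append(bc)
        ft = d / f"{prefix}features.tsv"
        ft.write_text("".join(f"{f}\t{matrix.modality}\n" for f in matrix.features))
        paths.append(ft)
    except OSError as exc:
        raise OSError(f"failed writing {exc.filename or directory}: {exc}") from exc
    return paths


def read_count_matrix(directory: str | os.PathLike, prefix: str = "") -> CountMatrix:
    d = Path(directory)
    counts = sp.csr_matrix(mmread(str(d / f"{prefix}matrix.mtx")))
    cells = (d / f"{prefix}barcodes.tsv").read_text().splitlines()
    feat_lines = (d / f"{prefix}features.tsv").read_text().splitlines()
    features, modalities = [], set()
    for line in feat_lines:
        parts = line.split("\t")
        features.append(parts[0])
        if len(parts) > 1:
            modalities.add(parts[1])
    if len(modalities) > 1:
        raise ValidationError(f"mixed modalities in features file: {sorted(modalities)}")
    modality = modalities.pop() if modalities else "RNA"
    # mmread of an empty-shape matrix still carries the header dimensions
    if counts.shape != (len(cells), len(features)):
        raise ValidationError(
            f"matrix shape {counts.shape} does not match names "
            f"({len(cells)} barcodes, {len(features)} features)"
        )
    return CountMatrix(cells=cells, features=features, counts=counts, modality=modality)


def write_molecule_table(molecules: MoleculeTable, path: str | os.PathLike) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    molecules.records.to_csv(p, index=False)
    return p


def read_molecule_table(path: str | os.PathLike) -> MoleculeTable:
    df = pd.read_csv(path, dtype={"cell": str, "feature": str, "umi": str})
    if df.empty:
        df = pd.DataFrame(columns=list(MoleculeTable.COLUMNS))
    return MoleculeTable(records=df)


def write_manifest(manifest: PanelManifest, path: str | os.PathLike) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    manifest.entries.to_csv(p, index=False)
    return p


def read_manifest(path: str | os.PathLike) -> PanelManifest:
    df = pd.read_csv(path, dtype=str)
    return PanelManifest(entries=df)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path: str | os.PathLike) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text("".join(f"{g}\n" for g in genes))
    return p
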