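"""Readers and writers for count matrices, gene signatures and run configs.

Count matrices are stored cells-as-rows in memory. On disk the Matrix Market
layout follows the common 10x convention (genes as rows) and is transposed on
read/write. Mitochondrial genes are recognized by the "MT-" symbol prefix,
case-insensitively.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml


class CountMatrixError(ValueError):
    """Malformed count-matrix input (negative, non-integer, duplicate ids)."""


class SignatureError(ValueError):
    """Malformed gene-signature input (empty list, duplicate names)."""


MITO_PREFIX = "MT-"


def _mito_mask_from_symbols(gene_ids: list[str]) -> np.ndarray:
    return np.array([g.upper().startswith(MITO_PREFIX) for g in gene_ids], dtype=bool)


@dataclass
class CountMatrix:
    """Integer UMI counts, cells x genes, with barcode and gene identifiers."""

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    mito_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise CountMatrixError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise CountMatrixError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountMatrixError("duplicate gene identifiers")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise CountMatrixError("negative count")
            if not np.allclose(data, np.round(data)):
                raise CountMatrixError("non-integer count")
        if self.mito_mask is None:
            self.mito_mask = _mito_mask_from_symbols(self.gene_ids)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        if self.mito_mask.size != len(self.gene_ids):
            raise CountMatrixError("mito_mask length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask, bool)
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask, bool)
        return CountMatrix(
            counts=self.counts[cm][:, gm],
            cell_ids=[c for c, m in zip(self.cell_ids, cm) if m],
            gene_ids=[g for g, m in zip(self.gene_ids, gm) if m],
            mito_mask=self.mito_mask[gm],
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)


@dataclass
class GeneSignatureSet:
    """Named, ordered gene lists (e.g. the GEP1/GEP2 prognostic signatures)."""

    signatures: dict[str, list[str]]

    def __post_init__(self):
        for name, genes in self.signatures.items():
            if not genes:
                raise SignatureError(f"empty signature: {name}")
            if len(set(genes)) != len(genes):
                raise SignatureError(f"duplicate genes within signature: {name}")

    def __getitem__(self, name: str) -> list[str]:
        return self.signatures[name]

    def names(self) -> list[str]:
        return list(self.signatures)


@dataclass
class RunConfig:
    """All stage parameters of a run; a serialized config determines a run."""

    seed: int = 0
    # QC
    min_cells_per_gene: int = 10
    mito_max: float = 0.25
    target_variance: float = 0.90
    n_pcs_requested: int = 50
    # imputation graph
    impute_k: int = 27
    impute_ka: int = 12
    impute_t: int = 3
    impute_n_pcs: int = 20
    # clustering
    cluster_k: int = 35
    stability_threshold: float = 0.75
    # classification / bootstrap
    bootstrap_n_cells: int = 500
    bootstrap_n_rounds: int = 20
    # phenotypic volume
    volume_n_cells: int = 150
    volume_n_repeats: int = 100
    # archetypes
    n_archetypes: int = 8
    diffusion_components: int = 5
    emd_n_resamples: int = 100

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# count-matrix I/O

def read_counts(path, format: str = "mtx-dir") -> CountMatrix:
    """Read a count matrix from an mtx directory (10x layout) or dense CSV.

    mtx-dir: ``matrix.mtx`` (genes x cells triplets), ``barcodes.tsv``,
    ``features.tsv`` (or ``genes.tsv``). dense-csv: header row of gene
    symbols, first column of cell barcodes.
    """
    path = Path(path)
    if format == "mtx-dir":
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        if not features.exists():
            features = path / "genes.tsv"
        for f in (mtx, barcodes, features):
            if not f.exists():
                raise FileNotFoundError(f"missing required file: {f}")
        mat = scipy.io.mmread(str(mtx))
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        feat = pd.read_csv(features, sep="\t", header=None)
        # features.tsv may be one column (symbol) or 10x two-plus columns
        # (id, symbol, ...); prefer the symbol column.
        gene_ids = (feat[1] if feat.shape[1] > 1 else feat[0]).astype(str).tolist()
        mat = sp.csr_matrix(mat)
        if mat.shape == (len(gene_ids), len(cell_ids)):
            mat = mat.T.tocsr()  # 10x convention: genes as rows
        elif mat.shape != (len(cell_ids), len(gene_ids)):
            raise CountMatrixError(
                f"matrix shape {mat.shape} matches neither orientation for "
                f"{len(cell_ids)} barcodes x {len(gene_ids)} features"
            )
        return CountMatrix(counts=mat, cell_ids=cell_ids, gene_ids=gene_ids)
    if format == "dense-csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(
            counts=sp.csr_matrix(df.to_numpy()),
            cell_ids=df.index.astype(str).tolist(),
            gene_ids=df.columns.astype(str).tolist(),
        )
    raise ValueError(f"unknown format: {format}")


def write_counts(cm: CountMatrix, path, format: str = "mtx-dir") -> None:
    """Write a CountMatrix; inverse of :func:`read_counts` for both formats."""
    path = Path(path)
    if format == "mtx-dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(cm.counts.T))
        (path / "barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n")
        (path / "features.tsv").write_text(
            "\n".join(f"{g}\t{g}" for g in cm.gene_ids) + "\n"
        )
        return
    if format == "dense-csv":
        df = pd.DataFrame(cm.to_dense().astype(int), index=cm.cell_ids, columns=cm.gene_ids)
        df.to_csv(path)
        return
    raise ValueError(f"unknown format: {format}")


# ---------------------------------------------------------------------------
# signature I/O

def load_signatures(path, format: str | None = None) -> GeneSignatureSet:
    """Load gene signatures from GMT (name, description, genes...) or JSON
    (name -> list) files."""
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "json"
    sigs: dict[str, list[str]] = {}
    if format == "gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SignatureError(f"GMT line with no genes: {fields[0] if fields else ''}")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if name in sigs:
                raise SignatureError(f"duplicate name: {name}")
            sigs[name] = genes
    elif format == "json":
        data = json.loads(path.read_text())
        for name, genes in data.items():
            if name in sigs:
                raise SignatureError(f"duplicate name: {name}")
            sigs[name] = list(genes)
    else:
        raise ValueError(f"unknown format: {format}")
    return GeneSignatureSet(sigs)


def restrict_signatures(
    sigs: GeneSignatureSet, gene_ids: list[str]
) -> GeneSignatureSet:
    """Drop signature genes absent from a matrix, warning per signature."""
    present = set(gene_ids)
    out = {}
    for name, genes in sigs.signatures.items():
        kept = [g for g in genes if g in present]
        if not kept:
            raise SignatureError(f"no genes of signature {name!r} present in matrix")
        if len(kept) < len(genes):
            warnings.warn(
                f"signature {name!r}: {len(genes) - len(kept)} gene(s) absent "
                "from matrix, dropped"
            )
        out[name] = kept
    return GeneSignatureSet(out)
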