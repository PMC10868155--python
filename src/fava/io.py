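"""Readers and writers for expression matrices, networks and gold standards.

Orientation convention: genes are rows, conditions (cells/samples) are
columns, because the autoencoder compresses the condition dimension and each
gene is one observation. AnnData/h5ad containers conventionally store
cells x genes, so that format is transposed on load.

Gene identifiers are taken verbatim; no mapping between Ensembl/UniProt/
symbol namespaces is attempted. Mismatches between a matrix and a gold
standard surface as coverage statistics downstream, never as errors here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .benchmark import GoldStandard
from .network import ScoredNetwork, canonical_sort

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "write_network",
    "read_network",
    "read_gold_standard",
]

_FORMATS = ("tsv", "csv", "mtx", "h5ad")


@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of finite non-negative values."""

    genes: list[str]
    conditions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.conditions)} conditions"
            )
        if len(self.genes) < 2 or len(self.conditions) < 2:
            raise ValueError("need at least 2 genes and 2 conditions")
        dup = pd.Index(self.genes)[pd.Index(self.genes).duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene identifiers: {list(dup)}")
        if not np.isfinite(self.values).all():
            raise ValueError("matrix contains NaN/Inf after loading")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.genes[i]!r}, "
                f"condition {self.conditions[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.conditions)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _read_dense(path: Path, sep: str) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gi, ci = np.argwhere(bad.values)[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[gi, ci]!r} at "
            f"gene {df.index[gi]!r}, condition {df.columns[ci]!r}"
        )
    values = numeric.fillna(0.0).to_numpy(dtype=float)  # missing/NA -> 0
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        conditions=[str(c) for c in df.columns],
        values=values,
    )


def _sidecar(path: Path, ext: str) -> Path:
    cand = path.with_suffix(ext)
    if not cand.exists():
        raise FileNotFoundError(f"missing sidecar file {cand} for {path}")
    return cand


def _read_mtx(path: Path) -> ExpressionMatrix:
    genes = _sidecar(path, ".rows").read_text().split()
    conditions = _sidecar(path, ".cols").read_text().split()
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    return ExpressionMatrix(genes, conditions, np.asarray(mat, dtype=float))


def _read_h5ad(path: Path) -> ExpressionMatrix:
    import anndata

    adata = anndata.read_h5ad(path)
    x = adata.X
    if scipy.sparse.issparse(x):
        x = x.toarray()
    # AnnData is cells x genes; transpose so genes are rows
    return ExpressionMatrix(
        genes=[str(g) for g in adata.var_names],
        conditions=[str(c) for c in adata.obs_names],
        values=np.asarray(x, dtype=float).T,
    )


def read_matrix(path, format: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix, normalizing orientation to genes-as-rows.

    Supported formats: dense ``tsv``/``csv`` (header row of condition names,
    first column of gene names), MatrixMarket ``mtx`` with ``.rows``/``.cols``
    sidecar name files, and ``h5ad`` AnnData containers (transposed on load).
    Missing values become 0; NaN/Inf, negative values and duplicate gene ids
    are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        return _read_dense(path, "\t")
    if fmt == "csv":
        return _read_dense(path, ",")
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt in ("h5ad", "h5ad-like"):
        return _read_h5ad(path)
    raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_matrix(m: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write an expression matrix in any supported format (inverse of read)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        m.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        path.with_suffix(".rows").write_text("\n".join(m.genes) + "\n")
        path.with_suffix(".cols").write_text("\n".join(m.conditions) + "\n")
    elif fmt in ("h5ad", "h5ad-like"):
        import anndata

        adata = anndata.AnnData(
            X=m.values.T.copy(),
            obs=pd.DataFrame(index=pd.Index(m.conditions, name="condition")),
            var=pd.DataFrame(index=pd.Index(m.genes, name="gene")),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_network(net: ScoredNetwork, path) -> None:
    """Serialize a network as TSV: gene1, gene2, score[, probability].

    Rows are sorted by score descending, ties by (gene1, gene2) ascending,
    so re-serializing a parsed network is byte-identical.
    """
    if len(net) == 0:
        raise ValueError("refusing to write an empty network")
    cols = ["gene1", "gene2", "score"]
    if net.is_calibrated:
        cols.append("probability")
    table = canonical_sort(net.table[cols])
    table.to_csv(path, sep="\t", index=False)


def read_network(path) -> ScoredNetwork:
    """Parse a network TSV written by :func:`write_network`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene1": str, "gene2": str},
        float_precision="round_trip",  # exact re-serialization of scores
    )
    if not {"gene1", "gene2", "score"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns gene1, gene2, score")
    return ScoredNetwork(canonical_sort(df))


def read_gold_standard(path, mode: str) -> GoldStandard:
    """Read a two-column TSV gold standard.

    membership mode: rows are (gene, group); pairs mode: rows are
    (gene, gene), symmetric duplicates collapse to one canonical pair and
    self-pairs are dropped (their count is reported via the returned
    object's ``n_self_pairs_dropped`` attribute).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty gold-standard file")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns, got {df.shape[1]}")
    a, b = df[0], df[1]
    if mode == "membership":
        membership: dict[str, set[str]] = {}
        for gene, group in zip(a, b):
            membership.setdefault(gene, set()).add(group)
        return GoldStandard.from_membership(membership)
    if mode == "pairs":
        n_self = int((a == b).sum())
        gs = GoldStandard.from_pairs(zip(a, b))
        gs.n_self_pairs_dropped = n_self
        return gs
    raise ValueError(f"unknown gold-standard mode {mode!r}")
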