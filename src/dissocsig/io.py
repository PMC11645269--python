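"""Readers/writers for the plain-text single-cell exchange formats.

The on-disk contract is the 10x-style triplet: ``matrix.mtx`` (Matrix Market
coordinate, integer, genes x cells), ``features.tsv`` and ``barcodes.tsv``
with one entry per line. Cell annotations are a TSV with header; gene lists
are one symbol per line. Counts are stored as 64-bit integers and are never
mutated after loading: every normalisation produces a new matrix.

Matrix orientation is fixed as genes x cells. Transposed inputs are not
auto-detected; a dimension mismatch is an error naming the offending files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import io as spio

from .errors import FormatError, ValidationError

RESERVED_ANNOTATION_COLUMNS = ("barcode", "sample_id", "group", "cell_class")


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise ValidationError(f"duplicate {what}: {n!r}")
            seen.add(n)


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer UMI counts.

    Parameters
    ----------
    genes
        Gene symbols, one per row; unique after whitespace trimming.
    barcodes
        Cell identifiers, one per column; unique.
    counts
        Any scipy sparse matrix of shape ``(len(genes), len(barcodes))``;
        coerced to CSR int64 with explicit zeros removed.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = [g.strip() for g in self.genes]
        self.barcodes = [b.strip() for b in self.barcodes]
        _check_unique(self.genes, "gene symbol")
        _check_unique(self.barcodes, "barcode")
        counts = sp.csr_matrix(self.counts)
        if counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        counts = counts.astype(np.int64)
        counts.eliminate_zeros()
        counts.sort_indices()
        self.counts = counts

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def subset_cells(self, keep: np.ndarray | Sequence[int]) -> "CountMatrix":
        """New matrix restricted to the given cell positions (bool mask or indices)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        barcodes = [self.barcodes[i] for i in keep]
        return CountMatrix(list(self.genes), barcodes, self.counts[:, keep])

    def subset_genes(self, keep: np.ndarray | Sequence[int]) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        genes = [self.genes[i] for i in keep]
        return CountMatrix(genes, list(self.barcodes), self.counts[keep, :])


@dataclass
class NormalizedMatrix:
    """Gene x cell matrix of log-normalised expression (float, sparse)."""

    genes: list[str]
    barcodes: list[str]
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        _check_unique(self.genes, "gene symbol")
        _check_unique(self.barcodes, "barcode")
        values = sp.csr_matrix(self.values).astype(np.float64)
        if values.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        values.sort_indices()
        self.values = values

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def subset_cells(self, keep: np.ndarray | Sequence[int]) -> "NormalizedMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        barcodes = [self.barcodes[i] for i in keep]
        return NormalizedMatrix(list(self.genes), barcodes, self.values[:, keep])


@dataclass
class CellAnnotations:
    """Per-cell sample/group/class labels plus per-sample numeric covariates.

    Wraps a DataFrame indexed by barcode with columns ``sample_id``,
    ``group``, optionally ``cell_class``, and any number of covariate
    columns that are constant within each sample.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "barcode":
            if "barcode" in df.columns:
                df = df.set_index("barcode")
            else:
                raise ValidationError("annotations need a 'barcode' column or index")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate barcode in annotations: {dup!r}")
        for col in ("sample_id", "group"):
            if col not in df.columns:
                raise ValidationError(f"annotations missing required column {col!r}")
        # group and covariates must be constant within a sample
        for col in df.columns:
            if col in ("sample_id", "cell_class"):
                continue
            nun = df.groupby("sample_id", sort=False)[col].nunique(dropna=True)
            bad = nun[nun > 1]
            if len(bad):
                raise ValidationError(
                    f"column {col!r} varies within sample {bad.index[0]!r}"
                )
        self.df = df

    @property
    def barcodes(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in RESERVED_ANNOTATION_COLUMNS]

    def sample_table(self) -> pd.DataFrame:
        """One row per sample: group plus covariates (constant within sample)."""
        cols = ["group"] + self.covariate_columns
        return (
            self.df.groupby("sample_id", sort=True)[cols]
            .first()
            .sort_index()
        )

    def subset(self, barcodes: Sequence[str]) -> "CellAnnotations":
        missing = [b for b in barcodes if b not in self.df.index]
        if missing:
            raise ValidationError(f"barcode not in annotations: {missing[0]!r}")
        return CellAnnotations(self.df.loc[list(barcodes)].copy())


@dataclass
class GeneList:
    """An ordered, named gene signature."""

    name: str
    species: str
    symbols: list[str]

    def __post_init__(self) -> None:
        self.symbols = [s.strip() for s in self.symbols]
        if not self.symbols:
            raise ValidationError(f"gene list {self.name!r} is empty")
        if any(not s for s in self.symbols):
            raise ValidationError(f"gene list {self.name!r} contains an empty symbol")
        _check_unique(self.symbols, f"symbol in gene list {self.name!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_counts(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a matrix.mtx / features.tsv / barcodes.tsv triplet.

    The result is independent of the order of the triplet lines in the
    ``.mtx`` file. Dimension mismatches and non-integer entries are format
    errors naming the file (and, for values, the line number).
    """
    genes = [line.split("\t")[0] for line in _read_lines(features_path)]
    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]
    try:
        mat = spio.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"{mtx_path}: invalid Matrix Market file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"dimension mismatch: {mtx_path} declares "
            f"{mat.shape[0]} x {mat.shape[1]} but {features_path} has "
            f"{len(genes)} entries and {barcodes_path} has {len(barcodes)}"
        )
    if not np.issubdtype(mat.dtype, np.integer):
        frac = mat.data % 1 != 0
        if frac.any():
            raise FormatError(
                f"{mtx_path}: non-integer value at line "
                f"{_find_noninteger_line(mtx_path)}"
            )
        mat = mat.astype(np.int64)
    return CountMatrix(genes, barcodes, mat.tocsr())


def _find_noninteger_line(mtx_path: str | Path) -> int:
    with open(mtx_path) as fh:
        past_header = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("%"):
                continue
            if not past_header:  # dimensions line
                past_header = True
                continue
            parts = line.split()
            if len(parts) >= 3:
                try:
                    if float(parts[2]) % 1 != 0:
                        return lineno
                except ValueError:
                    return lineno
    return -1


def write_counts(m: CountMatrix, dir_path: str | Path) -> dict[str, Path]:
    """Write the triplet files; ``read_counts`` on the result is the identity."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    mtx = out / "matrix.mtx"
    spio.mmwrite(str(mtx), m.counts.tocoo(), field="integer")
    features = out / "features.tsv"
    features.write_text("".join(g + "\n" for g in m.genes))
    barcodes = out / "barcodes.tsv"
    barcodes.write_text("".join(b + "\n" for b in m.barcodes))
    return {"matrix": mtx, "features": features, "barcodes": barcodes}


def write_normalized(m: NormalizedMatrix, dir_path: str | Path) -> dict[str, Path]:
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    mtx = out / "matrix.mtx"
    spio.mmwrite(str(mtx), m.values.tocoo(), field="real", precision=17)
    (out / "features.tsv").write_text("".join(g + "\n" for g in m.genes))
    (out / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))
    return {"matrix": mtx}


def read_normalized(dir_path: str | Path) -> NormalizedMatrix:
    out = Path(dir_path)
    genes = _read_lines(out / "features.tsv")
    barcodes = _read_lines(out / "barcodes.tsv")
    mat = sp.csr_matrix(spio.mmread(str(out / "matrix.mtx")))
    return NormalizedMatrix(genes, barcodes, mat)


def read_counts_dir(dir_path: str | Path) -> CountMatrix:
    d = Path(dir_path)
    return read_counts(d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv")


def read_annotations(tsv_path: str | Path) -> CellAnnotations:
    """Read a cell-annotation TSV (header: barcode, sample_id, group, ...).

    Covariate columns are parsed as numeric where every non-missing entry is
    castable; missing entries stay missing (NaN), never zero.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [c for c in ("barcode", "sample_id", "group") if c not in df.columns]
    if missing:
        raise ValidationError(f"{tsv_path}: missing required column(s) {missing}")
    for col in df.columns:
        if col in RESERVED_ANNOTATION_COLUMNS:
            continue
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        castable = converted.notna() | raw.isna()
        if castable.all():
            df[col] = converted
    return CellAnnotations(df)


def write_annotations(ann: CellAnnotations, path: str | Path) -> Path:
    path = Path(path)
    ann.df.reset_index().to_csv(path, sep="\t", index=False)
    return path


def read_gene_list(
    path: str | Path, name: str | None = None, species: str = "mouse"
) -> GeneList:
    """Read a plain-text gene list, one symbol per line; blanks ignored."""
    symbols = [line.strip() for line in _read_lines(path)]
    if name is None:
        name = Path(path).stem
    return GeneList(name=name, species=species, symbols=symbols)


def write_gene_list(gl: GeneList, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(s + "\n" for s in gl.symbols))
    return path


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """TSV writer whose output round-trips to numerically identical values."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_json(obj: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
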