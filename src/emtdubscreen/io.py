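"""Reading, validation and preprocessing of expression matrices, gene sets
and clinical tables.

File conventions
----------------
* Expression matrix: delimited text (TSV by default, CSV supported), header
  row of sample IDs, first column of gene symbols, log2-scale values.
  Missing entries are kept as explicit NaN and handled pairwise-complete
  downstream, never silently imputed.
* Gene set: plain text, one symbol per line, ``#`` comments allowed.
* Clinical table: delimited text with header ``sample_id,time,event``
  (time in days, event 1 = death observed / 0 = censored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "ClinicalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "log2_transform",
    "filter_tumour_samples",
    "tcga_sample_type_code",
    "read_gene_set",
    "write_gene_set",
    "read_clinical",
    "write_clinical",
]

# TCGA sample-type codes 01-09 denote tumour material (01 primary solid
# tumour ... 09 primary blood-derived cancer); 10+ are normals/controls.
_TUMOUR_CODES = frozenset(range(1, 10))


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2-scale expression values.

    ``data`` is a pandas DataFrame indexed by gene symbol with sample IDs
    as columns. Gene symbols and sample IDs must be unique; values must be
    float with NaN as the only representation of missingness.
    """

    data: pd.DataFrame
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene symbols: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample IDs: {dupes}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.floating):
            self.data = self.data.astype(float)
            values = self.data.to_numpy()
        if np.isinf(values).any():
            raise ParseError("non-finite (infinite) expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def gene(self, symbol: str) -> pd.Series:
        """Expression of one gene across samples (raises KeyError if absent)."""
        return self.data.loc[symbol]


@dataclass(frozen=True)
class GeneSet:
    """Named, ordered collection of unique gene symbols."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ParseError(f"gene set {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ParseError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass
class ClinicalTable:
    """Per-patient follow-up: sample ID, survival time (days), event flag."""

    data: pd.DataFrame  # columns: sample_id, time, event

    def __post_init__(self) -> None:
        required = ["sample_id", "time", "event"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ParseError(f"clinical table lacks columns {missing}")
        self.data = self.data[required].reset_index(drop=True)
        if self.data["sample_id"].duplicated().any():
            raise ParseError("duplicate sample IDs in clinical table")
        times = self.data["time"].to_numpy(dtype=float)
        if np.isnan(times).any() or (times < 0).any():
            raise ParseError("survival times must be non-negative and present")
        events = self.data["event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            bad = sorted(set(events) - {0, 1})
            raise ParseError(f"event indicator must be 0 or 1, found {bad}")
        self.data = self.data.astype({"time": float, "event": int})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids) -> "ClinicalTable":
        """Rows for the given sample IDs, in the given order."""
        sub = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(sub)


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a gene x sample expression matrix from delimited text.

    Duplicate gene rows are collapsed to the first occurrence with a
    warning; duplicate sample columns are a hard error. Empty cells become
    NaN; any other non-numeric cell is a :class:`ParseError` naming the
    offending gene/sample.
    """
    try:
        raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                          keep_default_na=True)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ParseError(f"cannot parse expression matrix {path}: {exc}") from exc
    if raw.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (wrong delimiter?)")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"{path}: non-numeric value {raw.loc[gene, sample]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        warnings.warn(
            f"{path}: {n_dup} duplicate gene row(s) collapsed to first occurrence",
            stacklevel=2,
        )
        numeric = numeric[~numeric.index.duplicated(keep="first")]
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write the matrix as delimited text; float formatting round-trips exactly."""
    m.data.to_csv(path, sep=delimiter)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace each linear-scale value x by log2(x + pseudocount).

    The default pseudocount of 1 keeps zeros finite (log2(0+1) = 0), the
    standard choice for RSEM-normalised counts. Negative input values are
    a :class:`DomainError`.
    """
    if pseudocount < 0:
        raise DomainError("pseudocount must be non-negative")
    values = m.data.to_numpy()
    if np.any(values < 0):
        raise DomainError("log2_transform requires non-negative linear-scale values")
    if pseudocount == 1.0:
        out = np.log1p(values) / np.log(2)  # log1p keeps tiny values distinct
    else:
        out = np.log2(values + pseudocount)
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                            cohort=m.cohort)


def tcga_sample_type_code(barcode: str) -> int | None:
    """Sample-type code of a TCGA-style barcode (4th dash field, first two
    digits), or None if the barcode carries no parseable code."""
    fields = str(barcode).split("-")
    if len(fields) < 4 or len(fields[3]) < 2 or not fields[3][:2].isdigit():
        return None
    return int(fields[3][:2])


def filter_tumour_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only tumour samples (TCGA sample-type code 01-09), preserving order.

    Samples whose barcode lacks a parseable sample-type field are dropped
    with a warning rather than raising.
    """
    keep, unparseable = [], []
    for s in m.samples:
        code = tcga_sample_type_code(s)
        if code is None:
            unparseable.append(s)
        elif code in _TUMOUR_CODES:
            keep.append(s)
    if unparseable:
        warnings.warn(
            f"dropped {len(unparseable)} sample(s) with unparseable TCGA "
            f"barcodes (e.g. {unparseable[0]!r})",
            stacklevel=2,
        )
    return ExpressionMatrix(m.data[keep], cohort=m.cohort)


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene set: one symbol per line, '#' comments and blanks ignored."""
    symbols: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                symbols.append(sym)
    if not symbols:
        raise ParseError(f"gene-set file {path} contains no symbols")
    seen: dict[str, None] = {}
    dupes = 0
    for sym in symbols:
        if sym in seen:
            dupes += 1
        else:
            seen[sym] = None
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicate symbol(s) dropped", stacklevel=2)
    if name is None:
        name = str(path)
    return GeneSet(name=name, symbols=tuple(seen))


def write_gene_set(gs: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for sym in gs.symbols:
            fh.write(sym + "\n")


def read_clinical(path, delimiter: str | None = None) -> ClinicalTable:
    """Read a clinical table with header sample_id,time,event.

    The delimiter is sniffed when not given (TSV and CSV both accepted).
    """
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python")
    except Exception as exc:
        raise ParseError(f"cannot parse clinical table {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"clinical table {path} is empty")
    return ClinicalTable(df)


def write_clinical(t: ClinicalTable, path, delimiter: str = "\t") -> None:
    t.data.to_csv(path, sep=delimiter, index=False)
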