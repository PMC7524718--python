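"""Marker-anchored Pearson correlation screening of a gene family.

The screen has two stages, mirroring how mesenchymal-associated family
members are nominated from bulk tumour expression data:

1. correlate every family gene with a positive mesenchymal anchor
   (vimentin, *VIM*) and keep genes with r >= r_min and p < p_stage1;
2. require, at a stricter p_dual, a concurrent *negative* correlation with
   the epithelial anchor (E-cadherin, *CDH1*).

All correlations are pairwise-complete Pearson with two-sided p-values
from the t-approximation ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees
of freedom. No multiple-testing correction is applied within a screen
(the table records how many genes were tested so users can post-correct).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, MissingGeneError, UndefinedCorrelationError
from .io import ExpressionMatrix, GeneSet

__all__ = [
    "CorrelationResult",
    "ScreenTable",
    "CorrelationMatrix",
    "pearson",
    "marker_screen",
    "dual_criterion_filter",
    "correlation_matrix",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one gene against an anchor."""

    gene: str
    anchor: str
    r: float
    p: float
    n: int


def pearson(x, y, *, min_n: int = 3) -> tuple[float, float, int]:
    """Pairwise-complete Pearson correlation with two-sided p-value.

    Returns ``(r, p, n)`` where n is the number of pairwise-complete
    observations. Perfect correlation (|r| = 1) yields p = 0. Raises
    :class:`InsufficientDataError` below ``min_n`` (never below 3) and
    :class:`UndefinedCorrelationError` on zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < max(min_n, 3):
        raise InsufficientDataError(
            f"{n} pairwise-complete observations (< {max(min_n, 3)} required)"
        )
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError("zero variance in input vector")
    r, p = stats.pearsonr(xs, ys)
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - abs(r) < 1e-14:  # exactly collinear up to rounding
        r = float(np.sign(r))
    p = 0.0 if abs(r) == 1.0 else float(p)
    return r, p, n


def marker_screen(
    m: ExpressionMatrix,
    family: GeneSet,
    anchor: str,
    *,
    min_n: int = 10,
) -> list[CorrelationResult]:
    """Correlate every family gene with an anchor marker gene.

    Family genes absent from the matrix are skipped with one summary
    warning; the anchor itself, if listed in the family, is excluded.
    """
    if anchor not in m:
        raise MissingGeneError(f"anchor gene {anchor!r} not in matrix")
    anchor_expr = m.gene(anchor).to_numpy(dtype=float)
    absent = [g for g in family if g not in m]
    if absent:
        warnings.warn(
            f"{len(absent)} family gene(s) absent from matrix "
            f"(e.g. {absent[0]!r}); skipped",
            stacklevel=2,
        )
    results = []
    for gene in family:
        if gene == anchor or gene in absent:
            continue
        r, p, n = pearson(m.gene(gene).to_numpy(dtype=float), anchor_expr, min_n=min_n)
        results.append(CorrelationResult(gene=gene, anchor=anchor, r=r, p=p, n=n))
    return results


@dataclass
class ScreenTable:
    """Dual-anchor screen outcome, one row per family gene.

    Columns: per-anchor r/p/n, ``pass_stage1`` (r_pos >= r_min and
    p_pos < p_stage1) and ``pass_dual`` (stage 1 plus p_pos < p_dual,
    r_neg < 0 and p_neg < p_dual). Rows sorted by descending r_pos, then
    ascending p_pos, then symbol.
    """

    table: pd.DataFrame
    anchor_pos: str
    anchor_neg: str
    r_min: float
    p_stage1: float
    p_dual: float

    @property
    def stage1_hits(self) -> list[str]:
        return list(self.table.loc[self.table["pass_stage1"], "gene"])

    @property
    def dual_hits(self) -> list[str]:
        return list(self.table.loc[self.table["pass_dual"], "gene"])

    @property
    def n_tested(self) -> int:
        return len(self.table)

    def write(self, path, delimiter: str = "\t") -> None:
        """Write as delimited text with a header comment recording thresholds."""
        digest = hashlib.sha256(
            self.table.to_csv(index=False).encode()
        ).hexdigest()[:12]
        with open(path, "w") as fh:
            fh.write(
                f"# anchor_pos={self.anchor_pos} anchor_neg={self.anchor_neg} "
                f"r_min={self.r_min} p_stage1={self.p_stage1} "
                f"p_dual={self.p_dual} n_tested={self.n_tested} "
                f"table_sha256={digest}\n"
            )
            self.table.to_csv(fh, sep=delimiter, index=False)


def dual_criterion_filter(
    vs_pos: list[CorrelationResult],
    vs_neg: list[CorrelationResult],
    r_min: float = 0.2,
    p_stage1: float = 0.05,
    p_dual: float = 0.01,
) -> ScreenTable:
    """Combine per-anchor screens into the two-stage selection table.

    ``vs_pos`` are correlations against the mesenchymal anchor (VIM),
    ``vs_neg`` against the epithelial anchor (CDH1). Both lists must cover
    the same gene family. The r_min comparison is inclusive (>=).
    """
    pos = {res.gene: res for res in vs_pos}
    neg = {res.gene: res for res in vs_neg}
    if set(pos) != set(neg):
        odd = sorted(set(pos) ^ set(neg))
        raise ValueError(f"genes present in only one screen: {odd}")
    if len(pos) != len(vs_pos) or len(neg) != len(vs_neg):
        raise ValueError("duplicate genes in screen inputs")
    anchor_pos = vs_pos[0].anchor if vs_pos else ""
    anchor_neg = vs_neg[0].anchor if vs_neg else ""
    rows = []
    for gene in pos:
        a, b = pos[gene], neg[gene]
        stage1 = (a.r >= r_min) and (a.p < p_stage1)
        dual = stage1 and (a.p < p_dual) and (b.r < 0) and (b.p < p_dual)
        rows.append({
            "gene": gene,
            "r_pos": a.r, "p_pos": a.p, "n_pos": a.n,
            "r_neg": b.r, "p_neg": b.p, "n_neg": b.n,
            "pass_stage1": stage1, "pass_dual": dual,
        })
    table = pd.DataFrame(
        rows,
        columns=["gene", "r_pos", "p_pos", "n_pos", "r_neg", "p_neg", "n_neg",
                 "pass_stage1", "pass_dual"],
    )
    if len(table):
        table = table.sort_values(
            by=["r_pos", "p_pos", "gene"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return ScreenTable(
        table=table,
        anchor_pos=anchor_pos,
        anchor_neg=anchor_neg,
        r_min=r_min,
        p_stage1=p_stage1,
        p_dual=p_dual,
    )


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with matched p-value matrix."""

    symbols: list[str]
    R: np.ndarray
    P: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(self.symbols)
        return (pd.DataFrame(self.R, index=idx, columns=idx),
                pd.DataFrame(self.P, index=idx, columns=idx))

    def write(self, path, delimiter: str = "\t") -> None:
        r_frame, p_frame = self.to_frames()
        digest = hashlib.sha256(r_frame.to_csv().encode()).hexdigest()[:12]
        with open(path, "w") as fh:
            fh.write(f"# pearson correlation matrix, n_genes={len(self.symbols)} "
                     f"r_sha256={digest}\n")
            fh.write("# block=R\n")
            r_frame.to_csv(fh, sep=delimiter)
            fh.write("# block=P\n")
            p_frame.to_csv(fh, sep=delimiter)


def correlation_matrix(
    m: ExpressionMatrix,
    symbols,
    *,
    min_n: int = 10,
) -> CorrelationMatrix:
    """Pairwise Pearson correlation matrix over the listed genes.

    All symbols must be present; a zero-variance gene raises
    :class:`UndefinedCorrelationError` naming the gene. The diagonal is
    r = 1, p = 0 by definition.
    """
    symbols = list(symbols)
    missing = [s for s in symbols if s not in m]
    if missing:
        raise MissingGeneError(f"genes absent from matrix: {missing}")
    vectors = {s: m.gene(s).to_numpy(dtype=float) for s in symbols}
    for s, v in vectors.items():
        finite = v[np.isfinite(v)]
        if finite.size and np.ptp(finite) == 0:
            raise UndefinedCorrelationError(f"gene {s!r} has zero variance")
    k = len(symbols)
    R = np.eye(k)
    P = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p, _ = pearson(vectors[symbols[i]], vectors[symbols[j]], min_n=min_n)
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    return CorrelationMatrix(symbols=symbols, R=R, P=P)
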