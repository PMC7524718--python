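"""Two-gene co-expression signature across many cohorts.

For a gene pair (e.g. *STAMBPL1* and *SNAI1*) the scan computes one
Pearson correlation per cohort, adjusts the raw p-values across cohorts
with the Benjamini-Hochberg step-up procedure (the family is the set of
cohorts in one scan, so adjusted values depend on family size, recorded in
the report), calls significance at ``p_adj < alpha`` (0.01 by default,
with the looser 0.05 call also reported) and ranks cohorts by descending
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import EmtScreenError
from .io import ExpressionMatrix
from .screen import pearson

__all__ = [
    "CohortCoSignature",
    "CoSignatureReport",
    "bh_adjust",
    "cosignature_scan",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up), original order.

    Standard definition: sort ascending, q_i = p_i * m / i, enforce
    monotone non-decreasing from the largest down, cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise EmtScreenError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


@dataclass(frozen=True)
class CohortCoSignature:
    """Co-expression of a gene pair within one cohort."""

    cohort: str
    gene_a: str
    gene_b: str
    r: float
    p: float
    p_adj: float
    significant: bool        # p_adj < alpha of the scan
    significant_at_05: bool  # the looser conventional call, also reported
    n: int


@dataclass
class CoSignatureReport:
    """Ranked multi-cohort co-signature scan outcome.

    Rows are ordered by descending r (ties: ascending p, then cohort
    label). ``alpha`` is the BH significance level; ``m`` the BH family
    size (number of cohorts scanned).
    """

    rows: list[CohortCoSignature]
    gene_a: str
    gene_b: str
    alpha: float

    @property
    def m(self) -> int:
        return len(self.rows)

    @property
    def n_positive(self) -> int:
        return sum(1 for row in self.rows if row.r > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for row in self.rows if row.r < 0)

    @property
    def n_significant(self) -> int:
        return sum(1 for row in self.rows if row.significant)

    @property
    def significant_cohorts(self) -> list[str]:
        return [row.cohort for row in self.rows if row.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(row) for row in self.rows])

    def write(self, path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(f"# gene_a={self.gene_a} gene_b={self.gene_b} "
                     f"alpha={self.alpha} m={self.m} "
                     f"n_significant={self.n_significant}\n")
            self.to_frame().to_csv(fh, sep=delimiter, index=False)


def cosignature_scan(
    cohorts: list[ExpressionMatrix],
    gene_a: str,
    gene_b: str,
    alpha: float = 0.01,
    *,
    min_n: int = 10,
) -> CoSignatureReport:
    """Per-cohort Pearson correlation of a gene pair with BH control.

    Cohorts missing either gene are excluded with a warning; at least one
    usable cohort is required. Cohorts are expected to be tumour-filtered
    and log2-transformed upstream.
    """
    usable: list[ExpressionMatrix] = []
    skipped: list[str] = []
    for cohort in cohorts:
        if gene_a in cohort and gene_b in cohort:
            usable.append(cohort)
        else:
            skipped.append(cohort.cohort or "<unlabelled>")
    if skipped:
        warnings.warn(
            f"{len(skipped)} cohort(s) missing {gene_a!r} or {gene_b!r} "
            f"excluded: {skipped}",
            stacklevel=2,
        )
    if not usable:
        raise EmtScreenError("no usable cohort contains both genes")
    stats = []
    for cohort in usable:
        r, p, n = pearson(
            cohort.gene(gene_a).to_numpy(dtype=float),
            cohort.gene(gene_b).to_numpy(dtype=float),
            min_n=min_n,
        )
        stats.append((cohort.cohort, r, p, n))
    p_adj = bh_adjust([s[2] for s in stats])
    rows = [
        CohortCoSignature(
            cohort=label,
            gene_a=gene_a,
            gene_b=gene_b,
            r=r,
            p=p,
            p_adj=float(q),
            significant=bool(q < alpha),
            significant_at_05=bool(q < 0.05),
            n=n,
        )
        for (label, r, p, n), q in zip(stats, p_adj)
    ]
    rows.sort(key=lambda row: (-row.r, row.p, row.cohort))
    return CoSignatureReport(rows=rows, gene_a=gene_a, gene_b=gene_b, alpha=alpha)
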