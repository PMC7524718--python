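"""Signature-based EMT scoring.

Each sample j receives the weighted sum ``S_j = sum_i w_i * G_ij`` over a
signature gene set (76 genes in the original metric), where the weight
``w_i`` is the Pearson correlation of signature gene i with an epithelial
anchor gene (E-cadherin, *CDH1*) computed within the same cohort, and
``G_ij`` is the normalised log2 expression of gene i in sample j. Scores
are centred by subtracting the cohort grand mean, so the mean centred
score is zero by construction; a centred score > 0 calls the sample
epithelial, < 0 mesenchymal, and exactly 0 "boundary".

The matrix is taken to be already normalised (the contract of
:class:`~emtdubscreen.io.ExpressionMatrix`); an optional per-gene z-score
flag exists for users who want scale-free weights, default off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingGeneError, UndefinedCorrelationError
from .io import ExpressionMatrix, GeneSet
from .screen import CorrelationResult, pearson

__all__ = [
    "EMTWeights",
    "EMTScoreSet",
    "compute_weights",
    "compute_scores",
    "correlate_gene_with_score",
]

PHENOTYPE_EPITHELIAL = "epithelial"
PHENOTYPE_MESENCHYMAL = "mesenchymal"
PHENOTYPE_BOUNDARY = "boundary"


@dataclass
class EMTWeights:
    """Anchor-correlation weights for a signature gene set.

    ``w`` maps each signature gene present in the source matrix to its
    Pearson r against the anchor; dropped genes (absent or zero-variance)
    are listed in ``dropped``. Weights are NOT renormalised after drops —
    the metric is a plain weighted sum.
    """

    signature_name: str
    anchor: str
    w: pd.Series  # index: gene symbol, values in [-1, 1]
    n_signature: int
    dropped: tuple[str, ...] = ()

    @property
    def n_used(self) -> int:
        return len(self.w)

    def write(self, path, delimiter: str = "\t") -> None:
        frame = self.w.rename("weight").rename_axis("gene").reset_index()
        with open(path, "w") as fh:
            fh.write(f"# anchor={self.anchor} signature={self.signature_name} "
                     f"n_used={self.n_used}/{self.n_signature}\n")
            frame.to_csv(fh, sep=delimiter, index=False)


@dataclass
class EMTScoreSet:
    """Per-sample raw and centred EMT scores with phenotype calls."""

    scores: pd.DataFrame  # columns: raw, centred, phenotype; index: sample
    weights: EMTWeights

    @property
    def raw(self) -> pd.Series:
        return self.scores["raw"]

    @property
    def centred(self) -> pd.Series:
        return self.scores["centred"]

    @property
    def phenotype(self) -> pd.Series:
        return self.scores["phenotype"]

    def write(self, path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(f"# anchor={self.weights.anchor} "
                     f"n_genes={self.weights.n_used}\n")
            self.scores.rename_axis("sample").to_csv(fh, sep=delimiter)


def compute_weights(
    m: ExpressionMatrix,
    signature: GeneSet,
    anchor: str,
) -> EMTWeights:
    """Weight each signature gene by its Pearson r against the anchor.

    Signature genes absent from the matrix are dropped with a warning, as
    are genes whose correlation with the anchor is undefined (zero
    variance). At least one signature gene must survive.
    """
    if anchor not in m:
        raise MissingGeneError(f"anchor gene {anchor!r} not in matrix")
    anchor_expr = m.gene(anchor).to_numpy(dtype=float)
    weights: dict[str, float] = {}
    dropped: list[str] = []
    for gene in signature:
        if gene not in m:
            dropped.append(gene)
            continue
        try:
            r, _, _ = pearson(m.gene(gene).to_numpy(dtype=float), anchor_expr)
        except UndefinedCorrelationError:
            dropped.append(gene)
            continue
        weights[gene] = r
    if not weights:
        raise MissingGeneError(
            f"no usable signature gene from {signature.name!r} in matrix"
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} signature gene(s) dropped "
            f"({len(weights)}/{len(signature)} used)",
            stacklevel=2,
        )
    return EMTWeights(
        signature_name=signature.name,
        anchor=anchor,
        w=pd.Series(weights, dtype=float),
        n_signature=len(signature),
        dropped=tuple(dropped),
    )


def compute_scores(
    m: ExpressionMatrix,
    weights: EMTWeights,
    *,
    zscore_genes: bool = False,
) -> EMTScoreSet:
    """Weighted-sum EMT score per sample, centred to cohort grand mean zero.

    With ``zscore_genes=True`` each weighted gene is standardised across
    samples before the sum (an optional deviation from the plain metric;
    it changes raw scores but not the centring identity).
    """
    missing = [g for g in weights.w.index if g not in m]
    if missing:
        raise MissingGeneError(f"weighted genes absent from matrix: {missing}")
    G = m.data.loc[list(weights.w.index)]
    if zscore_genes:
        mu = G.mean(axis=1)
        sd = G.std(axis=1, ddof=0).replace(0.0, 1.0)
        G = G.sub(mu, axis=0).div(sd, axis=0)
    raw = G.mul(weights.w, axis=0).sum(axis=0, skipna=False)
    centred = raw - raw.mean()
    phenotype = pd.Series(
        np.select(
            [centred > 0, centred < 0],
            [PHENOTYPE_EPITHELIAL, PHENOTYPE_MESENCHYMAL],
            default=PHENOTYPE_BOUNDARY,
        ),
        index=raw.index,
    )
    phenotype[centred.isna()] = pd.NA  # missing score, no call
    scores = pd.DataFrame({"raw": raw, "centred": centred, "phenotype": phenotype})
    return EMTScoreSet(scores=scores, weights=weights)


def correlate_gene_with_score(
    m: ExpressionMatrix,
    gene: str,
    scores: EMTScoreSet,
) -> CorrelationResult:
    """Pearson correlation of one gene's expression with the centred EMT score."""
    if gene not in m:
        raise MissingGeneError(f"gene {gene!r} not in matrix")
    expr = m.gene(gene).reindex(scores.scores.index)
    r, p, n = pearson(expr.to_numpy(dtype=float),
                      scores.centred.to_numpy(dtype=float))
    return CorrelationResult(gene=gene, anchor="EMT_SCORE", r=r, p=p, n=n)
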