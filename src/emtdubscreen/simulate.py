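"""Synthetic cohorts with a planted epithelial-mesenchymal axis.

The generator draws a latent EMT position ``t_j ~ N(0, 1)`` per sample and
emits each gene g as ``G_gj = a_g * t_j + eps_gj`` with independent
Gaussian noise ``eps ~ N(0, noise_sd^2)``. Under this single-factor
linear-Gaussian model every quantity the pipeline estimates has a closed
form; in particular the population correlation between genes g and h is

    corr(g, h) = a_g * a_h / sqrt((a_g^2 + sd^2) * (a_h^2 + sd^2))

so with unit loadings and unit noise two loaded genes correlate at 0.5.
Gene roles: a vimentin-like marker (positive loading, up in mesenchymal
samples), an E-cadherin-like marker (negative loading), a signature set
with mixed-sign loadings, planted family genes with stated loadings, and
null family genes (loading 0). Samples with latent t > 0 are ground-truth
mesenchymal, t < 0 epithelial.

Survival: exponential event times whose rate is ``baseline_hazard *
exp(beta)`` for samples whose hazard-gene expression exceeds the planted
threshold (its median) and ``baseline_hazard`` otherwise; independent
exponential censoring with rate solved numerically so the expected
censored fraction equals the configured value.

Expression is emitted on the already-log2-normalised scale the pipeline
contracts for; ``linear_scale=True`` instead emits ``2**x - 1`` shifted to
non-negative values, to exercise the log2 preprocessing stage. Everything
is a pure function of the config (including its seed); per-gene noise
streams are split off the master seed by gene index, so appending genes
never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import EmtScreenError, MissingGeneError
from .io import ClinicalTable, ExpressionMatrix, GeneSet

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "population_correlation",
    "generate_cohort",
    "generate_survival",
    "generate_multi_cohort",
    "write_cohort",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic cohort.

    Loadings are on the latent mesenchymal axis: positive = higher in
    mesenchymal samples. Defaults emulate a TCGA-like bulk cohort: n=500
    tumours, unit marker loadings, a 20-gene signature with |loading| in
    [1, 2.5] (signature genes are selected for strong differential
    expression, 1-2.5 log2 units per SD of the EMT axis), one planted
    family gene (unit loading, population r = 0.5 to the VIM-like marker)
    among 99 nulls, unit noise.
    """

    n_samples: int = 500
    cohort: str = "SYNTH"
    vim_name: str = "VIM"
    vim_loading: float = 1.0
    cdh1_name: str = "CDH1"
    cdh1_loading: float = -1.0
    n_signature: int = 20
    signature_loading_range: tuple[float, float] = (1.0, 2.5)
    n_null_family: int = 99
    planted_loadings: tuple[tuple[str, float], ...] = (("STAMBPL1", 1.0),)
    family_prefix: str = "DUB"
    noise_sd: float = 1.0
    # survival model (generate_survival); time unit: days
    hazard_gene: str = "STAMBPL1"
    baseline_hazard: float = 1.0 / 1000.0
    log_hazard_ratio: float = math.log(3.0)
    censoring_fraction: float = 0.2
    linear_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise EmtScreenError("n_samples must be >= 3")
        if self.noise_sd <= 0:
            raise EmtScreenError("noise_sd must be > 0")
        if not 0 <= self.censoring_fraction < 1:
            raise EmtScreenError("censoring_fraction must lie in [0, 1)")
        if self.vim_loading <= 0 or self.cdh1_loading >= 0:
            raise EmtScreenError(
                "vim_loading must be positive and cdh1_loading negative"
            )
        lo, hi = self.signature_loading_range
        if not 0 < lo <= hi:
            raise EmtScreenError("signature_loading_range must satisfy 0 < lo <= hi")

    @property
    def planted(self) -> dict[str, float]:
        return dict(self.planted_loadings)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort (fully determines its law)."""

    latent: pd.Series               # per-sample latent EMT position
    loadings: pd.Series             # per-gene loading on the latent axis
    phenotype: pd.Series            # mesenchymal (t > 0) / epithelial (t < 0)
    planted_genes: tuple[str, ...]
    noise_sd: float
    survival_threshold: float | None = None  # planted hazard dichotomy
    hazard_gene: str | None = None


@dataclass
class SyntheticCohort:
    """Expression + optional clinical outcome + generating truth."""

    expression: ExpressionMatrix
    truth: SyntheticTruth
    signature: GeneSet | None  # None when the config has no signature genes
    family: GeneSet | None
    clinical: ClinicalTable | None = None

    @property
    def label(self) -> str:
        return self.expression.cohort


def population_correlation(a_g: float, a_h: float, noise_sd: float) -> float:
    """Closed-form correlation between two genes of the latent-factor model."""
    s2 = noise_sd**2
    return a_g * a_h / math.sqrt((a_g**2 + s2) * (a_h**2 + s2))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _gene_loadings(cfg: SyntheticConfig) -> tuple[pd.Series, list[str]]:
    """Ordered gene -> loading map and the signature gene names."""
    loadings: dict[str, float] = {
        cfg.vim_name: cfg.vim_loading,
        cfg.cdh1_name: cfg.cdh1_loading,
    }
    lo, hi = cfg.signature_loading_range
    sig_rng = _rng(cfg.seed, 3)
    magnitudes = sig_rng.uniform(lo, hi, size=cfg.n_signature)
    signature = []
    for i in range(cfg.n_signature):
        name = f"SIG{i + 1:03d}"
        sign = 1.0 if i % 2 == 0 else -1.0  # mixed-sign signature
        loadings[name] = sign * magnitudes[i]
        signature.append(name)
    for name, loading in cfg.planted_loadings:
        if name in loadings:
            raise EmtScreenError(f"planted gene {name!r} collides with another gene")
        loadings[name] = float(loading)
    for i in range(cfg.n_null_family):
        name = f"{cfg.family_prefix}{i + 1:03d}"
        if name in loadings:
            raise EmtScreenError(f"null family name {name!r} collides")
        loadings[name] = 0.0
    return pd.Series(loadings, dtype=float), signature


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort from the latent-factor model (deterministic per seed)."""
    loadings, signature_genes = _gene_loadings(cfg)
    samples = [
        f"TCGA-{(cfg.cohort + 'XX')[:2].upper()}-{j + 1:04d}-01A"
        for j in range(cfg.n_samples)
    ]
    latent = pd.Series(
        _rng(cfg.seed, 0).standard_normal(cfg.n_samples), index=samples
    )
    rows = np.empty((len(loadings), cfg.n_samples))
    for gi, (gene, a) in enumerate(loadings.items()):
        noise = _rng(cfg.seed, 1, gi).normal(0.0, cfg.noise_sd, size=cfg.n_samples)
        rows[gi] = a * latent.to_numpy() + noise
    data = pd.DataFrame(rows, index=loadings.index, columns=samples)
    if cfg.linear_scale:
        data = np.power(2.0, data - data.min().min()) - 1.0  # non-negative, invertible
    expression = ExpressionMatrix(data, cohort=cfg.cohort)
    phenotype = pd.Series(
        np.where(latent > 0, "mesenchymal", "epithelial"), index=samples
    )
    truth = SyntheticTruth(
        latent=latent,
        loadings=loadings,
        phenotype=phenotype,
        planted_genes=tuple(name for name, _ in cfg.planted_loadings),
        noise_sd=cfg.noise_sd,
    )
    family_genes = list(truth.planted_genes) + [
        f"{cfg.family_prefix}{i + 1:03d}" for i in range(cfg.n_null_family)
    ]
    return SyntheticCohort(
        expression=expression,
        truth=truth,
        signature=(GeneSet(name="synthetic_signature", symbols=tuple(signature_genes))
                   if signature_genes else None),
        family=(GeneSet(name="synthetic_family", symbols=tuple(family_genes))
                if family_genes else None),
    )


def _solve_censor_rate(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving the target expected censored fraction.

    For exponential event time with rate lam and independent exponential
    censoring with rate mu, P(censored) = mu / (lam + mu); the cohort-level
    fraction is the average over subjects' rates.
    """
    def frac(mu: float) -> float:
        return float(np.mean(mu / (rates + mu)))

    hi = rates.max()
    while frac(hi) < target:
        hi *= 10.0
    return brentq(lambda mu: frac(mu) - target, 1e-300, hi)


def generate_survival(cohort: SyntheticCohort, cfg: SyntheticConfig) -> ClinicalTable:
    """Exponential survival driven by a planted expression dichotomy.

    The hazard gene's median is the planted threshold: samples above it
    have hazard ``baseline_hazard * exp(log_hazard_ratio)``. The returned
    table is also attached to ``cohort.clinical`` and the threshold
    recorded in ``cohort.truth``.
    """
    if cfg.hazard_gene not in cohort.expression:
        raise MissingGeneError(f"hazard gene {cfg.hazard_gene!r} not in cohort")
    expr = cohort.expression.gene(cfg.hazard_gene)
    threshold = float(np.median(expr.to_numpy()))
    high = expr.to_numpy() > threshold
    rates = cfg.baseline_hazard * np.exp(cfg.log_hazard_ratio * high.astype(float))
    rng = _rng(cfg.seed, 2)
    event_times = rng.exponential(1.0 / rates)
    if cfg.censoring_fraction == 0:
        time, event = event_times, np.ones(len(expr), dtype=int)
    else:
        mu = _solve_censor_rate(rates, cfg.censoring_fraction)
        censor_times = rng.exponential(1.0 / mu, size=len(expr))
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": expr.index,
        "time": time,
        "event": event,
    }))
    cohort.clinical = clinical
    cohort.truth.survival_threshold = threshold
    cohort.truth.hazard_gene = cfg.hazard_gene
    return clinical


def generate_multi_cohort(cfgs: list[SyntheticConfig]) -> list[SyntheticCohort]:
    """Independent cohorts, one per config; labels must be distinct."""
    labels = [cfg.cohort for cfg in cfgs]
    if len(set(labels)) != len(labels):
        raise EmtScreenError(f"duplicate cohort labels: {labels}")
    return [generate_cohort(cfg) for cfg in cfgs]


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write expression, gene lists, truth and (if present) clinical tables.

    Returns a name -> path map of everything written.
    """
    from pathlib import Path

    from .io import write_clinical, write_expression_matrix, write_gene_set

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"expression": str(outdir / "expression.tsv"),
             "truth": str(outdir / "truth.tsv")}
    write_expression_matrix(cohort.expression, paths["expression"])
    if cohort.signature is not None:
        paths["signature"] = str(outdir / "signature.txt")
        write_gene_set(cohort.signature, paths["signature"])
    if cohort.family is not None:
        paths["family"] = str(outdir / "family.txt")
        write_gene_set(cohort.family, paths["family"])
    truth = pd.DataFrame({
        "sample_id": cohort.truth.latent.index,
        "latent": cohort.truth.latent.to_numpy(),
        "phenotype": cohort.truth.phenotype.to_numpy(),
    })
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if cohort.clinical is not None:
        paths["clinical"] = str(outdir / "clinical.tsv")
        write_clinical(cohort.clinical, paths["clinical"])
    return paths


def write_manifest(entries: dict[str, str], path) -> None:
    """Manifest consumed by the co-signature scan: cohort label -> matrix path."""
    pd.DataFrame(
        {"cohort": list(entries), "path": list(entries.values())}
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"cohort", "path"} <= set(df.columns):
        raise EmtScreenError("manifest needs columns: cohort, path")
    return dict(zip(df["cohort"].astype(str), df["path"].astype(str)))
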