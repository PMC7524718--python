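"""Kaplan-Meier estimation, log-rank testing and optimal cut-point search.

The cut-point search reproduces the common "best-performing threshold"
procedure for expression-based survival stratification: every distinct
expression value strictly between two quantiles (quartiles by default) is
tried as a dichotomisation threshold (low: value <= threshold, high:
value > threshold), a two-group log-rank test is run at each, and the
threshold minimising the log-rank p is returned. The scan applies no
multiple-testing correction — faithfully matching how such thresholds are
reported in the literature — so the result records how many thresholds
were scanned and carries an explicit caveat field making the selection
effect visible (under the null, the minimal p over a scan is
stochastically smaller than uniform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import CutpointError, EmtScreenError, UndefinedTestError
from .io import ClinicalTable

__all__ = [
    "KMCurve",
    "CutpointResult",
    "km_estimate",
    "logrank",
    "optimal_cutpoint",
]

_SCAN_CAVEAT = (
    "minimal p over an exhaustive threshold scan; not corrected for the "
    "number of thresholds tried"
)


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times.

    ``survival_at`` step-interpolates: 1 before the first event, then the
    last product-limit value at or before t.
    """

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) at each event time
    at_risk: np.ndarray     # risk-set size just before each event time
    n: int                  # subjects

    def survival_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)


def km_estimate(clinical: ClinicalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    At each distinct event time S <- S * (1 - d / n_at_risk); censored
    subjects leave the risk set after their recorded time. With no
    observed events the curve has no drops (S = 1 everywhere).
    """
    if len(clinical) == 0:
        raise EmtScreenError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(clinical.time, event_observed=clinical.event)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    survival = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(times=times, survival=survival, at_risk=at_risk, n=len(clinical))


def _group_stats(time: np.ndarray, event: np.ndarray, in_a: np.ndarray):
    """O, E, V sums of the two-group log-rank statistic for group a."""
    event_times = np.unique(time[event == 1])
    # risk-set sizes just before each event time: counts of time >= t
    t_sorted_all = np.sort(time)
    t_sorted_a = np.sort(time[in_a])
    n_at = len(time) - np.searchsorted(t_sorted_all, event_times, side="left")
    n_a = in_a.sum() - np.searchsorted(t_sorted_a, event_times, side="left")
    # event counts at each event time, total and in group a
    et_all = np.sort(time[event == 1])
    et_a = np.sort(time[(event == 1) & in_a])
    d = (np.searchsorted(et_all, event_times, side="right")
         - np.searchsorted(et_all, event_times, side="left"))
    d_a = (np.searchsorted(et_a, event_times, side="right")
           - np.searchsorted(et_a, event_times, side="left"))
    O = d_a.sum()
    E = np.sum(d * n_a / n_at)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d * (n_a / n_at) * (1 - n_a / n_at) * (n_at - d) / (n_at - 1)
    V = np.nansum(v_terms)  # event times with a single subject at risk contribute 0
    return float(O), float(E), float(V)


def logrank(a: ClinicalTable, b: ClinicalTable) -> tuple[float, float]:
    """Two-group log-rank test (chi-square score form, 1 df, two-sided).

    At each distinct event time the observed event count in group a is
    compared with its expectation under the hypergeometric model given the
    risk sets; ``chi_square = (O - E)^2 / V``. Requires both groups
    non-empty and at least one event overall.
    """
    if len(a) == 0 or len(b) == 0:
        raise EmtScreenError("logrank requires two non-empty groups")
    time = np.concatenate([a.time, b.time])
    event = np.concatenate([a.event, b.event])
    if event.sum() == 0:
        raise UndefinedTestError("logrank undefined with zero events")
    in_a = np.zeros(len(time), dtype=bool)
    in_a[: len(a)] = True
    O, E, V = _group_stats(time, event, in_a)
    if V == 0:
        # all events occur where one group exhausts the risk set; no information
        return 0.0, 1.0
    chi_square = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi_square, df=1))
    return float(chi_square), p


def _logrank_arrays(time, event, in_a) -> tuple[float, float]:
    """logrank on raw arrays (internal fast path for the threshold scan)."""
    O, E, V = _group_stats(time, event, in_a)
    if V == 0:
        return 0.0, 1.0
    chi_square = (O - E) ** 2 / V
    return float(chi_square), float(stats.chi2.sf(chi_square, df=1))


@dataclass
class CutpointResult:
    """Best-performing expression threshold from an exhaustive scan."""

    threshold: float
    chi_square: float
    p: float
    n_low: int
    n_high: int
    n_thresholds_scanned: int
    q_low: float
    q_high: float
    gene: str = ""
    caveat: str = _SCAN_CAVEAT

    def write(self, path, delimiter: str = "\t") -> None:
        frame = pd.DataFrame([{k: v for k, v in vars(self).items()}])
        frame.to_csv(path, sep=delimiter, index=False)


def optimal_cutpoint(
    expr: pd.Series,
    clinical: ClinicalTable,
    q_low: float = 0.25,
    q_high: float = 0.75,
    *,
    min_expression: float | None = None,
    gene: str = "",
) -> CutpointResult:
    """Exhaustive optimal cut-point search over one gene's expression.

    ``expr`` maps sample ID to expression; samples are matched to the
    clinical table by ID. Candidate thresholds are all distinct expression
    values strictly between the ``q_low`` and ``q_high`` quantiles; ties
    in minimal p break to the smallest threshold. ``min_expression``
    optionally pre-filters samples (e.g. to those expressing the gene),
    default off.
    """
    if not 0 <= q_low < q_high <= 1:
        raise CutpointError("require 0 <= q_low < q_high <= 1")
    expr = expr.dropna()
    if min_expression is not None:
        expr = expr[expr > min_expression]
    shared = [s for s in expr.index if s in set(clinical.sample_ids)]
    if len(shared) < 2:
        raise CutpointError("fewer than 2 samples shared between expression and clinical")
    expr = expr.loc[shared]
    clin = clinical.subset(shared)
    values = expr.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        raise CutpointError("expression is constant; no cut-point exists")
    lo, hi = np.quantile(values, [q_low, q_high])
    candidates = np.unique(values[(values > lo) & (values < hi)])
    if candidates.size == 0:
        raise CutpointError(
            f"no distinct expression value strictly inside quantiles "
            f"({q_low}, {q_high})"
        )
    time, event = clin.time, clin.event
    if event.sum() == 0:
        raise UndefinedTestError("cut-point scan undefined with zero events")
    best = None
    for threshold in candidates:  # ascending, so ties keep the smallest
        in_low = values <= threshold
        chi_square, p = _logrank_arrays(time, event, in_low)
        if best is None or p < best[1]:
            best = (float(threshold), p, chi_square, int(in_low.sum()))
    threshold, p, chi_square, n_low = best
    return CutpointResult(
        threshold=threshold,
        chi_square=chi_square,
        p=p,
        n_low=n_low,
        n_high=len(values) - n_low,
        n_thresholds_scanned=int(candidates.size),
        q_low=q_low,
        q_high=q_high,
        gene=gene,
    )
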