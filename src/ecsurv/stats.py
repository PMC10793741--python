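"""Survival and hypothesis-testing primitives shared by the pipeline.

Thin, validated wrappers over lifelines / scipy / statsmodels plus a fast
vectorised two-sample logrank statistic used heavily by the survival-tree
and forest code.  Degenerate inputs (no events, identical groups, zero
margins) return the conventional "no evidence" answer instead of raising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence, Tuple

import numpy as np
from lifelines import KaplanMeierFitter, NelsonAalenFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Sentinel for a median that the estimator never reaches.
NOT_REACHED = float("inf")


def _validate_sample(times, events) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("survival sample is empty")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    return t, e


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function (survival or cumulative hazard)."""

    knots: np.ndarray
    values: np.ndarray
    kind: str  # "survival" | "cumulative-hazard"

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if k.shape != v.shape:
            raise ValueError("knots and values must align")
        if np.any(np.diff(k) < 0):
            raise ValueError("knots must be sorted")
        object.__setattr__(self, "knots", k)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        baseline = 1.0 if self.kind == "survival" else 0.0
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], baseline)
        return float(out) if out.ndim == 0 else out


def kaplan_meier(times, events) -> StepFunction:
    """Product-limit estimator of recurrence-free survival.

    S(0) = 1; the curve drops only at event times.
    """
    t, e = _validate_sample(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    return StepFunction(
        sf.index.to_numpy(dtype=float),
        sf.iloc[:, 0].to_numpy(dtype=float),
        kind="survival",
    )


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative hazard H(t) = sum d_i / n_i over event times."""
    t, e = _validate_sample(times, events)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(t, e)
    ch = naf.cumulative_hazard_
    return StepFunction(
        ch.index.to_numpy(dtype=float),
        ch.iloc[:, 0].to_numpy(dtype=float),
        kind="cumulative-hazard",
    )


def reverse_km_median_followup(times, events) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Censoring is treated as the event of interest; patients with the clinical
    event are censored.  Returns ``NOT_REACHED`` (inf) when the reversed curve
    never falls to one half.
    """
    t, e = _validate_sample(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, ~e)
    med = kmf.median_survival_time_
    return float(med) if np.isfinite(med) else NOT_REACHED


def two_sample_logrank(times, events, in_group_a) -> Tuple[float, float]:
    """Fast two-sample logrank chi-square statistic and p-value.

    Vectorised tabulation of observed-minus-expected events over the pooled
    event times; equivalent to the standard (unweighted) logrank test.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    a = np.asarray(in_group_a, dtype=bool)
    n = t.size
    if a.all() or not a.any():
        raise ValueError("both groups must be nonempty")
    order = np.argsort(t, kind="stable")
    t, d, ga = t[order], e[order].astype(float), a[order].astype(float)
    _, first = np.unique(t, return_index=True)
    d_tot = np.add.reduceat(d, first)
    d_a = np.add.reduceat(d * ga, first)
    n_tot = n - first.astype(float)
    cum_a = np.concatenate([[0.0], np.cumsum(ga)])
    n_a = ga.sum() - cum_a[first]
    mask = d_tot > 0
    if not mask.any():
        return 0.0, 1.0
    frac = n_a[mask] / n_tot[mask]
    o_minus_e = float(np.sum(d_a[mask] - d_tot[mask] * frac))
    nt, dt = n_tot[mask], d_tot[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = dt * frac * (1.0 - frac) * (nt - dt) / np.where(nt > 1, nt - 1, 1.0)
    var_terms = np.where(nt > 1, var_terms, 0.0)
    v = float(var_terms.sum())
    if v <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / v
    return stat, float(sps.chi2.sf(stat, 1))


def logrank_test(samples: Sequence[Tuple[Iterable, Iterable]]) -> Tuple[float, float]:
    """k-group logrank test.

    Parameters
    ----------
    samples : sequence of (times, events) pairs, one per group.

    Returns
    -------
    (statistic, p) : chi-square statistic on k-1 degrees of freedom and its
    upper-tail p-value.  With no events anywhere the test is degenerate and
    returns (0, 1).
    """
    if len(samples) < 2:
        raise ValueError("logrank test needs at least two groups")
    parts = [_validate_sample(t, e) for t, e in samples]
    times = np.concatenate([p[0] for p in parts])
    events = np.concatenate([p[1] for p in parts])
    labels = np.concatenate(
        [np.full(p[0].size, i) for i, p in enumerate(parts)]
    )
    if not events.any():
        warnings.warn("logrank test with zero events is degenerate", stacklevel=2)
        return 0.0, 1.0
    res = multivariate_logrank_test(times, labels, events)
    stat = float(res.test_statistic)
    # identical groups can give a numerically ~0 statistic; report p = 1 then
    p = float(res.p_value) if stat > 0 else 1.0
    return stat, p


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired observations.

    Zero differences are dropped (Wilcoxon's convention); with every
    difference zero the test is degenerate and p = 1.  Exact null
    distribution for small samples without ties, normal approximation with
    mid-ranks otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired samples must be nonempty and of equal length")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    method = "exact" if nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method)."""
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; Fisher test degenerate", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(tab, alternative="two-sided")[1])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_logrank_matrix(groups: Sequence[Tuple[np.ndarray, np.ndarray]]):
    """Raw and BH-adjusted logrank p for every unordered pair of groups.

    Returns (pairs, p_raw, p_adj) with ``pairs`` a list of index tuples.
    """
    pairs = list(combinations(range(len(groups)), 2))
    p_raw = []
    for i, j in pairs:
        ti, ei = groups[i]
        tj, ej = groups[j]
        t = np.concatenate([ti, tj])
        e = np.concatenate([ei, ej])
        mask = np.concatenate([np.ones(ti.size, bool), np.zeros(tj.size, bool)])
        p_raw.append(two_sample_logrank(t, e, mask)[1])
    p_raw = np.asarray(p_raw)
    p_adj = bh_fdr(p_raw) if p_raw.size else p_raw
    return pairs, p_raw, p_adj
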