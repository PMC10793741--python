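"""Recurrence-risk group discovery and the published four-group rule.

Two routes to risk groups:

* discovery — ``grow_tree`` recursively partitions disease-free survival by
  the covariate/threshold split with the largest logrank statistic, then
  ``merge_leaves`` greedily recombines prognostically similar leaves until
  every remaining pair differs at p < 0.001 and BH-adjusted p < 0.01;
* application — ``assign_group`` evaluates the published rule set
  (pN3 -> IV; pN2 or pN1 with LNR > 0.05 -> III; pN1 with LNR <= 0.05 or
  pN0 with LVI/PNI -> II; pN0 without either -> I).

The split-stopping rule applies a Sidak correction over the number of
candidate splits examined at the node, so that a null cohort yields a
single leaf at roughly the nominal rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import bh_fdr, kaplan_meier, pairwise_logrank_matrix, two_sample_logrank

#: Covariates offered to the tree by default (numeric / boolean only).
DEFAULT_COVARIATES = (
    "pT",
    "pN",
    "lvi",
    "pni",
    "lnr",
    "nodes_positive",
    "nodes_examined",
)

#: Cap on candidate thresholds per continuous covariate at one node.
MAX_THRESHOLDS = 32

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass
class TreeNode:
    members: np.ndarray  # row positions into the cohort
    depth: int
    leaf_id: Optional[int] = None
    covariate: Optional[str] = None
    threshold: Optional[float] = None
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class StratificationTree:
    root: TreeNode
    covariates: Tuple[str, ...]

    def leaves(self) -> List[TreeNode]:
        out: List[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def leaf_labels(self, n: int) -> np.ndarray:
        """Leaf id per cohort row."""
        labels = np.full(n, -1, dtype=int)
        for leaf in self.leaves():
            labels[leaf.members] = leaf.leaf_id
        return labels


@dataclass
class MergeTrace:
    steps: List[Tuple[Tuple[int, int], float, int]] = field(default_factory=list)
    final_pairs: List[Tuple[str, str]] = field(default_factory=list)
    final_p_raw: List[float] = field(default_factory=list)
    final_p_adj: List[float] = field(default_factory=list)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)
    if uniq.size < 2:
        return np.empty(0)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if mids.size > MAX_THRESHOLDS:
        take = np.unique(
            np.linspace(0, mids.size - 1, MAX_THRESHOLDS).round().astype(int)
        )
        mids = mids[take]
    return mids


def grow_tree(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_leaf: int = 50,
    max_depth: int = 4,
    stop_p: float = 0.01,
) -> StratificationTree:
    """Recursive partitioning of DFS by exhaustive logrank-split search.

    At each node every covariate/threshold pair (midpoints of consecutive
    observed values, at most ``MAX_THRESHOLDS`` per covariate) is scored by
    the two-sample logrank statistic; the best split is kept if its
    Sidak-corrected p-value (over the candidates examined) is below
    ``stop_p`` and both children have at least ``min_leaf`` members.
    Deterministic; ties are broken by covariate name order then threshold.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise KeyError(f"covariates missing from cohort: {missing}")
    covariates = tuple(sorted(covariates))
    times = cohort["dfs_months"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=bool)
    X = {c: cohort[c].to_numpy(dtype=float) for c in covariates}

    next_leaf = [0]

    def split_node(node: TreeNode) -> None:
        members = node.members
        if node.depth >= max_depth or members.size < 2 * min_leaf:
            node.leaf_id = next_leaf[0]
            next_leaf[0] += 1
            return
        t, e = times[members], events[members]
        best = None  # (chi2, covariate, threshold, mask)
        n_candidates = 0
        for cov in covariates:
            v = X[cov][members]
            for thr in _candidate_thresholds(v):
                mask = v <= thr
                nl = int(mask.sum())
                if nl < min_leaf or members.size - nl < min_leaf:
                    continue
                n_candidates += 1
                chi2, _ = two_sample_logrank(t, e, mask)
                if best is None or chi2 > best[0] + 1e-9:
                    best = (chi2, cov, float(thr), mask)
        if best is None or n_candidates == 0:
            node.leaf_id = next_leaf[0]
            next_leaf[0] += 1
            return
        chi2, cov, thr, mask = best
        from scipy.stats import chi2 as chi2_dist

        p_raw = float(chi2_dist.sf(chi2, 1))
        # Sidak correction over the candidates actually examined at this node
        p_corr = float(-np.expm1(n_candidates * np.log1p(-min(p_raw, 1 - 1e-16))))
        if p_corr >= stop_p:
            node.leaf_id = next_leaf[0]
            next_leaf[0] += 1
            return
        node.covariate = cov
        node.threshold = thr
        node.statistic = chi2
        node.p_value = p_raw
        node.left = TreeNode(members=members[mask], depth=node.depth + 1)
        node.right = TreeNode(members=members[~mask], depth=node.depth + 1)
        split_node(node.left)
        split_node(node.right)

    root = TreeNode(members=np.arange(len(cohort)), depth=0)
    split_node(root)
    return StratificationTree(root=root, covariates=covariates)


def merge_leaves(
    tree: StratificationTree,
    cohort: pd.DataFrame,
    alpha: float = 0.001,
    alpha_adj: float = 0.01,
) -> Tuple[Dict[int, str], MergeTrace]:
    """Iteratively merge the most prognostically similar pair of groups.

    At every round all pairwise logrank p-values among the current groups are
    computed and BH-adjusted; if any pair fails either threshold
    (raw p >= ``alpha`` or adjusted >= ``alpha_adj``) the pair with the
    largest raw p is merged.  Final groups are relabelled I..k by increasing
    Kaplan-Meier 60-month cumulative incidence.

    Returns (leaf_id -> group label, trace).
    """
    times = cohort["dfs_months"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=bool)
    leaves = tree.leaves()
    # group state: list of (member leaf_ids, member rows)
    groups: List[Tuple[List[int], np.ndarray]] = [
        ([leaf.leaf_id], leaf.members) for leaf in leaves
    ]
    trace = MergeTrace()
    while len(groups) > 1:
        samples = [(times[rows], events[rows]) for _, rows in groups]
        pairs, p_raw, p_adj = pairwise_logrank_matrix(samples)
        ok = (p_raw < alpha) & (p_adj < alpha_adj)
        if ok.all():
            break
        worst = int(np.argmax(p_raw))
        i, j = pairs[worst]
        merged = (
            groups[i][0] + groups[j][0],
            np.concatenate([groups[i][1], groups[j][1]]),
        )
        trace.steps.append(((i, j), float(p_raw[worst]), len(groups) - 1))
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]

    # order groups by 60-month cumulative incidence
    def cuminc60(rows: np.ndarray) -> float:
        km = kaplan_meier(times[rows], events[rows])
        horizon = min(60.0, float(times[rows].max()))
        return 1.0 - float(km(horizon))

    order = np.argsort([cuminc60(rows) for _, rows in groups], kind="stable")
    mapping: Dict[int, str] = {}
    ordered_rows = []
    for rank, gi in enumerate(order):
        label = _ROMAN[rank]
        ordered_rows.append((label, groups[gi][1]))
        for leaf_id in groups[gi][0]:
            mapping[leaf_id] = label
    if len(ordered_rows) > 1:
        samples = [(times[rows], events[rows]) for _, rows in ordered_rows]
        pairs, p_raw, p_adj = pairwise_logrank_matrix(samples)
        trace.final_pairs = [
            (ordered_rows[i][0], ordered_rows[j][0]) for i, j in pairs
        ]
        trace.final_p_raw = [float(p) for p in p_raw]
        trace.final_p_adj = [float(p) for p in p_adj]
    return mapping, trace


# ---------------------------------------------------------------------------
# Published rule set


@dataclass(frozen=True)
class RiskRule:
    group: str
    clauses: Tuple[Tuple[str, str, float], ...]  # (covariate, op, constant)


@dataclass(frozen=True)
class RiskRuleSet:
    """Ordered first-match-wins rules mapping covariates to groups I-IV."""

    rules: Tuple[RiskRule, ...]

    @classmethod
    def from_json(cls, text: str) -> "RiskRuleSet":
        items = json.loads(text)
        return cls(
            tuple(
                RiskRule(
                    group=item["group"],
                    clauses=tuple(
                        (c["covariate"], c["op"], c["value"]) for c in item["all"]
                    ),
                )
                for item in items
            )
        )

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "group": r.group,
                    "all": [
                        {"covariate": c[0], "op": c[1], "value": c[2]}
                        for c in r.clauses
                    ],
                }
                for r in self.rules
            ],
            indent=2,
        )


_OPS = {
    "==": lambda x, v: x == v,
    "<=": lambda x, v: x <= v,
    "<": lambda x, v: x < v,
    ">": lambda x, v: x > v,
    ">=": lambda x, v: x >= v,
}


def published_rules() -> RiskRuleSet:
    """The published four-group rule set, loaded from packaged data."""
    text = resources.files("ecsurv.data").joinpath("published_rules.json").read_text()
    return RiskRuleSet.from_json(text)


def assign_group(record: Mapping, rules: Optional[RiskRuleSet] = None) -> str:
    """Group label for one patient record (mapping or DataFrame row)."""
    rules = rules or published_rules()
    for rule in rules.rules:
        match = True
        for cov, op, value in rule.clauses:
            if cov not in record or (
                hasattr(record, "get") and record.get(cov) is None
            ):
                raise KeyError(f"record is missing covariate {cov!r}")
            x = record[cov]
            if isinstance(x, (bool, np.bool_)):
                x = float(x)
            if not _OPS[op](x, value):
                match = False
                break
        if match:
            return rule.group
    raise ValueError("rules are not exhaustive for this record")


def assign_groups(cohort: pd.DataFrame, rules: Optional[RiskRuleSet] = None) -> np.ndarray:
    """Vectorised ``assign_group`` over a cohort DataFrame."""
    rules = rules or published_rules()
    n = len(cohort)
    out = np.empty(n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in rules.rules:
        match = unassigned.copy()
        for cov, op, value in rule.clauses:
            if cov not in cohort.columns:
                raise KeyError(f"cohort is missing covariate {cov!r}")
            match &= _OPS[op](cohort[cov].to_numpy(dtype=float), value)
        out[match] = rule.group
        unassigned &= ~match
    if unassigned.any():
        raise ValueError("rules are not exhaustive over the cohort")
    return out


def bootstrap_validate_groups(
    cohort: pd.DataFrame,
    rules: Optional[RiskRuleSet] = None,
    n_trials: int = 1000,
    frac: float = 0.7,
    sig_level: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of 70 %-downsampling trials with all pairwise logrank p <
    ``sig_level``.

    Each trial subsamples ``floor(frac * n)`` records without replacement,
    assigns groups by the rules, and runs all pairwise logrank tests; trials
    where some group present in the full cohort is empty count as
    non-significant.
    """
    rules = rules or published_rules()
    rng = np.random.default_rng(seed)
    n = len(cohort)
    n_sub = int(np.floor(frac * n))
    times = cohort["dfs_months"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=bool)
    labels = assign_groups(cohort, rules)
    expected = sorted(set(labels))
    if len(expected) < 2:
        raise ValueError("cohort stratifies into fewer than two groups")
    hits = 0
    for _ in range(n_trials):
        idx = rng.choice(n, size=n_sub, replace=False)
        sub_labels = labels[idx]
        groups = [idx[sub_labels == g] for g in expected]
        if any(rows.size == 0 for rows in groups):
            continue
        samples = [(times[rows], events[rows]) for rows in groups]
        _, p_raw, _ = pairwise_logrank_matrix(samples)
        if np.all(p_raw < sig_level):
            hits += 1
    return hits / n_trials
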