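"""Optimal contiguous risk categories from shrunk procedure mortality rates.

Procedures are ordered by their model-based (shrunk) mortality and split
into K contiguous categories.  A partition is scored by the
case-weighted within-category sum of squares of the rates (the
homogeneity criterion; 0 = perfectly homogeneous), minimised exactly by
dynamic programming.  The number of categories is chosen by the Bayesian
information criterion of a per-category common binomial death rate
applied to the observed counts, scanned over K = 2..20 by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "StratificationResult",
    "RiskStratifier",
    "homogeneity_score",
    "optimal_partition",
    "partition_bic",
    "select_num_categories",
    "assign_categories",
]


@dataclass
class StratificationResult:
    """An ordered partition of procedures into K risk categories.

    ``boundaries`` holds the K-1 start indices of categories 2..K on the
    rate-ordered procedure list; ``category_of`` maps each procedure name
    to its ordinal category (1 = lowest pooled mortality).
    """
    K: int
    boundaries: tuple
    category_of: dict
    category_rates: np.ndarray
    homogeneity: float
    bic: float | None = None
    bic_trace: dict = field(default_factory=dict)
    order: list = field(default_factory=list)

    def to_json(self, path=None):
        obj = {
            "K": int(self.K),
            "boundaries": [int(b) for b in self.boundaries],
            "category_of": {k: int(v) for k, v in self.category_of.items()},
            "category_rates": [float(r) for r in self.category_rates],
            "homogeneity": float(self.homogeneity),
            "bic": None if self.bic is None else float(self.bic),
            "bic_trace": {str(k): float(v) for k, v in self.bic_trace.items()},
            "order": list(self.order),
        }
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as f:
            json.dump(obj, f, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as f:
            obj = json.load(f)
        return cls(K=obj["K"], boundaries=tuple(obj["boundaries"]),
                   category_of=obj["category_of"],
                   category_rates=np.asarray(obj["category_rates"]),
                   homogeneity=obj["homogeneity"], bic=obj["bic"],
                   bic_trace={int(k): v for k, v in obj["bic_trace"].items()},
                   order=obj["order"])


def _check_partition(n_items, boundaries):
    boundaries = tuple(int(b) for b in boundaries)
    if any(b <= 0 or b >= n_items for b in boundaries):
        raise ValueError("boundaries must lie strictly inside 1..J-1")
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ValueError("boundaries must be strictly increasing")
    return boundaries


def _segments(n_items, boundaries):
    edges = (0, *boundaries, n_items)
    return list(zip(edges[:-1], edges[1:]))


def homogeneity_score(rates, weights, boundaries):
    """Case-weighted within-category sum of squares of the rates.

    ``sum_cat sum_j w_j (r_j - rbar_cat)^2`` with ``rbar_cat`` the
    weighted mean rate of the category.  Rates must already be sorted
    ascending (the caller owns the ordering and its tie-breaks).
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(np.diff(rates) < 0):
        raise ValueError("rates must be sorted ascending")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    boundaries = _check_partition(len(rates), boundaries)
    total = 0.0
    for i, j in _segments(len(rates), boundaries):
        w = weights[i:j]
        r = rates[i:j]
        rbar = np.average(r, weights=w)
        total += float(np.sum(w * (r - rbar) ** 2))
    return total


def optimal_partition(rates, weights, K):
    """Globally optimal K-category contiguous partition by dynamic programming.

    Minimises :func:`homogeneity_score` over all C(J-1, K-1) contiguous
    partitions exactly, in O(K J^2) using prefix-sum segment costs.
    Deterministic: ties resolve to the smallest left boundary.
    Returns a :class:`StratificationResult` without BIC; ``category_rates``
    are the weighted mean rates per category.
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    J = len(rates)
    if np.any(np.diff(rates) < 0):
        raise ValueError("rates must be sorted ascending")
    if not 1 <= K <= J:
        raise ValueError(f"K={K} out of range 1..{J}")

    W = np.concatenate([[0.0], np.cumsum(weights)])
    WR = np.concatenate([[0.0], np.cumsum(weights * rates)])
    WR2 = np.concatenate([[0.0], np.cumsum(weights * rates**2)])

    def seg_cost(i, j):
        w = W[j] - W[i]
        wr = WR[j] - WR[i]
        return max(0.0, (WR2[j] - WR2[i]) - wr * wr / w)

    INF = np.inf
    D = np.full((K + 1, J + 1), INF)
    back = np.zeros((K + 1, J + 1), dtype=int)
    D[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, J + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = D[k - 1, i] + seg_cost(i, j)
                if c < best - 1e-15:
                    best, arg = c, i
            D[k, j] = best
            back[k, j] = arg

    cuts = []
    j = J
    for k in range(K, 0, -1):
        i = back[k, j]
        if k > 1:
            cuts.append(i)
        j = i
    boundaries = tuple(sorted(cuts))
    cat_rates = np.array([np.average(rates[i:j], weights=weights[i:j])
                          for i, j in _segments(J, boundaries)])
    return StratificationResult(
        K=K, boundaries=boundaries, category_of={},
        category_rates=cat_rates, homogeneity=float(D[K, J]))


def partition_bic(deaths, cases, boundaries):
    """BIC of a per-category common binomial rate on the observed counts.

    ``-2 sum_j log Binomial(d_j | n_j, phat_cat(j)) + K log(sum_j n_j)``,
    with ``phat_cat`` the pooled death rate of the category.  K free rate
    parameters; the sample size is the total case count.
    """
    deaths = np.asarray(deaths, dtype=float)
    cases = np.asarray(cases, dtype=float)
    boundaries = _check_partition(len(deaths), boundaries)
    N = cases.sum()
    loglik = 0.0
    for i, j in _segments(len(deaths), boundaries):
        nc = cases[i:j].sum()
        if nc == 0:
            raise ValueError(f"category over rows [{i}, {j}) has zero total cases")
        phat = deaths[i:j].sum() / nc
        d, n = deaths[i:j], cases[i:j]
        loglik += float(np.sum(gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1)
                               + xlogy(d, phat) + xlogy(n - d, 1 - phat)))
    K = len(boundaries) + 1
    return -2.0 * loglik + K * np.log(N)


def _rate_order(estimates, rate_col="posterior_mean"):
    """Stable ordering: rate ascending, then cases descending, then name."""
    df = estimates.copy()
    df["_neg_cases"] = -df["cases"]
    df = df.sort_values([rate_col, "_neg_cases", "procedure"], kind="mergesort")
    return df.drop(columns="_neg_cases").reset_index(drop=True)


def select_num_categories(estimates, k_range=(2, 20), rate_col="posterior_mean"):
    """Scan K over ``k_range``, pick the partition minimising BIC.

    ``estimates`` must carry ``procedure``, ``cases``, ``deaths`` and the
    shrunk rate column.  Ties in BIC resolve to the smaller K; the full
    K-vs-BIC trace is retained on the result.
    """
    df = _rate_order(estimates, rate_col)
    J = len(df)
    k_min, k_max = k_range
    if k_max > J:
        warnings.warn(f"k_max={k_max} exceeds number of procedures J={J}; truncating")
        k_max = J
    if k_min > k_max:
        raise ValueError("empty K range after truncation")

    rates = df[rate_col].to_numpy()
    weights = df["cases"].to_numpy(dtype=float)
    deaths = df["deaths"].to_numpy(dtype=float)

    best = None
    trace = {}
    for K in range(k_min, k_max + 1):
        res = optimal_partition(rates, weights, K)
        bic = partition_bic(deaths, weights, res.boundaries)
        trace[K] = bic
        if best is None or bic < best.bic - 1e-12:
            res.bic = bic
            best = res

    segs = _segments(J, best.boundaries)
    cat_idx = np.empty(J, dtype=int)
    for c, (i, j) in enumerate(segs, start=1):
        cat_idx[i:j] = c
    pooled = np.array([deaths[i:j].sum() / weights[i:j].sum() for i, j in segs])
    best.category_of = dict(zip(df["procedure"], (int(c) for c in cat_idx)))
    best.category_rates = pooled
    best.bic_trace = trace
    best.order = df["procedure"].tolist()
    return best


def assign_categories(patients, strat, procedure_col="procedure_name"):
    """Fill ``risk_category`` for each patient from the active stratification.

    Every patient's procedure must appear in ``strat.category_of``;
    unknown procedures raise with the offending names listed.
    """
    out = patients.copy()
    if len(out) == 0:
        out["risk_category"] = pd.Series(dtype=int)
        return out
    mapped = out[procedure_col].map(strat.category_of)
    if mapped.isna().any():
        missing = sorted(out.loc[mapped.isna(), procedure_col].unique())
        raise KeyError(f"procedures missing from stratification: {missing}")
    out["risk_category"] = mapped.astype(int)
    return out


class RiskStratifier(BaseEstimator):
    """Shrink-rate risk stratifier (fit selects K, transform assigns categories).

    Parameters
    ----------
    k_min, k_max : int
        Range of category counts scanned by BIC (inclusive).
    rate_col : str
        Column of the estimates table used as the ordering rate.

    Attributes
    ----------
    K_ : int selected number of categories.
    boundaries_ : tuple of cut indices on the rate-ordered list.
    category_of_ : dict procedure -> 1..K.
    category_rates_ : pooled observed death rate per category (increasing).
    homogeneity_, bic_ : scores of the selected partition.
    bic_trace_ : dict K -> BIC over the scanned range.
    result_ : the full :class:`StratificationResult`.
    """

    def __init__(self, k_min=2, k_max=20, rate_col="posterior_mean"):
        self.k_min = k_min
        self.k_max = k_max
        self.rate_col = rate_col

    def fit(self, X, y=None):
        """Fit on an estimates table (procedure, cases, deaths, shrunk rate)."""
        res = select_num_categories(X, (self.k_min, self.k_max), self.rate_col)
        self.result_ = res
        self.K_ = res.K
        self.boundaries_ = res.boundaries
        self.category_of_ = res.category_of
        self.category_rates_ = res.category_rates
        self.homogeneity_ = res.homogeneity
        self.bic_ = res.bic
        self.bic_trace_ = res.bic_trace
        return self

    def transform(self, X, procedure_col="procedure_name"):
        """Assign risk categories to a patient table (adds ``risk_category``)."""
        check_is_fitted(self, "result_")
        return assign_categories(X, self.result_, procedure_col)
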