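"""Minimum Redundancy Maximum Relevance feature ranking, from first principles.

Continuous features and target are discretized (equal-frequency by default,
10 bins), dependence is measured by plug-in mutual information in bits from
the joint contingency table, and features are ordered by greedy forward
selection.  The step score for a candidate j given the selected set S is

    quotient scheme (default):  I(x_j; y) / mean_{k in S} I(x_j; x_k)
    difference scheme:          I(x_j; y) - mean_{k in S} I(x_j; x_k)

with a small floor on the redundancy denominator.  The first selected
feature's importance equals its relevance.

Two estimator details matter for finite samples.  First, the plug-in MI of
two independent variables is biased upward by roughly
``(r-1)(c-1) / (2 N ln 2)`` bits; the ranking therefore uses the
Miller-Madow bias-corrected estimate (clamped at zero) for both relevance
and redundancy.  Second, a feature that is genuinely independent of the
target should carry zero importance rather than a small positive residue,
so relevance is set to exactly 0 when a permutation test on the plug-in MI
(399 target permutations, default alpha 0.01) cannot reject independence;
the permutation null is exact by construction, unlike the chi-square
approximation to the G statistic, which is anti-conservative at the cell
counts typical here.  Zero-relevance features are appended at the end of
the ranking, in input order, with importance 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .errors import ConfigurationError, InputError
from .indices import FeatureTable

__all__ = [
    "DiscretizationConfig",
    "MRMRRanking",
    "discretize",
    "mutual_information",
    "mrmr_rank",
]

logger = logging.getLogger(__name__)

EPS_BITS = 1e-12  # floor on redundancy denominators
N_PERMUTATIONS = 399  # relevance-screen permutation count
_SCREEN_SEED = 0x5EED  # fixed: the screen is a deterministic function of its inputs


@dataclass(frozen=True)
class DiscretizationConfig:
    """Binning used before mutual-information estimation."""

    n_bins: int = 10
    scheme: str = "equal-frequency"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if self.scheme not in ("equal-frequency", "equal-width"):
            raise ConfigurationError("scheme must be 'equal-frequency' or 'equal-width'")


@dataclass
class MRMRRanking:
    """Greedy MRMR output: features in selection order with scores."""

    ordered_features: list[str]
    importance: np.ndarray
    relevance: np.ndarray
    redundancy: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.ordered_features,
                "importance": self.importance,
                "relevance": self.relevance,
                "redundancy": self.redundancy,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame()[["feature", "importance"]].to_csv(path, index=False, encoding="utf-8")


def discretize(values: np.ndarray, config: DiscretizationConfig | None = None) -> np.ndarray:
    """Bin a continuous vector into integer labels ``0..n_bins-1``.

    Equal-frequency bins differ in size by at most one when values are
    distinct.  If there are fewer distinct values than bins, the bin count
    falls back to the number of distinct values with a logged warning; a
    constant vector collapses to a single bin.
    """
    config = config or DiscretizationConfig()
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise InputError("values must be a 1-D vector of length >= 2")
    n = values.size
    distinct = np.unique(values).size
    k = min(config.n_bins, distinct)
    if k < config.n_bins:
        logger.warning("only %d distinct values; falling back to %d bins", distinct, k)
    if k == 1:
        return np.zeros(n, dtype=int)

    if config.scheme == "equal-frequency":
        order = np.argsort(values, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        # Tied values must land in one bin: share the mean rank of the tie group.
        _, inverse = np.unique(values, return_inverse=True)
        mean_rank = np.zeros(distinct)
        np.add.at(mean_rank, inverse, ranks)
        counts = np.bincount(inverse)
        mean_rank /= counts
        labels = np.minimum((mean_rank[inverse] * k / n).astype(int), k - 1)
        return labels

    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, k + 1)
    labels = np.digitize(values, edges[1:-1], right=False)
    return labels.astype(int)


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    r, c = xi.max() + 1, yi.max() + 1
    table = np.zeros((r, c))
    np.add.at(table, (xi, yi), 1.0)
    return table


def _plugin_mi_bits(table: np.ndarray) -> float:
    n = table.sum()
    p = table / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    terms = p[mask] * np.log2(p[mask] / (px @ py)[mask])
    # summing in sorted order makes the estimate exactly symmetric in (x, y)
    return float(np.sort(terms).sum())


def mutual_information(x: np.ndarray, y: np.ndarray, corrected: bool = False) -> float:
    """Mutual information between two discrete vectors, in bits.

    The plug-in estimate from the joint contingency table; exactly symmetric
    and non-negative.  With ``corrected=True`` the Miller-Madow bias term
    ``(r-1)(c-1)/(2 N ln 2)`` is subtracted and the result clamped at zero.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise InputError("need at least 2 observations")
    table = _contingency(x, y)
    mi = _plugin_mi_bits(table)
    if corrected:
        r, c = table.shape
        bias = (r - 1) * (c - 1) / (2.0 * table.sum() * math.log(2.0))
        mi = max(0.0, mi - bias)
    return mi


def _independence_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int = N_PERMUTATIONS, seed: int = _SCREEN_SEED
) -> float:
    """Permutation p-value for independence of two discrete vectors.

    The plug-in MI of x against ``n_perm`` random permutations of y forms
    the null; the p-value is ``(1 + #null >= observed) / (n_perm + 1)``,
    exact under independence.
    """
    observed = _plugin_mi_bits(_contingency(x, y))
    rng = default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _plugin_mi_bits(_contingency(x, rng.permutation(y))) >= observed - 1e-12
    return (1 + hits) / (n_perm + 1)


def mrmr_rank(
    features: FeatureTable,
    target: np.ndarray | None = None,
    config: DiscretizationConfig | None = None,
    scheme: str = "quotient",
    alpha: float = 0.01,
) -> MRMRRanking:
    """Rank features by greedy minimum-redundancy maximum-relevance selection.

    Parameters
    ----------
    features : FeatureTable
        Feature matrix; ``features.target`` is used unless ``target`` given.
    scheme : {"quotient", "difference"}
        How redundancy discounts relevance at each greedy step.
    alpha : float
        Significance level of the relevance screen: features for which the
        MI permutation test against the target cannot reject independence
        get relevance (and importance) exactly 0 and are ranked last, in
        input order.

    Ties in the step score break toward the earlier input column, which
    places an original feature ahead of its exact duplicate.
    """
    if scheme not in ("quotient", "difference"):
        raise ConfigurationError("scheme must be 'quotient' or 'difference'")
    if not features.feature_names:
        raise InputError("empty feature set")
    y = features.target if target is None else np.asarray(target, dtype=float)
    if y is None:
        raise InputError("target chlorophyll vector required")
    if y.shape != (features.n_samples,):
        raise InputError("target length mismatch")

    config = config or DiscretizationConfig()
    names = list(features.feature_names)
    p = len(names)
    disc = [discretize(features.values[:, j], config) for j in range(p)]
    ydisc = discretize(y, config)

    relevance = np.zeros(p)
    for j in range(p):
        if _independence_pvalue(disc[j], ydisc) < alpha:
            relevance[j] = mutual_information(disc[j], ydisc, corrected=True)

    active = [j for j in range(p) if relevance[j] > EPS_BITS]
    inert = [j for j in range(p) if relevance[j] <= EPS_BITS]

    selected: list[int] = []
    importance = np.zeros(p)
    redundancy = np.zeros(p)
    pair_mi: dict[tuple[int, int], float] = {}

    def mi_pair(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in pair_mi:
            pair_mi[key] = mutual_information(disc[a], disc[b], corrected=True)
        return pair_mi[key]

    remaining = list(active)
    while remaining:
        best_j, best_score, best_red = -1, -np.inf, 0.0
        for j in remaining:
            if not selected:
                score, red = relevance[j], 0.0
            else:
                red = float(np.mean([mi_pair(j, k) for k in selected]))
                if scheme == "quotient":
                    score = relevance[j] / max(red, EPS_BITS)
                else:
                    score = relevance[j] - red
            if score > best_score:  # ties keep the earlier input column
                best_j, best_score, best_red = j, score, red
        selected.append(best_j)
        importance[best_j] = max(0.0, best_score)
        redundancy[best_j] = best_red
        remaining.remove(best_j)

    order = selected + inert
    return MRMRRanking(
        ordered_features=[names[j] for j in order],
        importance=importance[order],
        relevance=relevance[order],
        redundancy=redundancy[order],
    )
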