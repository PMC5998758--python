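"""Similarity profiling, gold-standard validation, threshold evaluation
and similar-pair selection.

The workflow mirrors how coexpression-network similarity measures are
calibrated in practice:

1. build the full pairwise similarity profile of a set of networks;
2. validate a measure by the Spearman rank correlation of its profile
   against an external gold standard (e.g., GO semantic similarity);
3. evaluate a decision threshold from group designs — the median score
   of within-"similar group" pairs, averaged over independent
   experiments;
4. select "similar pairs": pairs whose COEXsim and fuzzy scores both
   strictly exceed their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np
import pandas as pd
from scipy import stats

from . import graphlets as _graphlets
from . import measures as _measures
from .network import SimilarityMatrix, WeightedNetwork

__all__ = [
    "GoldStandard",
    "ThresholdReport",
    "SimilarPairSelection",
    "pairwise_matrix",
    "spearman_profile",
    "spearman_validation",
    "group_medians",
    "evaluate_threshold",
    "select_similar_pairs",
]

PAIR_SCOPES = ("full", "offdiag", "upper")
MEASURES = ("coexsim", "fuzzy", "gcd")


@dataclass
class GoldStandard:
    """Reference similarity matrix (e.g., GO semantic similarity)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.values.columns):
            raise ValueError("gold standard must be square with matching labels")
        v = self.values.to_numpy(dtype=float)
        if abs(v - v.T).max(initial=0.0) > 1e-8:
            raise ValueError("gold standard must be symmetric")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ThresholdReport:
    """Per-experiment group medians and the averaged decision threshold."""

    measure: str
    median_similar: list[float] = field(default_factory=list)
    median_other: list[float] = field(default_factory=list)
    threshold: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "median_similar": self.median_similar,
            "median_other": self.median_other,
            "threshold": self.threshold,
        }


@dataclass
class SimilarPairSelection:
    """Pairs passing both thresholds, sorted by COEXsim descending."""

    pairs: list[tuple[str, str, float, float]]
    t_coexsim: float
    t_fuzzy: float

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["label_a", "label_b", "coexsim", "fuzzy"]
        )


def pairwise_matrix(
    networks: list[WeightedNetwork],
    measure: str = "coexsim",
    orbit_set: str = "orbits4",
) -> SimilarityMatrix:
    """Full square pairwise similarity (or GCD distance) matrix.

    For ``coexsim`` and ``fuzzy`` the diagonal is exactly 1.  For ``gcd``
    the returned matrix holds *distances* (diagonal 0); transform with
    :func:`coexsim.graphlets.gcd_to_similarity`.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    labels = [n.label for n in networks]
    if len(networks) < 2:
        raise ValueError("pairwise_matrix requires at least 2 networks")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate network labels")
    out = np.zeros((len(networks), len(networks)))
    for i, a in enumerate(networks):
        for j in range(i, len(networks)):
            b = networks[j]
            if measure == "coexsim":
                v = _measures.coexsim(a, b)
            elif measure == "fuzzy":
                v = _measures.fuzzy_similarity(a, b)
            else:
                v = 0.0 if i == j else _graphlets.gcd(a, b, orbit_set)
            out[i, j] = out[j, i] = v
    return SimilarityMatrix(
        values=pd.DataFrame(out, index=labels, columns=labels), measure_name=measure
    )


def _scope_values(values: pd.DataFrame, pair_scope: str) -> np.ndarray:
    v = values.to_numpy(dtype=float)
    if pair_scope == "full":
        return v.ravel()
    if pair_scope == "offdiag":
        return v[~np.eye(len(v), dtype=bool)]
    if pair_scope == "upper":
        return v[np.triu_indices_from(v, k=1)]
    raise ValueError(f"pair_scope must be one of {PAIR_SCOPES}")


def spearman_profile(x, y) -> tuple[float, float]:
    """Spearman rank correlation of two paired 1-D score profiles.

    Average ranks for ties; p-value from the t-approximation with n - 2
    degrees of freedom.  Raises on constant input, where the rank
    correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("profiles must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant profile: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_validation(
    profile: SimilarityMatrix, gold: GoldStandard, pair_scope: str = "full"
) -> tuple[float, float]:
    """Spearman rank correlation of a similarity profile to a gold standard.

    Both matrices are flattened over the chosen pair scope (``full`` uses
    all |L|^2 cells including the diagonal and both orientations) and
    correlated with average ranks for ties; the p-value comes from the
    t-approximation with n - 2 degrees of freedom.
    """
    if set(profile.labels) != set(gold.labels):
        raise ValueError("profile and gold standard label sets differ")
    aligned = profile.values.loc[gold.labels, gold.labels]
    return spearman_profile(
        _scope_values(aligned, pair_scope), _scope_values(gold.values, pair_scope)
    )


def group_medians(
    matrix: SimilarityMatrix,
    groups: dict[str, str],
    similar_group: str,
) -> tuple[float, float]:
    """Median within-group score vs. median of all other matrix cells.

    The within-group block is the full |G| x |G| sub-matrix *including*
    the diagonal (a 5-member group contributes 25 values); every other
    cell of the full matrix belongs to the "other pairs" population.
    """
    unknown = set(groups) - set(matrix.labels)
    if unknown:
        raise ValueError(f"group file references unknown labels: {sorted(unknown)}")
    members = sorted(lab for lab, g in groups.items() if g == similar_group)
    if len(members) < 2:
        raise ValueError(f"similar group {similar_group!r} needs >= 2 members")
    v = matrix.values
    in_group = v.index.isin(members)
    block = v.loc[in_group, v.columns.isin(members)].to_numpy(dtype=float)
    mask = np.outer(in_group, v.columns.isin(members))
    others = v.to_numpy(dtype=float)[~mask]
    return float(median(block.ravel())), float(median(others.ravel()))


def evaluate_threshold(median_similar_exp1: float, median_similar_exp2: float) -> float:
    """Decision threshold: mean of the two similar-group medians."""
    if median_similar_exp1 < 0 or median_similar_exp2 < 0:
        raise ValueError("medians must be nonnegative")
    return (median_similar_exp1 + median_similar_exp2) / 2.0


def select_similar_pairs(
    coexsim_matrix: SimilarityMatrix,
    fuzzy_matrix: SimilarityMatrix,
    t_coexsim: float,
    t_fuzzy: float,
) -> SimilarPairSelection:
    """Pairs with COEXsim > t_coexsim AND fuzzy > t_fuzzy (strict).

    Matrices may be rectangular (e.g., disease modules x aging modules);
    they must share row and column label sets.  When a matrix is square
    with identical row/column labels, only unordered off-diagonal pairs
    are considered, so self-pairs are never reported.  Results are sorted
    by COEXsim descending (ties broken by fuzzy, then labels).
    """
    c, f = coexsim_matrix.values, fuzzy_matrix.values
    if set(c.index) != set(f.index) or set(c.columns) != set(f.columns):
        raise ValueError("coexsim and fuzzy matrices have mismatched label sets")
    f = f.loc[c.index, c.columns]
    pairs: list[tuple[str, str, float, float]] = []
    square = set(c.index) == set(c.columns)
    for i, ra in enumerate(c.index):
        for j, cb in enumerate(c.columns):
            if square and (ra == cb or ra > cb):
                continue
            cv, fv = float(c.iat[i, j]), float(f.iat[i, j])
            if cv > t_coexsim and fv > t_fuzzy:
                pairs.append((ra, cb, cv, fv))
    pairs.sort(key=lambda p: (-p[2], -p[3], p[0], p[1]))
    return SimilarPairSelection(pairs=pairs, t_coexsim=t_coexsim, t_fuzzy=t_fuzzy)
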