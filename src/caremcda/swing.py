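"""SMARTER swing weighting: rankings of criteria to normalized weights.

Respondents imagine a programme at the worst level on every criterion and
repeatedly pick the criterion they would swing to its best level next,
producing a full ranking without ties.  The ranking is converted to weights
with the rank-ordered-centroid (ROC) rule

    w_k = (1/K) * sum_{i=k}^{K} 1/i,   k = 1..K,

the expected weight of the k-th largest coordinate of a uniform draw from
the simplex.  A rank-sum alternative is available behind a flag.  Group
weights pool individual vectors by arithmetic mean (median optional) and
renormalize.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .scoring import WeightVector

STAKEHOLDER_GROUPS = ("patients", "partners", "professionals", "payers", "policy_makers")


@dataclass(frozen=True)
class SwingRanking:
    """One respondent's complete swing ranking (first = most important)."""

    respondent_id: str
    stakeholder_group: str
    ranking: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ranking)) != len(self.ranking):
            dupes = sorted({c for c in self.ranking if self.ranking.count(c) > 1})
            raise ValueError(
                f"respondent {self.respondent_id!r}: duplicated criteria {dupes} "
                "(ties are not part of the elicitation protocol)"
            )
        if not self.ranking:
            raise ValueError("empty ranking")


def roc_weights(k: int) -> np.ndarray:
    """Rank-ordered-centroid weights for ``k`` ranked criteria.

    Strictly decreasing, sums to 1 exactly in rational arithmetic.
    """
    if k < 1:
        raise ValueError(f"need at least one criterion, got k={k}")
    # 1/K * sum_{i=rank..K} 1/i, computed from the tail inward
    inv = 1.0 / np.arange(1, k + 1)
    return np.cumsum(inv[::-1])[::-1] / k


def roc_weights_exact(k: int) -> list[Fraction]:
    """ROC weights as exact rationals (oracle-grade arithmetic)."""
    if k < 1:
        raise ValueError(f"need at least one criterion, got k={k}")
    return [
        sum((Fraction(1, i) for i in range(rank, k + 1)), Fraction(0)) / k
        for rank in range(1, k + 1)
    ]


def rank_sum_weights(k: int) -> np.ndarray:
    """Rank-sum alternative: w_k = (K - k + 1) / (K(K+1)/2)."""
    if k < 1:
        raise ValueError(f"need at least one criterion, got k={k}")
    raw = np.arange(k, 0, -1, dtype=float)
    return raw / raw.sum()


_RULES = {"roc": roc_weights, "rank_sum": rank_sum_weights}


def ranking_to_weights(
    ranking: SwingRanking,
    expected_criteria: Sequence[str] | None = None,
    rule: str = "roc",
) -> WeightVector:
    """Convert one swing ranking into a weight vector.

    If ``expected_criteria`` is given, the ranking must be a permutation of
    exactly that set.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown rank-to-weight rule {rule!r}; valid: {sorted(_RULES)}")
    if expected_criteria is not None:
        expected = set(expected_criteria)
        got = set(ranking.ranking)
        if got != expected:
            raise ValueError(
                f"respondent {ranking.respondent_id!r}: ranking is not a "
                f"permutation of the criteria set (missing={sorted(expected - got)}, "
                f"unexpected={sorted(got - expected)})"
            )
    w = _RULES[rule](len(ranking.ranking))
    return WeightVector(
        dict(zip(ranking.ranking, w.tolist())),
        method="swing",
        stakeholder_group=ranking.stakeholder_group,
    )


def pool_weights(
    vectors: Iterable[WeightVector],
    mode: str = "within_group",
    estimator: str = "mean",
) -> WeightVector:
    """Pool weight vectors over the same criteria set.

    ``mode`` labels the provenance only (within_group keeps the common
    stakeholder group if there is one; across_groups records "pooled").
    ``estimator`` is "mean" (default convention) or "median"; the result is
    renormalized to sum 1.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no weight vectors to pool")
    if mode not in ("within_group", "across_groups"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    if estimator not in ("mean", "median"):
        raise ValueError(f"unknown pooling estimator {estimator!r}")
    ids = vectors[0].criterion_ids
    for v in vectors[1:]:
        if set(v.criterion_ids) != set(ids):
            raise ValueError("cannot pool weight vectors over different criteria sets")
    mat = np.array([[v[cid] for cid in ids] for v in vectors], dtype=float)
    pooled = mat.mean(axis=0) if estimator == "mean" else np.median(mat, axis=0)
    pooled = pooled / pooled.sum()
    groups = {v.stakeholder_group for v in vectors}
    group = groups.pop() if (mode == "within_group" and len(groups) == 1) else "pooled"
    return WeightVector(dict(zip(ids, pooled.tolist())), method="swing", stakeholder_group=group)


def group_swing_weights(
    rankings: Iterable[SwingRanking],
    expected_criteria: Sequence[str] | None = None,
    rule: str = "roc",
    estimator: str = "mean",
) -> dict[str, WeightVector]:
    """Per-stakeholder-group pooled swing weights from raw rankings."""
    by_group: dict[str, list[WeightVector]] = {}
    for r in rankings:
        by_group.setdefault(r.stakeholder_group, []).append(
            ranking_to_weights(r, expected_criteria, rule)
        )
    return {
        g: pool_weights(vs, mode="within_group", estimator=estimator)
        for g, vs in by_group.items()
    }
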