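"""Weighted-sum value scoring for a two-alternative MCDA.

Raw performance x_aj (intervention) and x_bj (comparator) on criterion j is
standardized by vector normalization,

    S_aj = x_aj / sqrt(x_aj^2 + x_bj^2),

so that for every benefit criterion S_aj^2 + S_bj^2 = 1.  Cost-direction
criteria take the complement 1 - x/||(x_a, x_b)||, so that lower spending
scores higher.  Overall value is the weight-weighted sum of standardized
scores; with weights on the simplex and S in [0, 1] the overall value is
itself in [0, 1].

Standardization is pairwise by construction: it is defined for exactly two
alternatives and is not generalized further here.

All aggregation uses unrounded standardized values; the 2-dp / 3-dp rounding
used in reports is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .criteria import CriteriaSet

TIE_TOL = 1e-12
WEIGHT_SUM_TOL = 1e-9


class DegeneratePairError(ValueError):
    """Both performance scores are zero: the pair cannot be standardized."""


def standardize_pair(x_a: float, x_b: float, direction: str) -> tuple[float, float]:
    """Standardize one criterion's performance pair to [0, 1].

    Benefit: S = x / sqrt(x_a^2 + x_b^2).  Cost: S = 1 - x / sqrt(...).
    Inputs must be nonnegative and not both zero.
    """
    if direction not in ("benefit", "cost"):
        raise ValueError(f"unknown direction {direction!r}")
    if x_a < 0 or x_b < 0:
        raise ValueError(
            f"standardization requires nonnegative scores, got ({x_a}, {x_b})"
        )
    norm = float(np.hypot(x_a, x_b))
    if norm == 0.0:
        raise DegeneratePairError("both performance scores are zero")
    s_a, s_b = x_a / norm, x_b / norm
    if direction == "cost":
        s_a, s_b = 1.0 - s_a, 1.0 - s_b
    return s_a, s_b


@dataclass(frozen=True)
class PerformanceTable:
    """Per-criterion mean and standard error for the two alternatives.

    ``cells`` maps (alternative, criterion_id) -> (mean, se).  Alternative
    labels are ordered: first = intervention (integrated care), second =
    comparator (usual care).
    """

    alternatives: tuple[str, str]
    cells: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.alternatives) != 2 or self.alternatives[0] == self.alternatives[1]:
            raise ValueError("exactly two distinct alternatives required")
        for (alt, cid), (mean, se) in self.cells.items():
            if alt not in self.alternatives:
                raise ValueError(f"unknown alternative {alt!r} in cell ({alt}, {cid})")
            if se < 0:
                raise ValueError(f"negative se for ({alt}, {cid})")

    @property
    def intervention(self) -> str:
        return self.alternatives[0]

    @property
    def comparator(self) -> str:
        return self.alternatives[1]

    def criterion_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for (_, cid) in self.cells:
            if cid not in seen:
                seen.append(cid)
        return tuple(seen)

    def mean(self, alt: str, cid: str) -> float:
        return self.cells[(alt, cid)][0]

    def se(self, alt: str, cid: str) -> float:
        return self.cells[(alt, cid)][1]

    def validate_against(self, cs: CriteriaSet) -> None:
        """Check completeness and range containment for a criteria set."""
        for c in cs:
            for alt in self.alternatives:
                if (alt, c.id) not in self.cells:
                    raise ValueError(
                        f"performance table missing criterion {c.id!r} for "
                        f"alternative {alt!r}"
                    )
                mean = self.mean(alt, c.id)
                if not (c.scale_min <= mean <= c.scale_max):
                    raise ValueError(
                        f"mean {mean} for ({alt}, {c.id}) outside scale "
                        f"[{c.scale_min}, {c.scale_max}]"
                    )

    def drop_criterion(self, cid: str) -> "PerformanceTable":
        return PerformanceTable(
            self.alternatives,
            {k: v for k, v in self.cells.items() if k[1] != cid},
        )


@dataclass(frozen=True)
class StandardizedTable:
    """Standardized scores in [0,1] per (alternative, criterion)."""

    alternatives: tuple[str, str]
    criterion_ids: tuple[str, ...]
    scores: dict[tuple[str, str], float]

    def score(self, alt: str, cid: str) -> float:
        return self.scores[(alt, cid)]


@dataclass(frozen=True)
class WeightVector:
    """Normalized criterion weights with elicitation provenance."""

    weights: dict[str, float]
    method: str = "unspecified"  # dce | swing | pooled | unspecified
    stakeholder_group: str = "pooled"

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(vals.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"weights must sum to 1 (got {vals.sum():.12f})")

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def __getitem__(self, cid: str) -> float:
        return self.weights[cid]


@dataclass(frozen=True)
class ValueResult:
    """Overall value scores plus the per-criterion weighted contributions."""

    alternatives: tuple[str, str]
    values: dict[str, float]
    contributions: dict[tuple[str, str], float]

    def value(self, alt: str) -> float:
        return self.values[alt]

    def contribution(self, alt: str, cid: str) -> float:
        return self.contributions[(alt, cid)]


def standardize_table(perf: PerformanceTable, cs: CriteriaSet) -> StandardizedTable:
    """Standardize every criterion pair of a performance table."""
    perf.validate_against(cs)
    a, b = perf.alternatives
    scores: dict[tuple[str, str], float] = {}
    for c in cs:
        s_a, s_b = standardize_pair(perf.mean(a, c.id), perf.mean(b, c.id), c.direction)
        scores[(a, c.id)] = s_a
        scores[(b, c.id)] = s_b
    return StandardizedTable(perf.alternatives, cs.ids, scores)


def overall_value(std: StandardizedTable, w: WeightVector) -> ValueResult:
    """Aggregate standardized scores into overall value per alternative."""
    if set(w.criterion_ids) != set(std.criterion_ids):
        missing = set(std.criterion_ids) - set(w.criterion_ids)
        extra = set(w.criterion_ids) - set(std.criterion_ids)
        raise ValueError(
            f"weight vector does not match criteria (missing={sorted(missing)}, "
            f"extra={sorted(extra)})"
        )
    contributions: dict[tuple[str, str], float] = {}
    values: dict[str, float] = {}
    for alt in std.alternatives:
        total = 0.0
        for cid in std.criterion_ids:
            contrib = w[cid] * std.score(alt, cid)
            contributions[(alt, cid)] = contrib
            total += contrib
        values[alt] = total
    return ValueResult(std.alternatives, values, contributions)


def preferred_alternative(result: ValueResult, tol: float = TIE_TOL) -> str:
    """Label of the higher-valued alternative, or ``"tie"`` within ``tol``."""
    a, b = result.alternatives
    diff = result.value(a) - result.value(b)
    if abs(diff) <= tol:
        return "tie"
    return a if diff > 0 else b


def score_pipeline(
    perf: PerformanceTable, cs: CriteriaSet, w: WeightVector
) -> ValueResult:
    """Convenience: standardize then aggregate."""
    return overall_value(standardize_table(perf, cs), w)
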