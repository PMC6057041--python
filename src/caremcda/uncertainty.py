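"""Uncertainty analysis: deterministic sensitivity analyses, Monte-Carlo
probabilistic sensitivity analysis (PSA), and the Conditional Multi-attribute
Acceptability Curve (CMAC).

The PSA propagates parameter uncertainty in the performance estimates
(normal around each mean, scaled by its standard error and truncated to the
criterion's scale range) and in the criterion weights (multivariate normal
on the DCE part-worths via their estimated covariance, or a respondent
bootstrap for swing rankings) through the full standardize-and-aggregate
pipeline.

The CMAC plots, against a budget threshold B, the probability that the
intervention both has the higher overall value score and keeps its budget
impact (population size times its drawn mean cost, or the incremental cost
versus the comparator) at or below B.  Its limit for large B is the
unconditional probability that the intervention is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .criteria import CriteriaSet
from .dce import PartWorths
from .scoring import (
    PerformanceTable,
    ValueResult,
    WeightVector,
    overall_value,
    preferred_alternative,
    score_pipeline,
    standardize_table,
)
from .swing import SwingRanking, pool_weights, ranking_to_weights


# ---------------------------------------------------------------------------
# Deterministic sensitivity analyses

def renormalize_without(w: WeightVector, criterion_id: str) -> WeightVector:
    """Drop one criterion and rescale the remaining weights to sum 1."""
    if criterion_id not in w.weights:
        raise ValueError(f"criterion {criterion_id!r} not in weight vector")
    rest = {cid: wt for cid, wt in w.weights.items() if cid != criterion_id}
    if len(rest) < 2:
        raise ValueError("removing the criterion would leave fewer than two criteria")
    total = sum(rest.values())
    if total <= 0:
        raise ValueError("remaining weights sum to zero; cannot renormalize")
    return WeightVector(
        {cid: wt / total for cid, wt in rest.items()},
        method=w.method,
        stakeholder_group=w.stakeholder_group,
    )


@dataclass(frozen=True)
class ExclusionResult:
    excluded: str
    with_criterion: ValueResult
    without_criterion: ValueResult

    @property
    def preference_flipped(self) -> bool:
        return preferred_alternative(self.with_criterion) != preferred_alternative(
            self.without_criterion
        )


def exclude_criterion_sa(
    perf: PerformanceTable, cs: CriteriaSet, w: WeightVector, criterion_id: str
) -> ExclusionResult:
    """Value scores with and without one (e.g. dominating) criterion."""
    base = score_pipeline(perf, cs, w)
    reduced_cs = cs.subset([c for c in cs.ids if c != criterion_id])
    if len(reduced_cs) < 2:
        raise ValueError("removing the criterion would leave fewer than two criteria")
    reduced = score_pipeline(
        perf.drop_criterion(criterion_id), reduced_cs, renormalize_without(w, criterion_id)
    )
    return ExclusionResult(criterion_id, base, reduced)


@dataclass(frozen=True)
class WeightMethodComparison:
    result_dce: ValueResult
    result_swing: ValueResult
    preferred_dce: str
    preferred_swing: str

    @property
    def agreement(self) -> bool:
        return self.preferred_dce == self.preferred_swing


def weight_method_swap_sa(
    perf: PerformanceTable,
    cs: CriteriaSet,
    w_dce: WeightVector,
    w_swing: WeightVector,
) -> WeightMethodComparison:
    """Compare conclusions under DCE-derived versus swing-derived weights."""
    std = standardize_table(perf, cs)
    r_dce = overall_value(std, w_dce)
    r_swing = overall_value(std, w_swing)
    return WeightMethodComparison(
        r_dce, r_swing, preferred_alternative(r_dce), preferred_alternative(r_swing)
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis

@dataclass(frozen=True)
class PSAConfig:
    """Configuration of the Monte-Carlo PSA and the CMAC budget grid.

    ``population_size`` is the number of persons treated over the budget
    horizon; ``budget_grid`` the strictly increasing currency thresholds of
    the CMAC x-axis.  ``budget_impact`` is "total" (population times the
    intervention's drawn mean cost) or "incremental" (intervention minus
    comparator).  ``include_cost_in_value`` keeps the cost criterion inside
    the value score (the default) even though it also drives the budget
    condition.
    """

    n_draws: int
    seed: int
    population_size: int
    budget_grid: tuple[float, ...]
    cost_criterion_id: str = "total_costs"
    budget_impact: str = "total"
    include_cost_in_value: bool = True

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        grid = np.asarray(self.budget_grid, dtype=float)
        if grid.size and not (np.diff(grid) > 0).all():
            raise ValueError("budget_grid must be strictly increasing")
        if self.budget_impact not in ("total", "incremental"):
            raise ValueError("budget_impact must be 'total' or 'incremental'")


def _sample_truncated_normal(
    rng: np.random.Generator,
    mean: float,
    se: float,
    lower: float,
    upper: float,
    size: int,
) -> np.ndarray:
    """Normal(mean, se) truncated to [lower, upper]; degenerate when se=0."""
    if se == 0.0:
        return np.full(size, mean)
    a, b = (lower - mean) / se, (upper - mean) / se
    dist = stats.truncnorm(a, b, loc=mean, scale=se)
    return dist.rvs(size=size, random_state=rng)


def _coefficient_draws(
    rng: np.random.Generator, beta: PartWorths, n_draws: int
) -> np.ndarray:
    p = beta.coefficients.shape[0]
    cov = beta.covariance
    if cov is None:
        return np.tile(beta.coefficients, (n_draws, 1))
    eigvals, eigvecs = np.linalg.eigh(cov)
    floor = -1e-10 * max(1.0, float(np.abs(eigvals).max()))
    if (eigvals < floor).any():
        raise ValueError(
            f"part-worth covariance is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3e})"
        )
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    z = rng.standard_normal((n_draws, p))
    return beta.coefficients + z @ root.T


def _weights_from_coefficient_draws(
    draws: np.ndarray, attribute_ids: Sequence[str], criterion_order: Sequence[str]
) -> np.ndarray:
    """Per-draw weights from good-level part-worths, clipped at zero.

    Sampled good-level coefficients can go negative even when the point
    estimate is positive; such draws are floored at zero before
    renormalizing so the simulation never aborts mid-run.
    """
    good = np.clip(draws[:, 1::2], 0.0, None)
    totals = good.sum(axis=1)
    # a draw with every good-level part-worth <= 0 carries no preference
    # information; fall back to uniform weights for that draw
    uniform = np.full(good.shape[1], 1.0 / good.shape[1])
    out = np.where(totals[:, None] > 0, good / np.where(totals == 0, 1, totals)[:, None], uniform)
    col = {aid: j for j, aid in enumerate(attribute_ids)}
    order = [col[cid] for cid in criterion_order]
    return out[:, order]


def _swing_bootstrap_weights(
    rng: np.random.Generator,
    rankings: Sequence[SwingRanking],
    criterion_order: Sequence[str],
    n_draws: int,
) -> np.ndarray:
    """Per-draw weights by resampling respondents' rankings with replacement."""
    base = [ranking_to_weights(r, criterion_order) for r in rankings]
    n = len(base)
    out = np.empty((n_draws, len(criterion_order)))
    for d in range(n_draws):
        idx = rng.integers(0, n, size=n)
        pooled = pool_weights([base[i] for i in idx], mode="across_groups")
        out[d] = [pooled[cid] for cid in criterion_order]
    return out


def run_psa(
    perf: PerformanceTable,
    cs: CriteriaSet,
    cfg: PSAConfig,
    beta: PartWorths | None = None,
    swing_rankings: Sequence[SwingRanking] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo draw matrix propagating performance and weight uncertainty.

    Exactly one weight-uncertainty source must be given: DCE part-worths
    with covariance (multivariate-normal draws) or swing rankings
    (respondent bootstrap).  Returns one row per draw with the two overall
    values and the drawn mean costs of both alternatives.
    """
    if (beta is None) == (swing_rankings is None):
        raise ValueError("provide exactly one of beta (DCE) or swing_rankings")
    perf.validate_against(cs)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_draws

    value_ids = [
        cid for cid in cs.ids if cfg.include_cost_in_value or cid != cfg.cost_criterion_id
    ]
    if beta is not None:
        coef_draws = _coefficient_draws(rng, beta, n)
        weights = _weights_from_coefficient_draws(coef_draws, beta.attribute_ids, value_ids)
    else:
        weights = _swing_bootstrap_weights(rng, swing_rankings, value_ids, n)

    alt_i, alt_c = perf.alternatives
    perf_draws: dict[tuple[str, str], np.ndarray] = {}
    for c in cs:
        for alt in perf.alternatives:
            perf_draws[(alt, c.id)] = _sample_truncated_normal(
                rng, perf.mean(alt, c.id), perf.se(alt, c.id), c.scale_min, c.scale_max, n
            )

    values = {alt: np.zeros(n) for alt in perf.alternatives}
    for w_col, cid in enumerate(value_ids):
        c = cs.get(cid)
        x_a = perf_draws[(alt_i, cid)]
        x_b = perf_draws[(alt_c, cid)]
        norm = np.hypot(x_a, x_b)
        if (norm == 0).any():
            raise ValueError(f"degenerate zero pair drawn for criterion {cid!r}")
        s_a, s_b = x_a / norm, x_b / norm
        if c.direction == "cost":
            s_a, s_b = 1.0 - s_a, 1.0 - s_b
        values[alt_i] += weights[:, w_col] * s_a
        values[alt_c] += weights[:, w_col] * s_b

    return pd.DataFrame(
        {
            "value_intervention": values[alt_i],
            "value_comparator": values[alt_c],
            "cost_intervention": perf_draws[(alt_i, cfg.cost_criterion_id)],
            "cost_comparator": perf_draws[(alt_c, cfg.cost_criterion_id)],
        }
    )


# ---------------------------------------------------------------------------
# CMAC

@dataclass(frozen=True)
class CMACCurve:
    """Acceptance probability per budget threshold plus the unconditional cap."""

    thresholds: tuple[float, ...]
    probability: tuple[float, ...]
    unconditional_probability: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "probability": self.probability}
        )

    def plot(self, path=None, ax=None):
        """Render the curve (threshold vs acceptance probability)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.step(self.thresholds, self.probability, where="post")
        ax.axhline(self.unconditional_probability, ls="--", color="grey",
                   label="unconditional preference probability")
        ax.set_xlabel("budget threshold")
        ax.set_ylabel("P(intervention preferred and affordable)")
        ax.set_ylim(0, 1)
        ax.legend(loc="lower right", fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        return ax


def budget_impact(draws: pd.DataFrame, cfg: PSAConfig) -> np.ndarray:
    """Per-draw budget impact on the currency scale of the budget grid."""
    cost = draws["cost_intervention"].to_numpy()
    if cfg.budget_impact == "incremental":
        cost = cost - draws["cost_comparator"].to_numpy()
    return cfg.population_size * cost


def cmac(draws: pd.DataFrame, cfg: PSAConfig) -> CMACCurve:
    """Conditional Multi-attribute Acceptability Curve from a PSA draw matrix.

    probability(B) = fraction of draws in which the intervention has the
    strictly higher overall value AND its budget impact is at most B.
    """
    if draws.empty:
        raise ValueError("empty draw matrix")
    if not cfg.budget_grid:
        raise ValueError("empty budget grid")
    preferred = (
        draws["value_intervention"].to_numpy() > draws["value_comparator"].to_numpy()
    )
    impact = budget_impact(draws, cfg)
    probs = tuple(
        float(np.mean(preferred & (impact <= b))) for b in cfg.budget_grid
    )
    return CMACCurve(tuple(float(b) for b in cfg.budget_grid), probs, float(preferred.mean()))
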