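"""Synthetic study generator with known ground truth.

Real evaluations feed this framework three inputs: two-arm performance
estimates on the core outcomes, DCE choice data, and swing rankings.  None
of these are publicly deposited, so this module simulates all three from an
explicit :class:`TruthSpec`, making every downstream stage testable for
recovery of known quantities.

The default truth encodes a fully worked two-programme example: the two-programme
performance table on the eight core outcomes, and two hypothetical
stakeholder-group weight vectors (P1, P2).  The true DCE part-worths are
anchored to the P1 weights (good-level coefficient proportional to the P1
weight, average level at half the good level) so that weight recovery has a
known target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .criteria import CriteriaSet, build_core_set
from .dce import ChoiceRecord, DCEDesign, PartWorths, choice_probability
from .scoring import PerformanceTable, WeightVector
from .swing import SwingRanking

# Worked-example performance means (intervention, comparator) per criterion.
EXAMPLE_MEANS = {
    "physical_functioning": (60.0, 70.0),
    "psychological_wellbeing": (70.0, 50.0),
    "social_participation": (3.0, 4.0),
    "resilience": (2.0, 4.0),
    "enjoyment_of_life": (4.0, 3.0),
    "person_centeredness": (4.0, 3.0),
    "continuity_of_care": (5.0, 3.0),
    "total_costs": (8000.0, 6000.0),
}

# Hypothetical stakeholder-group weights of the worked example.
P1_WEIGHTS = {
    "physical_functioning": 0.100,
    "psychological_wellbeing": 0.150,
    "social_participation": 0.125,
    "resilience": 0.050,
    "enjoyment_of_life": 0.300,
    "person_centeredness": 0.100,
    "continuity_of_care": 0.125,
    "total_costs": 0.050,
}
P2_WEIGHTS = {
    "physical_functioning": 0.250,
    "psychological_wellbeing": 0.100,
    "social_participation": 0.100,
    "resilience": 0.100,
    "enjoyment_of_life": 0.150,
    "person_centeredness": 0.050,
    "continuity_of_care": 0.050,
    "total_costs": 0.200,
}

# True good-level part-worths: good_j = BASE + SLOPE * w_j, an affine map of
# the example P1 weights.  This keeps the example's importance rank order
# while placing every poor-to-good swing utility in the 0.6-1.1 range typical
# of fitted stated-preference models (choice consistency around 70-80%).
PARTWORTH_GOOD_BASE = 0.5
PARTWORTH_GOOD_SLOPE = 2.0


def example_weights() -> tuple[WeightVector, WeightVector]:
    """The two hypothetical stakeholder-group weight vectors (P1, P2)."""
    return (
        WeightVector(dict(P1_WEIGHTS), method="dce", stakeholder_group="P1"),
        WeightVector(dict(P2_WEIGHTS), method="dce", stakeholder_group="P2"),
    )


def example_performance_table(alternatives=("integrated_care", "usual_care"), se=None):
    """The worked-example performance table; ``se`` maps criterion -> SE (default 0)."""
    se = se or {}
    cells = {}
    for cid, (m_i, m_c) in EXAMPLE_MEANS.items():
        cells[(alternatives[0], cid)] = (m_i, float(se.get(cid, 0.0)))
        cells[(alternatives[1], cid)] = (m_c, float(se.get(cid, 0.0)))
    return PerformanceTable(tuple(alternatives), cells)


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth from which all synthetic inputs are generated."""

    criteria: CriteriaSet
    part_worths: PartWorths
    group_weights: dict[str, WeightVector]
    performance: PerformanceTable  # cells hold the TRUE means plus SEs
    population_size: int
    seed: int

    def __post_init__(self) -> None:
        self.performance.validate_against(self.criteria)
        for w in self.group_weights.values():
            if set(w.criterion_ids) != set(self.criteria.ids):
                raise ValueError("true group weights must cover the criteria set")


def _partworths_from_weights(cs: CriteriaSet, weights: dict[str, float]) -> PartWorths:
    coef = np.empty(2 * len(cs))
    for j, c in enumerate(cs):
        good = PARTWORTH_GOOD_BASE + PARTWORTH_GOOD_SLOPE * weights[c.id]
        coef[2 * j] = 0.5 * good  # average level midway between poor and good
        coef[2 * j + 1] = good
    return PartWorths(cs.ids, coef)


def default_truth(se_fraction: float = 0.05, population_size: int = 1000, seed: int = 0) -> TruthSpec:
    """Worked-example truth with SEs at ``se_fraction`` of each scale range."""
    cs = build_core_set()
    se = {
        c.id: se_fraction * (c.scale_max - c.scale_min) for c in cs
    }
    perf = example_performance_table(se=se)
    w1, w2 = example_weights()
    return TruthSpec(
        criteria=cs,
        part_worths=_partworths_from_weights(cs, P1_WEIGHTS),
        group_weights={"P1": w1, "P2": w2},
        performance=perf,
        population_size=population_size,
        seed=seed,
    )


def worked_example_truth(population_size: int = 1000, seed: int = 0) -> TruthSpec:
    """Deterministic worked-example truth (all SEs zero)."""
    return default_truth(se_fraction=0.0, population_size=population_size, seed=seed)


# ---------------------------------------------------------------------------
# Generators (pure functions of spec + seed)

def simulate_trial(truth: TruthSpec, seed: int | None = None) -> PerformanceTable:
    """Observed two-arm performance estimates around the true means.

    Observed mean = true mean + normal noise with the cell's SE, truncated
    to the criterion's scale range so the table stays valid; SEs are copied
    through unchanged.  With SE = 0 the true means are reproduced exactly.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    cells = {}
    for (alt, cid), (mean, se) in truth.performance.cells.items():
        c = truth.criteria.get(cid)
        if se == 0.0:
            obs = mean
        else:
            from scipy import stats

            a = (c.scale_min - mean) / se
            b = (c.scale_max - mean) / se
            obs = float(stats.truncnorm(a, b, loc=mean, scale=se).rvs(random_state=rng))
        cells[(alt, cid)] = (obs, se)
    return PerformanceTable(truth.performance.alternatives, cells)


def simulate_dce_responses(
    design: DCEDesign,
    truth: TruthSpec,
    n_respondents: int,
    seed: int | None = None,
    stakeholder_group: str = "patients",
) -> list[ChoiceRecord]:
    """Respondents answering one random sub-design each under the true utilities.

    Each respondent draws a uniform-random sub-design and answers all of its
    choice sets; each answer is Bernoulli with the logit choice probability
    at the true part-worths.
    """
    if n_respondents < 1:
        raise ValueError("need at least one respondent")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    records: list[ChoiceRecord] = []
    for r in range(n_respondents):
        sub = int(rng.integers(0, design.n_sub_designs))
        for t in range(design.n_sets):
            p_a = choice_probability(design.choice_set(sub, t), truth.part_worths)
            chosen = "A" if rng.random() < p_a else "B"
            records.append(
                ChoiceRecord(f"r{r:05d}", stakeholder_group, sub, t, chosen)
            )
    return records


def simulate_swing_rankings(
    truth: TruthSpec,
    n_respondents: int,
    noise_sd: float,
    seed: int | None = None,
    stakeholder_group: str = "patients",
    group: str = "P1",
) -> list[SwingRanking]:
    """Respondents ranking criteria by perturbed true weights.

    Each respondent perceives weight_j + Normal(0, noise_sd) and ranks
    descending (additive perturbation on the weight scale).  With
    noise_sd = 0 every respondent reproduces the true-weight rank order
    (ties broken by criteria-set order, deterministically).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    w = truth.group_weights[group]
    ids = list(truth.criteria.ids)
    base = np.array([w[cid] for cid in ids])
    rankings = []
    for r in range(n_respondents):
        perceived = base + (rng.normal(0.0, noise_sd, size=len(ids)) if noise_sd else 0.0)
        order = np.argsort(-perceived, kind="stable")
        rankings.append(
            SwingRanking(
                f"r{r:05d}", stakeholder_group, tuple(ids[i] for i in order)
            )
        )
    return rankings
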