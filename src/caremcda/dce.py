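"""Discrete choice experiment engine for criterion-weight elicitation.

Respondents repeatedly choose between two hypothetical care programmes
described by their performance (poor / average / good) on the eight core
outcome criteria.  Part-worth utilities are estimated by conditional-logit
maximum likelihood on the paired choices; the relative sizes of the
good-level (best-level) part-worths give the criterion weights.

Design generation targets local D-efficiency under a point prior, subject
to a level-overlap constraint: in every choice set exactly 4 or 5 of the 8
attributes take identical levels in both alternatives, which reduces the
cognitive burden of a task at the price of per-set information.  The design
is organised as 10 sub-designs of 18 choice sets each, every sub-design
blocked into 3 blocks of 6 questions; a respondent answers one randomly
assigned sub-design.

Coding: each attribute's three levels are dummy-coded against the poor
reference, so the model has 2 coefficients per attribute (average, good)
and the good-level coefficient is directly the poor-to-good swing utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

N_LEVELS = 3
LEVEL_LABELS = ("poor", "average", "good")


class SeparationError(RuntimeError):
    """The likelihood has no finite maximizer (separated / inestimable data)."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class CostLevels:
    """Three cost-attribute levels on the currency scale.

    The poor level is the country mean inflated by 20%, the good level the
    mean deflated by 20%; worst-to-best runs by decreasing cost.
    """

    mean_cost: float
    levels: tuple[float, float, float]  # (poor, average, good)


def make_cost_levels(mean_cost: float) -> CostLevels:
    if mean_cost <= 0:
        raise ValueError(f"mean cost must be positive, got {mean_cost}")
    return CostLevels(mean_cost, (1.2 * mean_cost, mean_cost, 0.8 * mean_cost))


@dataclass(frozen=True)
class DCEDesign:
    """Level-overlap-constrained paired-choice design.

    ``sub_designs[s][t]`` is an integer array of shape (2, n_attributes)
    giving the levels (0=poor, 1=average, 2=good) of alternatives A and B
    in choice set ``t`` of sub-design ``s``.  ``blocks`` partitions each
    sub-design's choice sets into blocks presented as question batches.
    """

    attribute_ids: tuple[str, ...]
    sub_designs: tuple[np.ndarray, ...]
    blocks: tuple[tuple[int, ...], ...]
    overlap_range: tuple[int, int] = (4, 5)

    @property
    def n_attributes(self) -> int:
        return len(self.attribute_ids)

    @property
    def n_sub_designs(self) -> int:
        return len(self.sub_designs)

    @property
    def n_sets(self) -> int:
        return self.sub_designs[0].shape[0]

    def choice_set(self, sub_design: int, choice_set: int) -> np.ndarray:
        return self.sub_designs[sub_design][choice_set]

    def validate(self) -> None:
        lo, hi = self.overlap_range
        for s, sd in enumerate(self.sub_designs):
            if sd.shape != (self.n_sets, 2, self.n_attributes):
                raise ValueError(f"sub-design {s} has shape {sd.shape}")
            if sd.min() < 0 or sd.max() >= N_LEVELS:
                raise ValueError(f"sub-design {s} has out-of-range levels")
            for t in range(sd.shape[0]):
                ov = int((sd[t, 0] == sd[t, 1]).sum())
                if not (lo <= ov <= hi):
                    raise ValueError(
                        f"choice set ({s},{t}) overlaps {ov} attributes; "
                        f"required {lo}..{hi}"
                    )
        covered = sorted(i for b in self.blocks for i in b)
        if covered != list(range(self.n_sets)):
            raise ValueError("blocks do not partition the choice sets")


@dataclass(frozen=True)
class ChoiceRecord:
    """One answered choice task."""

    respondent_id: str
    stakeholder_group: str
    sub_design_id: int
    choice_set_id: int
    chosen: str  # "A" or "B"

    def __post_init__(self) -> None:
        if self.chosen not in ("A", "B"):
            raise ValueError(f"chosen must be 'A' or 'B', got {self.chosen!r}")


@dataclass(frozen=True)
class PartWorths:
    """Dummy-coded part-worth estimates with their sampling covariance.

    ``coefficients`` has shape (2 * n_attributes,), ordered
    (attr0_average, attr0_good, attr1_average, attr1_good, ...), all
    relative to the poor reference level.
    """

    attribute_ids: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray | None = None
    log_likelihood: float | None = None
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        p = 2 * len(self.attribute_ids)
        if self.coefficients.shape != (p,):
            raise ValueError(
                f"expected {p} coefficients for {len(self.attribute_ids)} attributes, "
                f"got shape {self.coefficients.shape}"
            )
        if self.covariance is not None:
            if self.covariance.shape != (p, p):
                raise ValueError("covariance shape mismatch")
            if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
                raise ValueError("covariance must be symmetric")

    def coefficient(self, attribute_id: str, level: int) -> float:
        """Part-worth of one level (0=poor reference -> 0.0)."""
        j = self.attribute_ids.index(attribute_id)
        if level == 0:
            return 0.0
        return float(self.coefficients[2 * j + (level - 1)])

    def good_level_coefficients(self) -> np.ndarray:
        return self.coefficients[1::2].copy()


def uniform_prior(
    attribute_ids: Sequence[str], average: float = 0.25, good: float = 0.5
) -> PartWorths:
    """Small positive monotone default prior (good > average > poor = 0)."""
    k = len(attribute_ids)
    coef = np.tile([average, good], k).astype(float)
    return PartWorths(tuple(attribute_ids), coef)


# ---------------------------------------------------------------------------
# Coding and choice probabilities

def code_difference(pair: np.ndarray) -> np.ndarray:
    """Dummy-coded attribute difference A - B for one choice set.

    ``pair`` is (2, K) of levels; returns a length-2K vector whose entries
    for attribute j are (1[A=avg]-1[B=avg], 1[A=good]-1[B=good]).
    Overlapped attributes contribute zeros.
    """
    a, b = pair
    k = a.shape[0]
    out = np.zeros(2 * k)
    for lvl, off in ((1, 0), (2, 1)):
        out[off::2] = (a == lvl).astype(float) - (b == lvl).astype(float)
    return out


def choice_probability(pair: np.ndarray, beta: PartWorths) -> float:
    """Probability of choosing alternative A under a binary logit."""
    dx = code_difference(np.asarray(pair))
    if dx.shape[0] != beta.coefficients.shape[0]:
        raise ValueError(
            f"coded difference has {dx.shape[0]} entries but part-worths have "
            f"{beta.coefficients.shape[0]}"
        )
    v = float(dx @ beta.coefficients)
    return 1.0 / (1.0 + np.exp(-v))


def _design_matrix(design: DCEDesign) -> np.ndarray:
    """Stack coded differences for all (sub-design, set) pairs: (S*T, 2K)."""
    rows = [
        code_difference(sd[t])
        for sd in design.sub_designs
        for t in range(sd.shape[0])
    ]
    return np.array(rows)


# ---------------------------------------------------------------------------
# D-error

def _information(diffs: np.ndarray, coef: np.ndarray) -> np.ndarray:
    v = diffs @ coef
    p = 1.0 / (1.0 + np.exp(-v))
    w = p * (1.0 - p)
    return (diffs * w[:, None]).T @ diffs


def d_error(design: DCEDesign, prior: PartWorths) -> float:
    """Local D-error det(I)^(-1/p) at the point prior; +inf if singular."""
    diffs = _design_matrix(design)
    p = prior.coefficients.shape[0]
    if diffs.shape[1] != p:
        raise ValueError("prior dimension does not match design coding")
    info = _information(diffs, prior.coefficients)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        return float("inf")
    return float(np.exp(-logdet / p))


# ---------------------------------------------------------------------------
# Design optimization (coordinate exchange under the overlap constraint)

def _random_constrained_set(rng: np.random.Generator, k: int, lo: int, hi: int) -> np.ndarray:
    """Random pair of level profiles overlapping on ``lo`` or ``hi`` attributes."""
    n_overlap = int(rng.integers(lo, hi + 1))
    overlap_idx = rng.choice(k, size=n_overlap, replace=False)
    a = rng.integers(0, N_LEVELS, size=k)
    b = rng.integers(0, N_LEVELS, size=k)
    b[overlap_idx] = a[overlap_idx]
    for j in range(k):
        if j not in overlap_idx and a[j] == b[j]:
            b[j] = (b[j] + 1 + rng.integers(0, N_LEVELS - 1)) % N_LEVELS
    return np.stack([a, b])


def _default_blocks(n_sets: int, n_blocks: int = 3) -> tuple[tuple[int, ...], ...]:
    size = n_sets // n_blocks
    return tuple(
        tuple(range(i * size, (i + 1) * size if i < n_blocks - 1 else n_sets))
        for i in range(n_blocks)
    )


def random_design(
    attribute_ids: Sequence[str],
    n_subdesigns: int = 10,
    n_sets: int = 18,
    seed: int | np.random.Generator = 0,
    overlap_range: tuple[int, int] = (4, 5),
) -> DCEDesign:
    """Random design satisfying the overlap constraint (optimization start)."""
    rng = np.random.default_rng(seed)
    k = len(attribute_ids)
    lo, hi = overlap_range
    subs = tuple(
        np.stack([_random_constrained_set(rng, k, lo, hi) for _ in range(n_sets)])
        for _ in range(n_subdesigns)
    )
    return DCEDesign(tuple(attribute_ids), subs, _default_blocks(n_sets), overlap_range)


def optimize_design(
    prior: PartWorths,
    n_subdesigns: int = 10,
    n_sets: int = 18,
    seed: int | np.random.Generator = 0,
    overlap_range: tuple[int, int] = (4, 5),
    max_passes: int = 20,
) -> DCEDesign:
    """Greedy coordinate-exchange search for a low-D-error design.

    Single-attribute level swaps are proposed in turn for every
    (sub-design, set, alternative, attribute) coordinate and accepted only
    when the set keeps the overlap count it was initialized with (drawn
    uniformly from ``overlap_range``), the two alternatives stay distinct,
    and the local D-error strictly decreases.  Preserving the per-set
    overlap count keeps the intended mix of 4- and 5-overlap tasks instead
    of letting the search collapse to the most informative extreme.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    design = random_design(prior.attribute_ids, n_subdesigns, n_sets, rng, overlap_range)
    coef = prior.coefficients
    p = coef.shape[0]
    subs = [sd.copy() for sd in design.sub_designs]
    # per-set overlap target, fixed at initialization
    targets = [
        [int((sd[t, 0] == sd[t, 1]).sum()) for t in range(n_sets)] for sd in subs
    ]

    diffs = np.array(
        [code_difference(sd[t]) for sd in subs for t in range(n_sets)]
    )
    info = _information(diffs, coef)

    def neg_logdet(m: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(m)
        return float("inf") if sign <= 0 else -logdet

    current = neg_logdet(info)
    for _ in range(max_passes):
        improved = False
        for s in range(n_subdesigns):
            for t in range(n_sets):
                row = s * n_sets + t
                for alt in range(2):
                    for j in range(design.n_attributes):
                        old_level = subs[s][t, alt, j]
                        best = None
                        for new_level in range(N_LEVELS):
                            if new_level == old_level:
                                continue
                            pair = subs[s][t].copy()
                            pair[alt, j] = new_level
                            ov = int((pair[0] == pair[1]).sum())
                            if ov != targets[s][t]:
                                continue
                            dx_new = code_difference(pair)
                            dx_old = diffs[row]
                            v_old = dx_old @ coef
                            v_new = dx_new @ coef
                            w_old = _logit_weight(v_old)
                            w_new = _logit_weight(v_new)
                            cand_info = (
                                info
                                - w_old * np.outer(dx_old, dx_old)
                                + w_new * np.outer(dx_new, dx_new)
                            )
                            cand = neg_logdet(cand_info)
                            if cand < current - 1e-12 and (best is None or cand < best[0]):
                                best = (cand, new_level, dx_new, cand_info)
                        if best is not None:
                            current, new_level, dx_new, info = best
                            subs[s][t, alt, j] = new_level
                            diffs[row] = dx_new
                            improved = True
        if not improved:
            break

    out = DCEDesign(
        design.attribute_ids,
        tuple(sd.copy() for sd in subs),
        design.blocks,
        overlap_range,
    )
    out.validate()
    return out


def _logit_weight(v: float) -> float:
    p = 1.0 / (1.0 + np.exp(-v))
    return p * (1.0 - p)


# ---------------------------------------------------------------------------
# Conditional-logit estimation

def _stack_choices(
    design: DCEDesign, data: Sequence[ChoiceRecord]
) -> tuple[np.ndarray, np.ndarray]:
    x = np.empty((len(data), 2 * design.n_attributes))
    y = np.empty(len(data))
    for i, rec in enumerate(data):
        pair = design.choice_set(rec.sub_design_id, rec.choice_set_id)
        x[i] = code_difference(pair)
        y[i] = 1.0 if rec.chosen == "A" else 0.0
    return x, y


def fit_conditional_logit(
    design: DCEDesign,
    data: Sequence[ChoiceRecord],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PartWorths:
    """Maximum-likelihood part-worths from paired-choice data.

    Damped Newton iterations with step-halving on the log-likelihood;
    convergence when the gradient max-norm falls below ``tol`` or the
    Newton step would change no coefficient by more than 1e-8 (at tens of
    thousands of choices the log-likelihood's floating-point granularity
    caps the attainable gradient norm, so a pure gradient criterion can
    stall short of any absolute tolerance).  The covariance is the inverse
    observed information at the optimum.
    """
    if not data:
        raise ValueError("no choice records")
    x, y = _stack_choices(design, data)
    p = x.shape[1]
    if len(data) < p:
        raise ValueError(
            f"only {len(data)} choices for {p} coefficients; need at least one "
            "response per estimable coefficient"
        )
    # a coefficient whose coded difference is identically zero is inestimable
    dead = np.where(np.abs(x).sum(axis=0) == 0)[0]
    if dead.size:
        names = sorted({design.attribute_ids[d // 2] for d in dead})
        raise SeparationError(
            f"attributes {names} are fully overlapped across all answered sets; "
            "their part-worths are not identifiable"
        )
    rank = np.linalg.matrix_rank(np.unique(x, axis=0))
    if rank < p:
        raise SeparationError(
            f"design matrix of the answered sets has rank {rank} < {p}; the "
            "design does not identify all part-worths (too few distinct "
            "choice sets)"
        )

    beta = np.zeros(p)

    def loglik(b: np.ndarray) -> float:
        v = x @ b
        # log P(choice): y*v - log(1+e^v), numerically stable via logaddexp
        return float(np.sum(y * v - np.logaddexp(0.0, v)))

    ll = loglik(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        v = x @ beta
        prob = 1.0 / (1.0 + np.exp(-v))
        grad = x.T @ (y - prob)
        if np.max(np.abs(grad)) < tol:
            break
        w = prob * (1.0 - prob)
        hess = (x * w[:, None]).T @ x  # observed information
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix is singular; data do not identify all "
                "part-worths"
            ) from exc
        if np.max(np.abs(step)) < 1e-8:
            break
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(60):
            cand = beta + scale * step
            ll_cand = loglik(cand)
            if ll_cand >= ll - 1e-13:
                beta, ll = cand, ll_cand
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {n_iter} "
                f"(log-likelihood {ll:.6f}, |grad|={np.max(np.abs(grad)):.3e})"
            )
        if np.max(np.abs(beta)) > 50:
            raise SeparationError(
                "coefficients diverging (|beta| > 50); the data are separated"
            )
    else:
        v = x @ beta
        prob = 1.0 / (1.0 + np.exp(-v))
        grad = x.T @ (y - prob)
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(|grad|={np.max(np.abs(grad)):.3e}, log-likelihood {ll:.6f})"
        )

    v = x @ beta
    prob = 1.0 / (1.0 + np.exp(-v))
    w = prob * (1.0 - prob)
    info = (x * w[:, None]).T @ x
    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    return PartWorths(
        design.attribute_ids,
        beta,
        covariance=cov,
        log_likelihood=ll,
        converged=True,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# Adaptive prior update

@dataclass(frozen=True)
class PriorUpdate:
    updated: bool
    part_worths: PartWorths
    design: DCEDesign
    n_respondents: int


def update_priors(
    design: DCEDesign,
    data: Sequence[ChoiceRecord],
    threshold: int = 50,
    seed: int = 0,
) -> PriorUpdate:
    """Refit part-worths on accumulated data and re-optimize the design.

    The design is re-optimized with the refit as point prior once at least
    ``threshold`` respondents have answered; below the threshold the input
    design is returned unchanged and flagged as not updated.
    """
    n_resp = len({rec.respondent_id for rec in data})
    if n_resp < threshold:
        return PriorUpdate(False, uniform_prior(design.attribute_ids), design, n_resp)
    refit = fit_conditional_logit(design, data)
    new_design = optimize_design(
        refit,
        n_subdesigns=design.n_sub_designs,
        n_sets=design.n_sets,
        seed=seed,
        overlap_range=design.overlap_range,
    )
    return PriorUpdate(True, refit, new_design, n_resp)


# ---------------------------------------------------------------------------
# Weights

def partworths_to_weights(beta: PartWorths, stakeholder_group: str = "pooled"):
    """Relative best-level part-worths as normalized criterion weights.

    w_j = beta_j,good / sum_j beta_j,good.  A negative good-level
    coefficient contradicts the monotone poor<average<good framing of the
    elicitation and is rejected.
    """
    from .scoring import WeightVector

    good = beta.good_level_coefficients()
    if (good < 0).any():
        bad = [beta.attribute_ids[j] for j in np.where(good < 0)[0]]
        raise ValueError(
            f"negative best-level part-worth for {bad}: a 'good' level valued "
            "below 'poor' violates the elicitation's monotone framing; review "
            "coefficient signs before deriving weights"
        )
    total = good.sum()
    if total <= 0:
        raise ValueError("all best-level part-worths are zero; weights undefined")
    w = good / total
    return WeightVector(
        dict(zip(beta.attribute_ids, w.tolist())),
        method="dce",
        stakeholder_group=stakeholder_group,
    )
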