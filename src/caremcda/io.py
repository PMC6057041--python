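"""Delimited-text file formats, run configuration, and the full pipeline.

All interchange formats are plain CSV with explicit headers and '.' decimal
separators; weight files carry provenance (elicitation method, stakeholder
group) as comment headers so DCE and swing weight sets — which are not
directly comparable — cannot be mixed silently.  Costs are plain numbers;
currency is metadata, never parsed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .criteria import (
    CriteriaSet,
    build_core_set,
    build_programme_set,
    PROGRAMME_TAGS,
    read_catalog,
)
from .dce import ChoiceRecord, DCEDesign, fit_conditional_logit, partworths_to_weights
from .scoring import (
    PerformanceTable,
    ValueResult,
    WeightVector,
    preferred_alternative,
    score_pipeline,
    standardize_table,
)
from .swing import SwingRanking, group_swing_weights
from .uncertainty import (
    PSAConfig,
    cmac,
    exclude_criterion_sa,
    run_psa,
    weight_method_swap_sa,
)

log = logging.getLogger("caremcda")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Performance tables

PERF_COLUMNS = ["criterion_id", "alt", "mean", "se"]


def read_performance_table(path, criteria: CriteriaSet | None = None) -> PerformanceTable:
    """Read a (criterion_id, alt, mean, se) file; row order is irrelevant."""
    df = pd.read_csv(path)
    missing = [c for c in PERF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    alts = list(dict.fromkeys(df["alt"]))
    if len(alts) != 2:
        raise ValueError(f"{path}: expected exactly 2 alternatives, found {alts}")
    cells = {}
    for i, row in df.iterrows():
        cid = str(row["criterion_id"])
        if criteria is not None:
            if cid not in criteria:
                raise ValueError(f"{path} row {i + 2}: unknown criterion {cid!r}")
            c = criteria.get(cid)
            if not (c.scale_min <= row["mean"] <= c.scale_max):
                raise ValueError(
                    f"{path} row {i + 2}: mean {row['mean']} outside scale "
                    f"[{c.scale_min}, {c.scale_max}] of {cid!r}"
                )
        cells[(str(row["alt"]), cid)] = (float(row["mean"]), float(row["se"]))
    table = PerformanceTable((alts[0], alts[1]), cells)
    if criteria is not None:
        table.validate_against(criteria)
    return table


def write_performance_table(table: PerformanceTable, path) -> None:
    rows = [
        {"criterion_id": cid, "alt": alt, "mean": m, "se": se}
        for (alt, cid), (m, se) in table.cells.items()
    ]
    pd.DataFrame(rows, columns=PERF_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Weight vectors (with provenance headers)

def write_weights(w: WeightVector, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# method: {w.method}\n")
        fh.write(f"# stakeholder_group: {w.stakeholder_group}\n")
        fh.write("criterion_id,weight\n")
        for cid, wt in w.weights.items():
            fh.write(f"{cid},{wt!r}\n")


def read_weights(path) -> WeightVector:
    method, group = "unspecified", "pooled"
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "method":
                method = val.strip()
            elif key.strip() == "stakeholder_group":
                group = val.strip()
        else:
            break
    df = pd.read_csv(path, skiprows=body_start)
    if not {"criterion_id", "weight"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns criterion_id, weight")
    return WeightVector(
        dict(zip(df["criterion_id"].astype(str), df["weight"].astype(float))),
        method=method,
        stakeholder_group=group,
    )


# ---------------------------------------------------------------------------
# Swing rankings

def write_rankings(rankings: Sequence[SwingRanking], path) -> None:
    rows = [
        {"respondent_id": r.respondent_id, "group": r.stakeholder_group,
         "rank": k + 1, "criterion_id": cid}
        for r in rankings
        for k, cid in enumerate(r.ranking)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rankings(path) -> list[SwingRanking]:
    df = pd.read_csv(path)
    need = {"respondent_id", "group", "rank", "criterion_id"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    out = []
    for (rid, grp), sub in df.groupby(["respondent_id", "group"], sort=False):
        sub = sub.sort_values("rank")
        out.append(SwingRanking(str(rid), str(grp), tuple(sub["criterion_id"].astype(str))))
    return out


# ---------------------------------------------------------------------------
# DCE choice records and designs

def write_choices(records: Sequence[ChoiceRecord], path) -> None:
    rows = [
        {"respondent_id": r.respondent_id, "group": r.stakeholder_group,
         "sub_design": r.sub_design_id, "choice_set": r.choice_set_id,
         "chosen": r.chosen}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_choices(path) -> list[ChoiceRecord]:
    df = pd.read_csv(path)
    need = {"respondent_id", "group", "sub_design", "choice_set", "chosen"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return [
        ChoiceRecord(str(r.respondent_id), str(r.group), int(r.sub_design),
                     int(r.choice_set), str(r.chosen))
        for r in df.itertuples()
    ]


def write_design(design: DCEDesign, path) -> None:
    rows = []
    for s, sd in enumerate(design.sub_designs):
        for t in range(sd.shape[0]):
            for a, alt in enumerate("AB"):
                for j, aid in enumerate(design.attribute_ids):
                    rows.append({"sub_design": s, "choice_set": t, "alternative": alt,
                                 "attribute": aid, "level": int(sd[t, a, j])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design(design_path, overlap_range=(4, 5)) -> DCEDesign:
    df = pd.read_csv(design_path)
    attrs = tuple(dict.fromkeys(df["attribute"].astype(str)))
    n_sub = int(df["sub_design"].max()) + 1
    n_sets = int(df["choice_set"].max()) + 1
    subs = []
    aidx = {a: j for j, a in enumerate(attrs)}
    for s in range(n_sub):
        arr = np.zeros((n_sets, 2, len(attrs)), dtype=int)
        sub = df[df["sub_design"] == s]
        for r in sub.itertuples():
            arr[int(r.choice_set), 0 if r.alternative == "A" else 1, aidx[str(r.attribute)]] = int(r.level)
        subs.append(arr)
    from .dce import _default_blocks

    design = DCEDesign(attrs, tuple(subs), _default_blocks(n_sets), overlap_range)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Run configuration and pipeline

@dataclass
class RunConfig:
    """Everything a full pipeline run needs, loadable from YAML."""

    performance_path: str
    weights_paths: list[str]
    criteria_set: str = "core"
    cost_worst: float = 8500.0
    cost_best: float = 5500.0
    catalog_path: str | None = None
    swing_rankings_path: str | None = None
    dce_design_path: str | None = None
    dce_choices_path: str | None = None
    sa_exclude: list[str] = field(default_factory=list)
    psa_draws: int = 1000
    psa_seed: int = 1
    population_size: int = 1000
    budget_grid: list[float] = field(default_factory=list)
    budget_impact: str = "total"
    include_cost_in_value: bool = True
    output_dir: str = "results"
    standardized_decimals: int = 2
    value_decimals: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def criteria(self) -> CriteriaSet:
        if self.catalog_path:
            return read_catalog(self.catalog_path)
        if self.criteria_set == "core":
            return build_core_set(self.cost_worst, self.cost_best)
        if self.criteria_set in PROGRAMME_TAGS:
            return build_programme_set(self.criteria_set, self.cost_worst, self.cost_best)
        raise ValueError(
            f"unknown criteria_set {self.criteria_set!r}; valid: "
            f"{['core', *PROGRAMME_TAGS]}"
        )


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def format_summary(
    cs: CriteriaSet,
    perf: PerformanceTable,
    results: dict[str, ValueResult],
    std_dp: int = 2,
    val_dp: int = 3,
) -> str:
    """Human-readable summary mirroring the worked-example table layout."""
    std = standardize_table(perf, cs)
    a, b = perf.alternatives
    lines = []
    header = (
        f"{'criterion':<28}{'perf ' + a:>22}{'perf ' + b:>18}"
        f"{'std ' + a:>22}{'std ' + b:>18}"
    )
    lines.append(header)
    for c in cs:
        lines.append(
            f"{c.id:<28}{perf.mean(a, c.id):>22g}{perf.mean(b, c.id):>18g}"
            f"{std.score(a, c.id):>22.{std_dp}f}{std.score(b, c.id):>18.{std_dp}f}"
        )
    lines.append("")
    for name, res in results.items():
        lines.append(
            f"overall value [{name}]: {a}={res.value(a):.{val_dp}f}  "
            f"{b}={res.value(b):.{val_dp}f}  preferred={preferred_alternative(res)}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute score -> weights -> comparison -> SA -> PSA -> CMAC.

    Writes a machine-readable bundle (CSV/JSON) plus a human-readable
    summary into ``cfg.output_dir`` and returns the bundle as a dict.  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {"seeds": {"psa": cfg.psa_seed}, "inputs": {}, "stages": []}

    def stage(name):
        log.info("pipeline stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("criteria")
        cs = cfg.criteria()
    except Exception as exc:
        raise PipelineError(f"criteria stage failed: {exc}") from exc

    try:
        stage("performance")
        perf = read_performance_table(cfg.performance_path, cs)
        manifest["inputs"]["performance"] = _digest(cfg.performance_path)
    except Exception as exc:
        raise PipelineError(f"performance stage failed: {exc}") from exc

    try:
        stage("weights")
        weight_vectors: dict[str, WeightVector] = {}
        for p in cfg.weights_paths:
            w = read_weights(p)
            weight_vectors[f"{w.method}:{w.stakeholder_group}"] = w
            manifest["inputs"][str(p)] = _digest(p)
        swing_rankings = None
        if cfg.swing_rankings_path:
            swing_rankings = read_rankings(cfg.swing_rankings_path)
            manifest["inputs"]["swing_rankings"] = _digest(cfg.swing_rankings_path)
            for g, w in group_swing_weights(swing_rankings, cs.ids).items():
                weight_vectors[f"swing:{g}"] = w
        beta = None
        if cfg.dce_choices_path and cfg.dce_design_path:
            design = read_design(cfg.dce_design_path)
            choices = read_choices(cfg.dce_choices_path)
            manifest["inputs"]["dce_choices"] = _digest(cfg.dce_choices_path)
            beta = fit_conditional_logit(design, choices)
            weight_vectors["dce:fitted"] = partworths_to_weights(beta)
        if not weight_vectors:
            raise ValueError("no weight vectors available")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"weights stage failed: {exc}") from exc

    try:
        stage("value_scores")
        results = {name: score_pipeline(perf, cs, w) for name, w in weight_vectors.items()}
        rows = []
        for name, res in results.items():
            for alt in perf.alternatives:
                rows.append({"weights": name, "alt": alt, "value": res.value(alt)})
        pd.DataFrame(rows).to_csv(out / "values.csv", index=False)
        (out / "summary.txt").write_text(
            format_summary(cs, perf, results, cfg.standardized_decimals, cfg.value_decimals)
        )
        bundle["values"] = {
            name: {alt: res.value(alt) for alt in perf.alternatives}
            for name, res in results.items()
        }
        bundle["preferred"] = {
            name: preferred_alternative(res) for name, res in results.items()
        }
    except Exception as exc:
        raise PipelineError(f"value_scores stage failed: {exc}") from exc

    try:
        stage("deterministic_sa")
        first = next(iter(weight_vectors.values()))
        sa_rows = []
        for cid in cfg.sa_exclude:
            for name, w in weight_vectors.items():
                res = exclude_criterion_sa(perf, cs, w, cid)
                sa_rows.append(
                    {
                        "weights": name,
                        "excluded": cid,
                        "value_intervention": res.without_criterion.value(perf.intervention),
                        "value_comparator": res.without_criterion.value(perf.comparator),
                        "preference_flipped": res.preference_flipped,
                    }
                )
        if sa_rows:
            pd.DataFrame(sa_rows).to_csv(out / "sa_exclusion.csv", index=False)
            bundle["sa_exclusion"] = sa_rows
        dce_vs, swing_vs = (
            [w for n, w in weight_vectors.items() if n.startswith("dce")],
            [w for n, w in weight_vectors.items() if n.startswith("swing")],
        )
        if dce_vs and swing_vs:
            comp = weight_method_swap_sa(perf, cs, dce_vs[0], swing_vs[0])
            bundle["method_swap"] = {
                "preferred_dce": comp.preferred_dce,
                "preferred_swing": comp.preferred_swing,
                "agreement": comp.agreement,
            }
    except Exception as exc:
        raise PipelineError(f"deterministic_sa stage failed: {exc}") from exc

    try:
        if cfg.budget_grid:
            stage("psa")
            psa_cfg = PSAConfig(
                n_draws=cfg.psa_draws,
                seed=cfg.psa_seed,
                population_size=cfg.population_size,
                budget_grid=tuple(cfg.budget_grid),
                budget_impact=cfg.budget_impact,
                include_cost_in_value=cfg.include_cost_in_value,
            )
            if beta is not None and beta.covariance is not None:
                draws = run_psa(perf, cs, psa_cfg, beta=beta)
            elif swing_rankings:
                draws = run_psa(perf, cs, psa_cfg, swing_rankings=swing_rankings)
            else:
                draws = None
            if draws is not None:
                draws.to_csv(out / "psa_draws.csv", index=False)
                stage("cmac")
                curve = cmac(draws, psa_cfg)
                curve.as_frame().to_csv(out / "cmac.csv", index=False)
                bundle["cmac"] = {
                    "thresholds": list(curve.thresholds),
                    "probability": list(curve.probability),
                    "unconditional_probability": curve.unconditional_probability,
                }
    except Exception as exc:
        raise PipelineError(f"psa stage failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "results.json").write_text(json.dumps(bundle, indent=2))
    return bundle
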