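"""End-to-end pipeline orchestration and result reporting.

``run_pipeline`` takes an extraction table through ingestion, effect-size
computation, classification, overall and subgroup pooling, per-species
labelling and the physiological regressions, and writes a results bundle:
TSV tables, full-precision JSON, a human-readable summary (percentages to 1
decimal, lnRR to 4 decimals) and a run manifest whose observation counts
reconcile (parsed = analyzed + rejected, and per grouping
analyzed = pooled + excluded).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .association import RegressionResult, regression_table
from .effects import (
    EffectCategory,
    EffectSize,
    Z95,
    classify_effect,
    compute_effects,
    effects_to_frame,
    percent_change,
)
from .ingest import IngestConfig, ParseResult, parse_observations
from .meta import (
    Grouping,
    PooledEffect,
    SubgroupTable,
    pool,
    subgroup_pool,
)
from .records import VariableKind

logger = logging.getLogger(__name__)

DEFAULT_SUBGROUPS: tuple[str, ...] = tuple(
    g.value for g in Grouping if g is not Grouping.PHYSIOLOGICAL_VARIABLE
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: Union[str, Path]
    out_dir: Optional[Union[str, Path]] = None
    ingest_config: Optional[IngestConfig] = None
    tau2_method: str = "REML"
    transform: str = "ratio"
    #: "auto" applies the I^2 > 50% rule; "random"/"fixed" force a model
    model_mode: str = "auto"
    subgroups: Sequence[str] = field(default_factory=lambda: list(DEFAULT_SUBGROUPS))
    regression: bool = True
    pairing_rule: str = "per_observation"
    min_k: int = 2
    ci95_rule: str = "mean_over_10"
    variance_floor: float = 1e-10
    log_level: str = "INFO"

    def model_arg(self) -> str:
        mode = self.model_mode.lower()
        if mode == "auto":
            return "auto"
        if mode in ("random", "fixed"):
            return mode.upper()
        raise ValueError(f"unknown model mode {self.model_mode!r}")

    def to_jsonable(self) -> dict:
        d = {
            "input_path": str(self.input_path),
            "tau2_method": self.tau2_method,
            "transform": self.transform,
            "model_mode": self.model_mode,
            "subgroups": list(self.subgroups),
            "regression": self.regression,
            "pairing_rule": self.pairing_rule,
            "min_k": self.min_k,
            "ci95_rule": self.ci95_rule,
            "variance_floor": self.variance_floor,
        }
        return d


@dataclass
class ResultsBundle:
    effects_frame: pd.DataFrame
    rejections_frame: pd.DataFrame
    overall: PooledEffect
    subgroups: dict[str, SubgroupTable]
    physiological: Optional[SubgroupTable]
    classification: dict
    species_frame: pd.DataFrame
    regressions: list[RegressionResult]
    regression_dropped: dict[str, int]
    manifest: dict


def classification_summary(
    effects: Sequence[EffectSize], z: float = Z95
) -> dict:
    """Fractions of positive/neutral/negative effects and the lnRR range."""
    if not effects:
        raise ValueError("at least one effect required")
    counts = {c: 0 for c in EffectCategory}
    lnrrs = []
    for e in effects:
        counts[classify_effect(e, z=z).category] += 1
        lnrrs.append(e.lnrr)
    n = len(effects)
    return {
        "n": n,
        "counts": {c.value: counts[c] for c in EffectCategory},
        "fractions": {c.value: counts[c] / n for c in EffectCategory},
        "lnrr_min": float(min(lnrrs)),
        "lnrr_max": float(max(lnrrs)),
    }


def species_labels(
    effects: Sequence[EffectSize],
    model: str = "auto",
    tau2_method: str = "REML",
    transform: str = "ratio",
) -> pd.DataFrame:
    """Per-species beneficial/ineffective labels from pooled CIs.

    A species is 'Beneficial' when its pooled CI lies entirely above zero
    and 'Ineffective' otherwise. Because a species spanning several source
    studies can be beneficial in one and not another, per-study labels are
    reported alongside the pooled verdict rather than forced into one.
    """
    by_species: dict[str, list[EffectSize]] = {}
    for e in effects:
        if e.record is None:
            continue
        by_species.setdefault(e.record.plant_species, []).append(e)
    rows = []
    for species in sorted(by_species):
        members = by_species[species]
        pooled = pool(
            members, model=model, tau2_method=tau2_method,
            label=species, transform=transform,
        )
        by_study: dict[str, list[EffectSize]] = {}
        for e in members:
            by_study.setdefault(e.record.study_id, []).append(e)
        study_labels = []
        for sid in sorted(by_study):
            sp = pool(
                by_study[sid], model=model, tau2_method=tau2_method,
                label=sid, transform=transform,
            )
            study_labels.append(
                f"{sid}:{'Beneficial' if sp.ci_low > 0 else 'Ineffective'}"
            )
        rows.append(
            {
                "plant_species": species,
                "k": pooled.k,
                "n_studies": len(by_study),
                "estimate_lnrr": pooled.estimate_lnrr,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "percent": pooled.percent,
                "label": "Beneficial" if pooled.ci_low > 0 else "Ineffective",
                "per_study_labels": "; ".join(study_labels),
            }
        )
    return pd.DataFrame(rows)


def _pooled_row(p: PooledEffect, grouping: str) -> dict:
    het = p.het
    return {
        "grouping": grouping,
        "label": p.label,
        "k": p.k,
        "model": p.model.value,
        "estimate_lnrr": p.estimate_lnrr,
        "se": p.se,
        "ci_low": p.ci_low,
        "ci_high": p.ci_high,
        "percent_ratio": percent_change(p.estimate_lnrr, "ratio"),
        "percent_log_points": percent_change(p.estimate_lnrr, "log_points"),
        "significant": p.significant,
        "unpooled": p.unpooled,
        "low_k": p.low_k,
        "Q": het.Q if het else np.nan,
        "df": het.df if het else np.nan,
        "p_value": het.p_value if het else np.nan,
        "I2": het.I2 if het else np.nan,
        "tau2": het.tau2 if het else np.nan,
    }


def pooled_table(
    overall: PooledEffect,
    subgroups: dict[str, SubgroupTable],
    physiological: Optional[SubgroupTable],
) -> pd.DataFrame:
    rows = [_pooled_row(overall, "OVERALL")]
    for name, table in subgroups.items():
        rows.extend(_pooled_row(p, name) for p in table.groups)
    if physiological is not None:
        rows.extend(
            _pooled_row(p, Grouping.PHYSIOLOGICAL_VARIABLE.value)
            for p in physiological.groups
        )
    return pd.DataFrame(rows)


def _config_hash(cfg: RunConfig) -> str:
    # hash the analytic settings only, not where the input file happens to live
    settings = {k: v for k, v in cfg.to_jsonable().items() if k != "input_path"}
    blob = json.dumps(settings, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: RunConfig) -> ResultsBundle:
    """Run the full analysis and (optionally) write the results bundle.

    Deterministic given the input file and configuration; the manifest
    carries a hash of the configuration, all observation counts, and every
    warning emitted during ingestion.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    for name in cfg.subgroups:
        Grouping(name)  # fail fast on unknown subgroup names

    parsed: ParseResult = parse_observations(cfg.input_path, cfg.ingest_config)
    ingredient_records = [
        r for r in parsed.records if r.variable_kind is VariableKind.INGREDIENT
    ]
    physio_records = [
        r for r in parsed.records if r.variable_kind is not VariableKind.INGREDIENT
    ]
    if not ingredient_records:
        raise ValueError("no valid ingredient observations in input")

    ingredient_effects = compute_effects(
        ingredient_records, variance_floor=cfg.variance_floor, ci95_rule=cfg.ci95_rule
    )
    physio_effects = compute_effects(
        physio_records, variance_floor=cfg.variance_floor, ci95_rule=cfg.ci95_rule
    )

    model = cfg.model_arg()
    overall = pool(
        ingredient_effects,
        model=model,
        tau2_method=cfg.tau2_method,
        label="overall",
        transform=cfg.transform,
    )
    subgroups: dict[str, SubgroupTable] = {}
    for name in cfg.subgroups:
        grouping = Grouping(name)
        if grouping is Grouping.PHYSIOLOGICAL_VARIABLE:
            continue
        subgroups[name] = subgroup_pool(
            ingredient_effects,
            grouping,
            model=model,
            tau2_method=cfg.tau2_method,
            min_k=cfg.min_k,
            transform=cfg.transform,
        )
    physiological = (
        subgroup_pool(
            physio_effects,
            Grouping.PHYSIOLOGICAL_VARIABLE,
            model=model,
            tau2_method=cfg.tau2_method,
            min_k=cfg.min_k,
            transform=cfg.transform,
        )
        if physio_effects
        else None
    )

    classification = classification_summary(ingredient_effects)
    species = species_labels(
        ingredient_effects, model=model, tau2_method=cfg.tau2_method,
        transform=cfg.transform,
    )
    regressions: list[RegressionResult] = []
    dropped: dict[str, int] = {}
    if cfg.regression and physio_effects:
        regressions, dropped = regression_table(
            ingredient_effects, physio_effects, rule=cfg.pairing_rule
        )

    manifest = {
        "config": cfg.to_jsonable(),
        "config_hash": _config_hash(cfg),
        "counts": {
            "data_rows": parsed.n_rows,
            "records": len(parsed.records),
            "rejections": len(parsed.rejections),
            "ingredient_effects": len(ingredient_effects),
            "physiological_effects": len(physio_effects),
            "excluded_by_grouping": {
                name: table.n_excluded for name, table in subgroups.items()
            },
            "regression_dropped": dropped,
        },
        "warnings": list(parsed.warnings),
        "empty_subgroup_notes": [
            f"{name}: no groups formed"
            for name, table in subgroups.items()
            if not table.groups
        ],
    }

    bundle = ResultsBundle(
        effects_frame=effects_to_frame(ingredient_effects + physio_effects),
        rejections_frame=parsed.rejections_frame(),
        overall=overall,
        subgroups=subgroups,
        physiological=physiological,
        classification=classification,
        species_frame=species,
        regressions=regressions,
        regression_dropped=dropped,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        write_bundle(bundle, cfg.out_dir)
    return bundle


def _regression_frame(regs: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": r.factor.value,
                "slope": r.slope,
                "intercept": r.intercept,
                "r2": r.r2,
                "p_value": r.p_value,
                "n_pairs": r.n_pairs,
            }
            for r in regs
        ],
        columns=["factor", "slope", "intercept", "r2", "p_value", "n_pairs"],
    )


def write_bundle(bundle: ResultsBundle, out_dir: Union[str, Path]) -> None:
    """Write TSV tables, full-precision JSON, and the textual summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle.effects_frame.to_csv(out / "effects.tsv", sep="\t", index=False)
    bundle.rejections_frame.to_csv(out / "rejections.tsv", sep="\t", index=False)
    pooled = pooled_table(bundle.overall, bundle.subgroups, bundle.physiological)
    pooled.to_csv(out / "pooled.tsv", sep="\t", index=False)
    (out / "pooled.json").write_text(
        json.dumps(pooled.to_dict(orient="records"), indent=2), encoding="utf-8"
    )
    (out / "classification.json").write_text(
        json.dumps(bundle.classification, indent=2), encoding="utf-8"
    )
    bundle.species_frame.to_csv(out / "species_labels.tsv", sep="\t", index=False)
    reg = _regression_frame(bundle.regressions)
    reg.to_csv(out / "regression.tsv", sep="\t", index=False)
    (out / "regression.json").write_text(
        json.dumps(reg.to_dict(orient="records"), indent=2), encoding="utf-8"
    )
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "report.txt").write_text(render_report(bundle), encoding="utf-8")


def render_report(bundle: ResultsBundle) -> str:
    """Human-readable summary; every displayed number is also in the JSON."""
    lines = []
    o = bundle.overall
    cls = bundle.classification
    lines.append("Mycorrhizal inoculation effects on medicinal active ingredients")
    lines.append("=" * 63)
    lines.append(
        f"Ingredient observations: {cls['n']}  "
        f"(lnRR range {cls['lnrr_min']:.4f} to {cls['lnrr_max']:.4f})"
    )
    fr = cls["fractions"]
    lines.append(
        "Per-observation classification: "
        f"positive {100 * fr['POSITIVE']:.1f}%, "
        f"neutral {100 * fr['NEUTRAL']:.1f}%, "
        f"negative {100 * fr['NEGATIVE']:.1f}%"
    )
    lines.append(
        f"Overall pooled effect ({o.model.value}, k={o.k}): "
        f"lnRR {o.estimate_lnrr:.4f} "
        f"[{o.ci_low:.4f}, {o.ci_high:.4f}] = {o.percent:.1f}% change"
        f"{' *' if o.significant else ''}"
    )
    if o.het is not None:
        lines.append(
            f"Heterogeneity: Q={o.het.Q:.2f} (df={o.het.df}, p={o.het.p_value:.3g}), "
            f"I2={o.het.I2:.1f}%, tau2={o.het.tau2:.4f}"
        )
    for name, table in bundle.subgroups.items():
        lines.append("")
        lines.append(f"Subgroup: {name} (excluded {table.n_excluded})")
        for p in table.groups:
            flags = "".join(
                [" *" if p.significant else "", " [k=1]" if p.unpooled else "",
                 " [low-k]" if p.low_k and not p.unpooled else ""]
            )
            lines.append(
                f"  {p.label}: k={p.k}, lnRR {p.estimate_lnrr:.4f} "
                f"[{p.ci_low:.4f}, {p.ci_high:.4f}] = {p.percent:.1f}%{flags}"
            )
    if bundle.physiological is not None:
        lines.append("")
        lines.append("Physiological factors:")
        for p in bundle.physiological.groups:
            lines.append(
                f"  {p.label}: k={p.k}, lnRR {p.estimate_lnrr:.4f} "
                f"= {p.percent:.1f}%{' *' if p.significant else ''}"
            )
    if bundle.regressions:
        lines.append("")
        lines.append("Ingredient ~ physiological-factor regressions (lnRR scale):")
        for r in bundle.regressions:
            lines.append(
                f"  {r.factor.value}: slope {r.slope:.4f}, r2 {r.r2:.4f}, "
                f"p {r.p_value:.3g}, n {r.n_pairs}"
            )
    lines.append("")
    lines.append("* pooled 95% CI excludes zero")
    return "\n".join(lines) + "\n"
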