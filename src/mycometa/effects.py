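"""Per-observation effect sizes: the log response ratio and its variance.

The effect metric is the natural log response ratio

    lnRR = ln(mean_T / mean_C),

with sampling variance propagated from the within-arm dispersions,

    v = SD_T^2 / (n_T * mean_T^2) + SD_C^2 / (n_C * mean_C^2).

Each observation is classified positive / neutral / negative from whether
its 95% confidence interval excludes zero.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ingest import harmonize_record
from .records import ArmSummary, DispersionKind, ObservationRecord

#: two-sided 95% normal critical value
Z95 = 1.959963984540054

#: default replacement for an exactly-zero sampling variance
VARIANCE_FLOOR = 1e-10


class EffectCategory(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEUTRAL = "NEUTRAL"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class EffectClass:
    category: EffectCategory
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class EffectSize:
    """lnRR and its sampling variance, with the source record carried along."""

    obs_id: str
    lnrr: float
    variance: float
    record: Optional[ObservationRecord] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.lnrr):
            raise ValueError("lnRR must be finite")
        if self.variance <= 0:
            raise ValueError("variance must be positive (apply the floor first)")


class UndefinedEffectError(ValueError):
    """lnRR is undefined (non-positive mean in an arm)."""


def log_response_ratio(treatment: ArmSummary, control: ArmSummary) -> float:
    """ln(mean_T) - ln(mean_C); antisymmetric under swapping the arms."""
    if treatment.mean <= 0 or control.mean <= 0:
        raise UndefinedEffectError("both arm means must be positive")
    return math.log(treatment.mean) - math.log(control.mean)


def lnrr_variance(treatment: ArmSummary, control: ArmSummary) -> float:
    """Sampling variance of lnRR from harmonized (SD) arm dispersions."""
    for arm, name in ((treatment, "treatment"), (control, "control")):
        if arm.dispersion_kind is not DispersionKind.SD:
            raise ValueError(f"{name} arm dispersion must be SD; harmonize first")
        if arm.mean <= 0:
            raise UndefinedEffectError("both arm means must be positive")
    vt = treatment.dispersion_value**2 / (treatment.n * treatment.mean**2)
    vc = control.dispersion_value**2 / (control.n * control.mean**2)
    return vt + vc


def percent_change(lnrr: float, transform: str = "ratio") -> float:
    """Back-transform an lnRR to a percent change.

    ``"ratio"`` (default): (e^lnRR - 1) * 100, the relative change of the
    treatment mean over the control mean. ``"log_points"``: lnRR * 100.
    Both are strictly increasing and map 0 to 0.
    """
    if transform == "ratio":
        return (math.exp(lnrr) - 1.0) * 100.0
    if transform == "log_points":
        return lnrr * 100.0
    raise ValueError(f"unknown percent transform {transform!r}")


def classify_effect(effect: EffectSize, z: float = Z95) -> EffectClass:
    """Classify one effect from whether its z-interval excludes zero."""
    half = z * math.sqrt(effect.variance)
    lo, hi = effect.lnrr - half, effect.lnrr + half
    if lo > 0:
        cat = EffectCategory.POSITIVE
    elif hi < 0:
        cat = EffectCategory.NEGATIVE
    else:
        cat = EffectCategory.NEUTRAL
    return EffectClass(category=cat, ci_low=lo, ci_high=hi)


def compute_effect(
    record: ObservationRecord,
    variance_floor: float = VARIANCE_FLOOR,
    ci95_rule: str = "mean_over_10",
) -> EffectSize:
    """Harmonize a record's dispersions and compute its effect size.

    A degenerate zero sampling variance (both SDs zero) is replaced by
    ``variance_floor`` so inverse-variance weights stay finite.
    """
    rec = harmonize_record(record, ci95_rule=ci95_rule)
    y = log_response_ratio(rec.treatment, rec.control)
    v = lnrr_variance(rec.treatment, rec.control)
    if v <= 0:
        v = variance_floor
    return EffectSize(obs_id=rec.obs_id, lnrr=y, variance=v, record=rec)


def compute_effects(
    records: Iterable[ObservationRecord],
    variance_floor: float = VARIANCE_FLOOR,
    ci95_rule: str = "mean_over_10",
) -> list[EffectSize]:
    return [
        compute_effect(r, variance_floor=variance_floor, ci95_rule=ci95_rule)
        for r in records
    ]


def effects_to_frame(effects: Sequence[EffectSize], z: float = Z95) -> pd.DataFrame:
    """Tabulate effects with their classification and grouping columns."""
    rows = []
    for e in effects:
        cls = classify_effect(e, z=z)
        r = e.record
        rows.append(
            {
                "obs_id": e.obs_id,
                "lnrr": e.lnrr,
                "variance": e.variance,
                "ci_low": cls.ci_low,
                "ci_high": cls.ci_high,
                "category": cls.category.value,
                "percent_ratio": percent_change(e.lnrr, "ratio"),
                "percent_log_points": percent_change(e.lnrr, "log_points"),
                "study_id": r.study_id if r else "",
                "plant_species": r.plant_species if r else "",
                "variable_kind": r.variable_kind.value if r else "",
                "compound_class": (
                    r.compound_class.value if r and r.compound_class else ""
                ),
                "organ": r.organ.value if r and r.organ else "",
                "inoculum_mode": r.inoculum_mode.value if r else "",
                "amf_order": (r.amf_order or "") if r else "",
                "amf_family": (r.amf_family or "") if r else "",
                "amf_genus": (r.amf_genus or "") if r else "",
            }
        )
    return pd.DataFrame(rows)
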