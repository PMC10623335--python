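"""Regression of ingredient effect sizes on physiological-factor effects.

Ingredient and physiological lnRR values are paired within a study: each
ingredient effect is matched to the study's effect for a given factor
(averaged when the study reports the factor more than once). An ordinary
least-squares line of ingredient lnRR on factor lnRR summarizes whether
studies where the inoculum improved the factor are also studies where it
raised ingredient content. Regression is done on the lnRR scale, not on the
percent transform, which is monotone but nonlinear.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectSize
from .records import VariableKind

logger = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """The regressor has zero variance; the slope is undefined."""


@dataclass(frozen=True)
class PairedEffect:
    study_id: str
    factor: VariableKind
    x: float  # physiological-factor lnRR
    y: float  # ingredient lnRR


@dataclass(frozen=True)
class RegressionResult:
    factor: VariableKind
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_pairs: int


def pair_effects(
    ingredient_effects: Sequence[EffectSize],
    physiological_effects: Sequence[EffectSize],
    factor: VariableKind,
    rule: str = "per_observation",
) -> tuple[list[PairedEffect], int]:
    """Match ingredient effects with same-study effects of one factor.

    ``rule="per_observation"`` (default) pairs every ingredient effect in a
    study with the study's factor effect, so a study with three ingredient
    effects contributes three pairs. ``rule="study_mean"`` collapses each
    study to the mean of its ingredient lnRRs, one pair per study. Returns
    the pairs and the number of ingredient effects dropped for lack of a
    same-study factor measurement.
    """
    if factor is VariableKind.INGREDIENT:
        raise ValueError("factor must be a physiological variable")
    by_study: dict[str, list[float]] = {}
    for e in physiological_effects:
        r = e.record
        if r is not None and r.variable_kind is factor:
            by_study.setdefault(r.study_id, []).append(e.lnrr)
    factor_mean = {sid: float(np.mean(vals)) for sid, vals in by_study.items()}

    pairs: list[PairedEffect] = []
    n_dropped = 0
    if rule == "per_observation":
        for e in ingredient_effects:
            sid = e.record.study_id if e.record else None
            if sid in factor_mean:
                pairs.append(
                    PairedEffect(study_id=sid, factor=factor, x=factor_mean[sid], y=e.lnrr)
                )
            else:
                n_dropped += 1
    elif rule == "study_mean":
        ing_by_study: dict[str, list[float]] = {}
        for e in ingredient_effects:
            sid = e.record.study_id if e.record else None
            if sid is None:
                n_dropped += 1
                continue
            ing_by_study.setdefault(sid, []).append(e.lnrr)
        for sid, vals in ing_by_study.items():
            if sid in factor_mean:
                pairs.append(
                    PairedEffect(
                        study_id=sid,
                        factor=factor,
                        x=factor_mean[sid],
                        y=float(np.mean(vals)),
                    )
                )
            else:
                n_dropped += len(vals)
    else:
        raise ValueError(f"unknown pairing rule {rule!r}")

    if not pairs:
        logger.warning("no pairs formed for factor %s; regression skipped", factor.value)
    return pairs, n_dropped


def linear_fit(pairs: Sequence[PairedEffect]) -> RegressionResult:
    """OLS of ingredient lnRR on factor lnRR, with r^2 and two-sided p.

    Requires at least 3 pairs and non-degenerate x; r^2 is the squared
    Pearson correlation of the paired values.
    """
    if len(pairs) < 3:
        raise ValueError("linear fit requires at least 3 pairs")
    x = np.asarray([p.x for p in pairs], dtype=float)
    y = np.asarray([p.y for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("regressor has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        factor=pairs[0].factor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_pairs=len(pairs),
    )


def regression_table(
    ingredient_effects: Sequence[EffectSize],
    physiological_effects: Sequence[EffectSize],
    rule: str = "per_observation",
) -> tuple[list[RegressionResult], dict[str, int]]:
    """Fit one regression per physiological factor present in the data.

    Factors with fewer than 3 pairs are skipped. Returns the fits and a map
    factor -> dropped-ingredient-effect count.
    """
    results: list[RegressionResult] = []
    dropped: dict[str, int] = {}
    factors = sorted(
        {
            e.record.variable_kind
            for e in physiological_effects
            if e.record is not None and e.record.variable_kind is not VariableKind.INGREDIENT
        },
        key=lambda f: f.value,
    )
    for factor in factors:
        pairs, n_dropped = pair_effects(
            ingredient_effects, physiological_effects, factor, rule=rule
        )
        dropped[factor.value] = n_dropped
        if len(pairs) >= 3:
            try:
                results.append(linear_fit(pairs))
            except DegenerateFitError:
                logger.warning("degenerate fit for factor %s skipped", factor.value)
    return results, dropped
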