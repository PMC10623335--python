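"""Inverse-variance pooling, heterogeneity statistics and subgroup analyses.

Fixed-effects pooling weights each observation by ``1/v_i``; random-effects
pooling by ``1/(v_i + tau^2)`` where the between-observation variance tau^2
is estimated by DerSimonian-Laird (closed form) or REML (iterative).
Heterogeneity is quantified by Cochran's Q (chi-square under homogeneity)
and I^2 = max(0, (Q - df)/Q) * 100. Model selection follows the I^2 > 50%
rule: random effects above the threshold, fixed effects at or below it.
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .effects import EffectSize, Z95, percent_change
from .records import InoculumMode, VariableKind

logger = logging.getLogger(__name__)

ArrayLike = Union[Sequence[float], np.ndarray]


class Model(str, enum.Enum):
    FIXED = "FIXED"
    RANDOM = "RANDOM"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value, I^2 (%) and tau^2."""

    Q: float
    df: int
    p_value: float
    I2: float
    tau2: float


@dataclass(frozen=True)
class PooledEffect:
    """A pooled lnRR with its Wald 95% CI and attached heterogeneity.

    ``unpooled`` marks single-observation groups reported with the
    observation's own CI; ``low_k`` marks groups below the configured
    minimum size, which are reported but should be read with caution.
    """

    label: str
    k: int
    model: Model
    estimate_lnrr: float
    se: float
    ci_low: float
    ci_high: float
    percent: float
    significant: bool
    het: Optional[HeterogeneityResult] = None
    unpooled: bool = False
    low_k: bool = False


def _as_arrays(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray([e.lnrr for e in effects], dtype=float)
    v = np.asarray([e.variance for e in effects], dtype=float)
    return y, v


def _validate_yv(y: ArrayLike, v: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("y and v must be 1-d arrays of equal length")
    if y.size == 0:
        raise ValueError("empty input")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    return y, v


def tau2_dl(y: ArrayLike, v: ArrayLike) -> float:
    """DerSimonian-Laird moment estimator of the between-effect variance.

    tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w) and
    fixed-effect weights w = 1/v.
    """
    y, v = _validate_yv(y, v)
    if y.size < 2:
        raise ValueError("tau^2 requires at least 2 effects")
    w = 1.0 / v
    sw = w.sum()
    mu = float(np.sum(w * y) / sw)
    q = float(np.sum(w * (y - mu) ** 2))
    c = sw - float(np.sum(w**2)) / sw
    if c <= 0:
        return 0.0
    return max(0.0, (q - (y.size - 1)) / c)


def tau2_reml(
    y: ArrayLike,
    v: ArrayLike,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> float:
    """REML estimate of tau^2 by fixed-point iteration.

    Iterates the restricted-likelihood estimating equation

        tau^2 <- sum(w^2 [(y - mu)^2 - v]) / sum(w^2) + 1 / sum(w),

    with w = 1/(v + tau^2) and mu the current weighted mean, truncating at
    zero, until successive values differ by less than ``tol``. On
    non-convergence after ``max_iter`` iterations, falls back to the
    DerSimonian-Laird estimate with a warning.
    """
    y, v = _validate_yv(y, v)
    if y.size < 2:
        raise ValueError("tau^2 requires at least 2 effects")
    tau2 = tau2_dl(y, v)  # moment start
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * y) / w.sum())
        num = float(np.sum(w**2 * ((y - mu) ** 2 - v)))
        new = num / float(np.sum(w**2)) + 1.0 / float(w.sum())
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    logger.warning("REML did not converge in %d iterations; using DL", max_iter)
    return tau2_dl(y, v)


_TAU2_METHODS: dict[str, Callable[..., float]] = {"DL": tau2_dl, "REML": tau2_reml}


def estimate_tau2(
    effects: Sequence[EffectSize], method: str = "REML"
) -> float:
    """Between-observation variance of a set of effects ('DL' or 'REML')."""
    y, v = _as_arrays(effects)
    return estimate_tau2_values(y, v, method=method)


def estimate_tau2_values(y: ArrayLike, v: ArrayLike, method: str = "REML") -> float:
    try:
        fn = _TAU2_METHODS[method.upper()]
    except KeyError:
        raise ValueError(f"unknown tau^2 method {method!r}")
    return fn(y, v)


def heterogeneity_values(
    y: ArrayLike, v: ArrayLike, tau2_method: str = "REML"
) -> HeterogeneityResult:
    """Q, its chi-square p-value, I^2 and tau^2 for a set of effects."""
    y, v = _validate_yv(y, v)
    k = y.size
    if k < 2:
        raise ValueError("heterogeneity requires at least 2 effects")
    w = 1.0 / v
    mu = float(np.sum(w * y) / w.sum())
    q = float(np.sum(w * (y - mu) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q * 100.0) if q > 0 else 0.0
    tau2 = estimate_tau2_values(y, v, method=tau2_method)
    return HeterogeneityResult(Q=q, df=df, p_value=p, I2=i2, tau2=tau2)


def heterogeneity(
    effects: Sequence[EffectSize], tau2_method: str = "REML"
) -> HeterogeneityResult:
    y, v = _as_arrays(effects)
    return heterogeneity_values(y, v, tau2_method=tau2_method)


def select_model(het: HeterogeneityResult, threshold: float = 50.0) -> Model:
    """Random effects when I^2 exceeds the threshold, fixed otherwise.

    The boundary I^2 == threshold maps to FIXED (the selection rule is
    stated only for strict inequalities; the tie goes to the simpler model).
    """
    return Model.RANDOM if het.I2 > threshold else Model.FIXED


def pool_values(
    y: ArrayLike,
    v: ArrayLike,
    model: Union[Model, str] = Model.RANDOM,
    tau2_method: str = "REML",
    label: str = "overall",
    z: float = Z95,
    transform: str = "ratio",
    low_k: bool = False,
) -> PooledEffect:
    """Inverse-variance pooling of lnRR values given their variances.

    ``model`` may be FIXED, RANDOM, or ``"auto"`` to apply the I^2 > 50%
    selection rule. A single effect is passed through unpooled with its own
    sampling CI.
    """
    y, v = _validate_yv(y, v)
    k = y.size
    if k == 1:
        est, se = float(y[0]), float(math.sqrt(v[0]))
        lo, hi = est - z * se, est + z * se
        return PooledEffect(
            label=label,
            k=1,
            model=Model.FIXED,
            estimate_lnrr=est,
            se=se,
            ci_low=lo,
            ci_high=hi,
            percent=percent_change(est, transform),
            significant=lo > 0 or hi < 0,
            het=None,
            unpooled=True,
            low_k=low_k,
        )

    het = heterogeneity_values(y, v, tau2_method=tau2_method)
    if isinstance(model, str) and model.lower() == "auto":
        model = select_model(het)
    else:
        model = Model(model)
    tau2 = het.tau2 if model is Model.RANDOM else 0.0
    w = 1.0 / (v + tau2)
    sw = float(w.sum())
    est = float(np.sum(w * y) / sw)
    se = 1.0 / math.sqrt(sw)
    lo, hi = est - z * se, est + z * se
    return PooledEffect(
        label=label,
        k=k,
        model=model,
        estimate_lnrr=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        percent=percent_change(est, transform),
        significant=lo > 0 or hi < 0,
        het=het,
        low_k=low_k,
    )


def pool(
    effects: Sequence[EffectSize],
    model: Union[Model, str] = Model.RANDOM,
    tau2_method: str = "REML",
    label: str = "overall",
    z: float = Z95,
    transform: str = "ratio",
) -> PooledEffect:
    """Pool a sequence of effect sizes (see :func:`pool_values`)."""
    y, v = _as_arrays(effects)
    return pool_values(
        y, v, model=model, tau2_method=tau2_method, label=label, z=z,
        transform=transform,
    )


class Grouping(str, enum.Enum):
    """Stratifications used in the subgroup analyses."""

    ORGAN = "ORGAN"
    COMPOUND_CLASS = "COMPOUND_CLASS"
    COMPOUND_CLASS_BY_ORGAN = "COMPOUND_CLASS_BY_ORGAN"
    INOCULUM_MODE_BY_ORGAN = "INOCULUM_MODE_BY_ORGAN"
    AMF_ORDER = "AMF_ORDER"
    AMF_FAMILY = "AMF_FAMILY"
    AMF_GENUS = "AMF_GENUS"
    AMF_GENUS_BY_ORGAN = "AMF_GENUS_BY_ORGAN"
    PHYSIOLOGICAL_VARIABLE = "PHYSIOLOGICAL_VARIABLE"


def _group_key(effect: EffectSize, grouping: Grouping) -> Optional[str]:
    """Subgroup label for one effect, or None if it lacks the key.

    Taxonomy groupings apply only to single-species inocula; consortium
    records have no order/family/genus and are excluded (and counted).
    """
    r = effect.record
    if r is None:
        return None
    if grouping is Grouping.ORGAN:
        return r.organ.value if r.organ else None
    if grouping is Grouping.COMPOUND_CLASS:
        return r.compound_class.value if r.compound_class else None
    if grouping is Grouping.COMPOUND_CLASS_BY_ORGAN:
        if r.compound_class and r.organ:
            return f"{r.compound_class.value}|{r.organ.value}"
        return None
    if grouping is Grouping.INOCULUM_MODE_BY_ORGAN:
        if r.organ:
            return f"{r.inoculum_mode.value}|{r.organ.value}"
        return None
    if grouping is Grouping.AMF_ORDER:
        return r.amf_order if r.inoculum_mode is InoculumMode.SINGLE else None
    if grouping is Grouping.AMF_FAMILY:
        return r.amf_family if r.inoculum_mode is InoculumMode.SINGLE else None
    if grouping is Grouping.AMF_GENUS:
        return r.amf_genus if r.inoculum_mode is InoculumMode.SINGLE else None
    if grouping is Grouping.AMF_GENUS_BY_ORGAN:
        if r.inoculum_mode is InoculumMode.SINGLE and r.amf_genus and r.organ:
            return f"{r.amf_genus}|{r.organ.value}"
        return None
    if grouping is Grouping.PHYSIOLOGICAL_VARIABLE:
        if r.variable_kind is not VariableKind.INGREDIENT:
            return r.variable_kind.value
        return None
    raise ValueError(f"unknown grouping {grouping!r}")


@dataclass
class SubgroupTable:
    """Pooled results per subgroup plus the count of excluded effects."""

    grouping: Grouping
    groups: list[PooledEffect]
    n_excluded: int


def subgroup_pool(
    effects: Sequence[EffectSize],
    grouping: Union[Grouping, str],
    model: Union[Model, str] = Model.RANDOM,
    tau2_method: str = "REML",
    min_k: int = 2,
    z: float = Z95,
    transform: str = "ratio",
) -> SubgroupTable:
    """Pool effects within each level of a grouping.

    Effects lacking the grouping key are excluded and counted. Every
    non-empty group is reported; groups with fewer than ``min_k`` effects
    are flagged ``low_k`` rather than dropped (a k=1 group is additionally
    flagged ``unpooled``).
    """
    grouping = Grouping(grouping)
    buckets: dict[str, list[EffectSize]] = {}
    n_excluded = 0
    for e in effects:
        key = _group_key(e, grouping)
        if key is None:
            n_excluded += 1
        else:
            buckets.setdefault(key, []).append(e)
    groups = []
    for key in sorted(buckets):
        members = buckets[key]
        y, v = _as_arrays(members)
        groups.append(
            pool_values(
                y,
                v,
                model=model,
                tau2_method=tau2_method,
                label=key,
                z=z,
                transform=transform,
                low_k=len(members) < min_k,
            )
        )
    return SubgroupTable(grouping=grouping, groups=groups, n_excluded=n_excluded)
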