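"""Simulation experiments that check the pipeline against known truth.

Each experiment simulates many meta-analyses under stated conditions and
measures an operating characteristic of the pooling machinery: the
rejection rate of the Q test under homogeneity, the coverage of the pooled
95% CI, the false-positive rate of the significance flag under a zero
truth, the recovery of a configured subgroup ordering, and the recovery of
a known regression slope. They back both the test suite and the
``recover`` CLI subcommand.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .association import linear_fit
from .meta import heterogeneity_values, pool_values
from .records import CompoundClass
from .simulate import sample_effect_values, simulate_paired_effects

#: subgroup truths used by the ranking experiment (descending order)
RANKING_TRUTHS: dict[CompoundClass, float] = {
    CompoundClass.FLAVONOIDS: 0.52,
    CompoundClass.TERPENOIDS: 0.43,
    CompoundClass.QUINONES: 0.22,
    CompoundClass.PHENOLS: 0.12,
}


def q_calibration_experiment(
    seed: int,
    n_replicates: int = 1000,
    k: int = 30,
    mu: float = 0.25,
    alpha: float = 0.01,
) -> dict:
    """Q-test size and I^2 distribution under homogeneity (tau = 0).

    Effects are drawn under the model's own distributional assumptions
    (normal around a common mean, with known sampling variances of
    realistic magnitude), which is what the chi-square reference for Q
    presumes. With 3-6 replicates per arm the *estimated* variances have
    so few degrees of freedom that Q is markedly anti-conservative; that
    small-sample behaviour is documented, not asserted, so this experiment
    checks the statistic's nominal size where it is defined.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    i2_values = np.empty(n_replicates)
    for i in range(n_replicates):
        cv = rng.uniform(0.05, 0.20, size=k)
        n = rng.integers(3, 7, size=k)
        v = 2.0 * cv**2 / n  # delta-method lnRR variance, equal cv both arms
        y = rng.normal(mu, np.sqrt(v))
        het = heterogeneity_values(y, v, tau2_method="DL")
        if het.p_value < alpha:
            rejections += 1
        i2_values[i] = het.I2
    return {
        "rejection_rate": rejections / n_replicates,
        "i2_median": float(np.median(i2_values)),
        "i2_mean": float(np.mean(i2_values)),
        "n_replicates": n_replicates,
        "k": k,
        "alpha": alpha,
    }


def coverage_experiment(
    seed: int,
    n_replicates: int = 500,
    k: int = 233,
    mu: float = 0.24,
    tau: float = 0.2,
    tau2_method: str = "DL",
) -> dict:
    """Coverage of the pooled random-effects 95% CI for a known mean."""
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        y, v = sample_effect_values(k, mu, tau=tau, rng=rng)
        p = pool_values(y, v, model="RANDOM", tau2_method=tau2_method)
        if p.ci_low <= mu <= p.ci_high:
            covered += 1
    return {
        "coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "k": k,
        "mu": mu,
        "tau": tau,
    }


def type1_experiment(
    seed: int,
    n_replicates: int = 1000,
    k: int = 233,
    tau: float = 0.2,
    tau2_method: str = "DL",
) -> dict:
    """Rate at which the significance flag fires when the true mean is 0."""
    rng = np.random.default_rng(seed)
    fired = 0
    for _ in range(n_replicates):
        y, v = sample_effect_values(k, 0.0, tau=tau, rng=rng)
        p = pool_values(y, v, model="RANDOM", tau2_method=tau2_method)
        if p.significant:
            fired += 1
    return {
        "type1_rate": fired / n_replicates,
        "n_replicates": n_replicates,
        "k": k,
        "tau": tau,
    }


def ranking_experiment(
    seed: int,
    n_replicates: int = 200,
    k_per_group: int = 30,
    tau: float = 0.2,
    truths: Optional[dict[CompoundClass, float]] = None,
    tau2_method: str = "REML",
) -> dict:
    """How often the pooled estimates reproduce the true subgroup ordering."""
    truths = truths or RANKING_TRUTHS
    ordered = sorted(truths, key=truths.get, reverse=True)
    rng = np.random.default_rng(seed)
    recovered = 0
    for _ in range(n_replicates):
        estimates = {}
        for group, mu in truths.items():
            y, v = sample_effect_values(k_per_group, mu, tau=tau, rng=rng)
            estimates[group] = pool_values(y, v, model="RANDOM", tau2_method=tau2_method).estimate_lnrr
        observed = sorted(estimates, key=estimates.get, reverse=True)
        if observed == ordered:
            recovered += 1
    return {
        "recovery_rate": recovered / n_replicates,
        "n_replicates": n_replicates,
        "k_per_group": k_per_group,
        "tau": tau,
        "truths": {g.value: t for g, t in truths.items()},
    }


def regression_recovery_experiment(
    seed: int,
    n_replicates: int = 200,
    slope: float = 0.8,
    noise_sd: float = 0.1,
    n_pairs: int = 50,
    slope_tol: float = 0.1,
    r2_min: float = 0.8,
) -> dict:
    """How often OLS recovers a known slope within tolerance with high r^2."""
    rng = np.random.default_rng(seed)
    ok = 0
    slopes = np.empty(n_replicates)
    r2s = np.empty(n_replicates)
    for i in range(n_replicates):
        pairs = simulate_paired_effects(slope, noise_sd, n_pairs, rng)
        fit = linear_fit(pairs)
        slopes[i] = fit.slope
        r2s[i] = fit.r2
        if abs(fit.slope - slope) <= slope_tol and fit.r2 > r2_min:
            ok += 1
    return {
        "recovery_rate": ok / n_replicates,
        "slope_mean": float(np.mean(slopes)),
        "r2_mean": float(np.mean(r2s)),
        "n_replicates": n_replicates,
        "n_pairs": n_pairs,
        "true_slope": slope,
    }
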