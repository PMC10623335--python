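"""Synthetic extraction tables with known ground truth.

The generator emulates the statistical structure of a multi-study database
of paired inoculation/control measurements: subgroup-specific true log
response ratios, between-observation heterogeneity (SD ``tau``), within-arm
sampling noise at small replicate counts (3-6 per arm), and the mixed
dispersion reporting found in practice (SD given, SE given, only a CI given,
or nothing). Defaults mirror the synthesis this package reproduces: 28
studies contributing 233 ingredient observations, with compound-class truths
on the order of ln(1.1)-ln(1.7) and an overall mean effect near +0.25.

Physiological-factor effects are generated per study as linear functions of
the study's mean ingredient truth plus noise, so the association module can
be tested against known coupling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .ingest import DEFAULT_COLUMNS
from .records import (
    ArmSummary,
    CompoundClass,
    DispersionKind,
    InoculumMode,
    ObservationRecord,
    Organ,
    VariableKind,
)

#: genus -> (order, family) for the single-inoculum taxonomy fields
GENUS_TAXONOMY: dict[str, tuple[str, str]] = {
    "Rhizophagus": ("Glomerales", "Glomeraceae"),
    "Funneliformis": ("Glomerales", "Glomeraceae"),
    "Glomus": ("Glomerales", "Glomeraceae"),
    "Claroideoglomus": ("Glomerales", "Claroideoglomeraceae"),
    "Gigaspora": ("Diversisporales", "Gigasporaceae"),
    "Acaulospora": ("Diversisporales", "Acaulosporaceae"),
}

#: a realistic pool of mycorrhiza-responsive medicinal species
SPECIES_POOL: tuple[str, ...] = (
    "Salvia miltiorrhiza",
    "Glycyrrhiza uralensis",
    "Artemisia annua",
    "Ocimum basilicum",
    "Hypericum perforatum",
    "Panax quinquefolius",
    "Stevia rebaudiana",
    "Catharanthus roseus",
    "Calendula officinalis",
    "Plantago lanceolata",
    "Dianthus superbus",
    "Passiflora edulis",
    "Salvia officinalis",
    "Echinacea purpurea",
    "Withania somnifera",
    "Curcuma longa",
    "Mentha piperita",
    "Valeriana officinalis",
    "Scutellaria baicalensis",
    "Angelica sinensis",
)


@dataclass
class TrueEffects:
    """Ground-truth lnRR structure: compound base + additive shifts."""

    compound: dict[CompoundClass, float] = field(
        default_factory=lambda: {
            CompoundClass.FLAVONOIDS: 0.52,
            CompoundClass.TERPENOIDS: 0.43,
            CompoundClass.QUINONES: 0.22,
            CompoundClass.ORGANIC_ACIDS: 0.17,
            CompoundClass.PHENOLS: 0.12,
            CompoundClass.ALKALOIDS: -0.05,
            CompoundClass.OTHER: -0.08,
        }
    )
    organ_shift: dict[Organ, float] = field(
        default_factory=lambda: {Organ.ABOVEGROUND: -0.06, Organ.BELOWGROUND: 0.06}
    )
    genus_shift: dict[str, float] = field(
        default_factory=lambda: {"Rhizophagus": 0.15}
    )
    mode_shift: dict[InoculumMode, float] = field(
        default_factory=lambda: {InoculumMode.SINGLE: 0.0, InoculumMode.MULTI: -0.03}
    )

    def truth_for(
        self,
        compound: CompoundClass,
        organ: Organ,
        mode: InoculumMode,
        genus: Optional[str],
    ) -> float:
        t = self.compound[compound] + self.organ_shift[organ] + self.mode_shift[mode]
        if genus is not None:
            t += self.genus_shift.get(genus, 0.0)
        return t


@dataclass(frozen=True)
class PhysioLink:
    """Linear coupling of a factor's lnRR to a study's ingredient truth."""

    intercept: float
    slope: float
    noise_sd: float


def _default_physio_links() -> dict[VariableKind, PhysioLink]:
    # intercepts place factor means near their typical observed responses
    # (carotenoids ~+6%, chlorophylls ~+30-40%, conductance/photosynthesis
    # ~+80-95%, carbohydrates ~-30%) at the ~0.25 mean ingredient truth
    spec = {
        VariableKind.TC: (-0.5, 0.058),
        VariableKind.CHL_A: (1.0, 0.247),
        VariableKind.CHL_B: (0.8, 0.344),
        VariableKind.CHO: (-0.5, -0.342),
        VariableKind.GS: (1.0, 0.663),
        VariableKind.PN: (1.0, 0.610),
        VariableKind.WUE: (0.6, 0.673),
    }
    return {
        f: PhysioLink(intercept=mean - slope * 0.25, slope=slope, noise_sd=0.15)
        for f, (slope, mean) in spec.items()
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic extraction database.

    Defaults are the study conditions of the synthesis being emulated:
    28 studies, 233 ingredient observations, between-observation SD
    ``tau`` = 0.2, replicate counts 3-6 per arm, within-arm coefficient of
    variation 5-20%, and a mixed dispersion-reporting pattern.
    """

    n_studies: int = 28
    n_ingredient_obs: int = 233
    obs_per_study: tuple[int, int] = (2, 15)
    true_effects: TrueEffects = field(default_factory=TrueEffects)
    tau: float = 0.2
    cv_range: tuple[float, float] = (0.05, 0.20)
    n_reps_range: tuple[int, int] = (3, 6)
    dispersion_pattern: dict[DispersionKind, float] = field(
        default_factory=lambda: {
            DispersionKind.SD: 0.50,
            DispersionKind.SE: 0.35,
            DispersionKind.CI95: 0.10,
            DispersionKind.NONE: 0.05,
        }
    )
    compound_weights: dict[CompoundClass, float] = field(
        default_factory=lambda: {
            CompoundClass.TERPENOIDS: 0.28,
            CompoundClass.FLAVONOIDS: 0.18,
            CompoundClass.PHENOLS: 0.22,
            CompoundClass.ALKALOIDS: 0.10,
            CompoundClass.ORGANIC_ACIDS: 0.07,
            CompoundClass.QUINONES: 0.07,
            CompoundClass.OTHER: 0.08,
        }
    )
    organ_weights: dict[Organ, float] = field(
        default_factory=lambda: {Organ.ABOVEGROUND: 0.5, Organ.BELOWGROUND: 0.5}
    )
    mode_weights: dict[InoculumMode, float] = field(
        default_factory=lambda: {InoculumMode.SINGLE: 0.8, InoculumMode.MULTI: 0.2}
    )
    genus_weights: dict[str, float] = field(
        default_factory=lambda: {
            "Rhizophagus": 0.30,
            "Funneliformis": 0.20,
            "Glomus": 0.25,
            "Claroideoglomus": 0.10,
            "Gigaspora": 0.08,
            "Acaulospora": 0.07,
        }
    )
    baseline_mean: float = 10.0
    baseline_log_sd: float = 1.0
    physio_links: dict[VariableKind, PhysioLink] = field(
        default_factory=_default_physio_links
    )
    physio_presence: float = 0.5  # probability a study reports a given factor
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (
            ("dispersion_pattern", self.dispersion_pattern),
            ("compound_weights", self.compound_weights),
            ("organ_weights", self.organ_weights),
            ("mode_weights", self.mode_weights),
            ("genus_weights", self.genus_weights),
        ):
            total = sum(probs.values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not (0 < self.cv_range[0] <= self.cv_range[1]):
            raise ValueError("cv range must be positive and ordered")
        if self.n_reps_range[0] < 1 or self.n_reps_range[0] > self.n_reps_range[1]:
            raise ValueError("invalid replicate-count range")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SyntheticConfig":
        """Load scalar overrides (sizes, tau, cv, ranges, seed) from YAML."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls()
        for key in (
            "n_studies",
            "n_ingredient_obs",
            "tau",
            "baseline_mean",
            "baseline_log_sd",
            "physio_presence",
            "seed",
        ):
            if key in raw:
                setattr(cfg, key, type(getattr(cfg, key))(raw[key]))
        for key in ("obs_per_study", "cv_range", "n_reps_range"):
            if key in raw:
                setattr(cfg, key, tuple(raw[key]))
        cfg.validate()
        return cfg


def _choice(rng: np.random.Generator, weights: dict):
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _sample_arm(
    mu: float,
    cv: float,
    n: int,
    kind: DispersionKind,
    rng: np.random.Generator,
) -> ArmSummary:
    """Draw an observed arm: sample mean, sample SD, reported dispersion."""
    sd_true = cv * mu
    mean_obs = float(rng.normal(mu, sd_true / math.sqrt(n)))
    if mean_obs <= 0:  # vanishingly rare at cv <= 0.2, n >= 3
        mean_obs = mu
    if n > 1 and sd_true > 0:
        sd_obs = sd_true * math.sqrt(float(rng.chisquare(n - 1)) / (n - 1))
    else:
        sd_obs = sd_true
    if kind is DispersionKind.SD:
        return ArmSummary(mean=mean_obs, n=n, dispersion_kind=kind, dispersion_value=sd_obs)
    if kind is DispersionKind.SE:
        return ArmSummary(
            mean=mean_obs, n=n, dispersion_kind=kind,
            dispersion_value=sd_obs / math.sqrt(n),
        )
    if kind is DispersionKind.CI95:
        return ArmSummary(
            mean=mean_obs, n=n, dispersion_kind=kind,
            dispersion_value=1.959963984540054 * sd_obs / math.sqrt(n),
        )
    return ArmSummary(mean=mean_obs, n=n, dispersion_kind=DispersionKind.NONE)


def simulate_observation(
    truth: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    *,
    obs_id: str,
    study_id: str,
    plant_species: str,
    inoculum_mode: InoculumMode,
    variable_kind: VariableKind = VariableKind.INGREDIENT,
    compound_class: Optional[CompoundClass] = None,
    organ: Optional[Organ] = None,
    amf_genus: Optional[str] = None,
    tau: Optional[float] = None,
) -> ObservationRecord:
    """Draw one paired observation around a subgroup truth.

    The observation-level true effect is ``Normal(truth, tau^2)``; the
    control mean is log-normal around the configured baseline; the treatment
    mean is the control mean times ``exp(theta)``; both arms then get sample
    means and SDs at the drawn replicate count, and the dispersion is
    reported in the form drawn from ``cfg.dispersion_pattern``.
    """
    tau = cfg.tau if tau is None else tau
    theta = float(rng.normal(truth, tau)) if tau > 0 else truth
    mu_c = float(rng.lognormal(math.log(cfg.baseline_mean), cfg.baseline_log_sd))
    mu_t = mu_c * math.exp(theta)
    cv = float(rng.uniform(*cfg.cv_range))
    n = int(rng.integers(cfg.n_reps_range[0], cfg.n_reps_range[1] + 1))
    kind = _choice(rng, cfg.dispersion_pattern)
    treatment = _sample_arm(mu_t, cv, n, kind, rng)
    control = _sample_arm(mu_c, cv, n, kind, rng)
    order = family = None
    if amf_genus is not None:
        order, family = GENUS_TAXONOMY.get(amf_genus, ("Incertae sedis", "Incertae sedis"))
    return ObservationRecord(
        obs_id=obs_id,
        study_id=study_id,
        plant_species=plant_species,
        variable_kind=variable_kind,
        inoculum_mode=inoculum_mode,
        treatment=treatment,
        control=control,
        compound_class=compound_class,
        organ=organ,
        amf_order=order,
        amf_family=family,
        amf_genus=amf_genus,
    )


def _study_sizes(cfg: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    """Ingredient-observation counts per study, summing to the target."""
    lo, hi = cfg.obs_per_study
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_studies)]
    # rebalance to hit the configured total while respecting the bounds
    diff = cfg.n_ingredient_obs - sum(sizes)
    idx = 0
    while diff != 0:
        i = idx % cfg.n_studies
        if diff > 0 and sizes[i] < hi:
            sizes[i] += 1
            diff -= 1
        elif diff < 0 and sizes[i] > lo:
            sizes[i] -= 1
            diff += 1
        idx += 1
        if idx > 100 * cfg.n_studies:  # bounds cannot accommodate the total
            sizes[i] += diff
            diff = 0
    return sizes


def generate_records(cfg: SyntheticConfig) -> list[ObservationRecord]:
    """Generate the full synthetic database as validated records.

    Each study has one plant species, one organ, one inoculum mode (and one
    genus when single); compound classes vary within study. Physiological
    records are appended per study for the factors it 'reports', with their
    truths linked linearly to the study's mean ingredient truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records: list[ObservationRecord] = []
    counter = 0
    sizes = _study_sizes(cfg, rng)
    for s, size in enumerate(sizes, start=1):
        study_id = f"study{s:03d}"
        species = SPECIES_POOL[int(rng.integers(len(SPECIES_POOL)))]
        organ = _choice(rng, cfg.organ_weights)
        mode = _choice(rng, cfg.mode_weights)
        genus = _choice(rng, cfg.genus_weights) if mode is InoculumMode.SINGLE else None
        truths = []
        for _ in range(size):
            compound = _choice(rng, cfg.compound_weights)
            truth = cfg.true_effects.truth_for(compound, organ, mode, genus)
            truths.append(truth)
            counter += 1
            records.append(
                simulate_observation(
                    truth,
                    cfg,
                    rng,
                    obs_id=f"obs{counter:04d}",
                    study_id=study_id,
                    plant_species=species,
                    inoculum_mode=mode,
                    compound_class=compound,
                    organ=organ,
                    amf_genus=genus,
                )
            )
        mean_truth = float(np.mean(truths))
        for factor, link in cfg.physio_links.items():
            if rng.uniform() < cfg.physio_presence:
                x_truth = link.intercept + link.slope * mean_truth + float(
                    rng.normal(0.0, link.noise_sd)
                )
                counter += 1
                records.append(
                    simulate_observation(
                        x_truth,
                        cfg,
                        rng,
                        obs_id=f"obs{counter:04d}",
                        study_id=study_id,
                        plant_species=species,
                        inoculum_mode=mode,
                        variable_kind=factor,
                        organ=organ,
                        amf_genus=genus,
                        tau=0.0,  # study-level factor effect; noise already drawn
                    )
                )
    return records


def generate_dataset(cfg: SyntheticConfig) -> pd.DataFrame:
    """Generate the synthetic database as an extraction table.

    The frame uses the default ingest dialect and parses with zero
    rejections; the same seed yields an identical frame.
    """
    from .ingest import records_to_frame

    frame = records_to_frame(generate_records(cfg))
    assert list(frame.columns) == list(DEFAULT_COLUMNS.values())
    return frame


def write_dataset(cfg: SyntheticConfig, path: Union[str, Path]) -> pd.DataFrame:
    """Write the synthetic table as CSV; byte-identical for equal configs."""
    frame = generate_dataset(cfg)
    frame.to_csv(path, index=False)
    return frame


def sample_effect_values(
    k: int,
    mu: float,
    tau: float,
    rng: np.random.Generator,
    cv_range: tuple[float, float] = (0.05, 0.20),
    n_reps_range: tuple[int, int] = (3, 6),
    baseline_mean: float = 10.0,
    baseline_log_sd: float = 1.0,
    variance_floor: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of k (lnRR, variance) pairs around a common truth.

    Includes both between-observation heterogeneity (``tau``) and within-arm
    sampling noise, exactly as the record-level generator does, but without
    building records; intended for calibration experiments that need many
    thousands of simulated meta-analyses.
    """
    theta = rng.normal(mu, tau, size=k) if tau > 0 else np.full(k, mu)
    mu_c = rng.lognormal(math.log(baseline_mean), baseline_log_sd, size=k)
    mu_t = mu_c * np.exp(theta)
    cv = rng.uniform(cv_range[0], cv_range[1], size=k)
    n = rng.integers(n_reps_range[0], n_reps_range[1] + 1, size=k)
    sd_t, sd_c = cv * mu_t, cv * mu_c
    m_t = rng.normal(mu_t, sd_t / np.sqrt(n))
    m_c = rng.normal(mu_c, sd_c / np.sqrt(n))
    m_t = np.where(m_t <= 0, mu_t, m_t)
    m_c = np.where(m_c <= 0, mu_c, m_c)
    s_t = sd_t * np.sqrt(rng.chisquare(n - 1) / (n - 1))
    s_c = sd_c * np.sqrt(rng.chisquare(n - 1) / (n - 1))
    out_y = np.log(m_t / m_c)
    out_v = s_t**2 / (n * m_t**2) + s_c**2 / (n * m_c**2)
    out_v = np.maximum(out_v, variance_floor)
    return out_y, out_v


def simulate_paired_effects(
    slope: float,
    noise_sd: float,
    n_pairs: int,
    rng: np.random.Generator,
    factor: VariableKind = VariableKind.CHL_A,
    intercept: float = 0.0,
    x_mean: float = 0.25,
    x_sd: float = 0.5,
):
    """Draw paired (factor, ingredient) effects with a known linear law.

    ``y = intercept + slope * x + Normal(0, noise_sd)`` with the factor
    effects spread as ``Normal(x_mean, x_sd)``; the default spread matches
    the span of physiological responses seen across inoculation studies.
    """
    from .association import PairedEffect

    x = rng.normal(x_mean, x_sd, size=n_pairs)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n_pairs)
    return [
        PairedEffect(study_id=f"study{i:03d}", factor=factor, x=float(xi), y=float(yi))
        for i, (xi, yi) in enumerate(zip(x, y), start=1)
    ]
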