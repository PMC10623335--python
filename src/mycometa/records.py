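"""Core record types for paired treatment/control observations.

An observation is one treatment/control comparison extracted from a source
study: the arithmetic mean, a dispersion measure, and the replicate count of
each arm, plus the grouping metadata the downstream analyses stratify on
(plant organ, compound class, inoculum composition, fungal taxonomy).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class DispersionKind(str, enum.Enum):
    """How an arm's dispersion was reported in the source study."""

    SD = "SD"
    SE = "SE"
    CI95 = "CI95"  # value is the half-width of the 95% interval
    NONE = "NONE"


class VariableKind(str, enum.Enum):
    """What was measured: an active-ingredient content or a physiological factor."""

    INGREDIENT = "INGREDIENT"
    TC = "TC"          # total carotenoids
    CHL_A = "CHL_A"    # chlorophyll A
    CHL_B = "CHL_B"    # chlorophyll B
    CHO = "CHO"        # total carbohydrates
    GS = "GS"          # stomatal conductance
    PN = "PN"          # net photosynthetic rate
    WUE = "WUE"        # water-use efficiency


PHYSIOLOGICAL_FACTORS: tuple[VariableKind, ...] = tuple(
    k for k in VariableKind if k is not VariableKind.INGREDIENT
)


class CompoundClass(str, enum.Enum):
    PHENOLS = "PHENOLS"
    FLAVONOIDS = "FLAVONOIDS"
    ALKALOIDS = "ALKALOIDS"
    TERPENOIDS = "TERPENOIDS"
    ORGANIC_ACIDS = "ORGANIC_ACIDS"
    QUINONES = "QUINONES"
    OTHER = "OTHER"


class Organ(str, enum.Enum):
    ABOVEGROUND = "ABOVEGROUND"
    BELOWGROUND = "BELOWGROUND"


class InoculumMode(str, enum.Enum):
    SINGLE = "SINGLE"
    MULTI = "MULTI"


@dataclass(frozen=True)
class ArmSummary:
    """Summary statistics for one experimental arm (treatment or control).

    Parameters
    ----------
    mean : float
        Arithmetic mean of the measured quantity (any consistent unit).
    n : int
        Replicate count, at least 1.
    dispersion_kind : DispersionKind
        How ``dispersion_value`` is to be interpreted.
    dispersion_value : float, optional
        Non-negative dispersion; absent iff ``dispersion_kind`` is NONE.
    """

    mean: float
    n: int
    dispersion_kind: DispersionKind = DispersionKind.NONE
    dispersion_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"replicate count must be >= 1, got {self.n}")
        if self.dispersion_kind is DispersionKind.NONE:
            if self.dispersion_value is not None:
                raise ValueError("dispersion_value must be absent when kind is NONE")
        else:
            if self.dispersion_value is None:
                raise ValueError(
                    f"dispersion_value required for kind {self.dispersion_kind.value}"
                )
            if self.dispersion_value < 0:
                raise ValueError("dispersion_value must be non-negative")


@dataclass(frozen=True)
class ObservationRecord:
    """One paired treatment/control observation with its grouping metadata.

    Invariants: ``compound_class`` is present iff the record measures an
    ingredient; fungal taxonomy fields are absent for multi-species inocula
    (a consortium has no single genus); ``study_id`` is non-empty.
    """

    obs_id: str
    study_id: str
    plant_species: str
    variable_kind: VariableKind
    inoculum_mode: InoculumMode
    treatment: ArmSummary
    control: ArmSummary
    compound_class: Optional[CompoundClass] = None
    organ: Optional[Organ] = None
    amf_order: Optional[str] = None
    amf_family: Optional[str] = None
    amf_genus: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        is_ingredient = self.variable_kind is VariableKind.INGREDIENT
        if is_ingredient and self.compound_class is None:
            raise ValueError("compound_class required for ingredient observations")
        if not is_ingredient and self.compound_class is not None:
            raise ValueError("compound_class only valid for ingredient observations")
        if self.inoculum_mode is InoculumMode.MULTI:
            if any((self.amf_order, self.amf_family, self.amf_genus)):
                raise ValueError("taxonomy fields must be absent for multi-AMF inocula")
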