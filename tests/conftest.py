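from __future__ import annotations

from typing import Optional

import pytest
from hypothesis import HealthCheck, settings

from mycometa.records import (
    ArmSummary,
    CompoundClass,
    DispersionKind,
    InoculumMode,
    ObservationRecord,
    Organ,
    VariableKind,
)
from mycometa.effects import EffectSize

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_arm(
    mean: float = 10.0,
    n: int = 4,
    kind: DispersionKind = DispersionKind.SD,
    value: Optional[float] = 1.0,
) -> ArmSummary:
    if kind is DispersionKind.NONE:
        value = None
    return ArmSummary(mean=mean, n=n, dispersion_kind=kind, dispersion_value=value)


def make_record(
    obs_id: str = "obs1",
    study_id: str = "study001",
    species: str = "Salvia miltiorrhiza",
    variable_kind: VariableKind = VariableKind.INGREDIENT,
    compound: Optional[CompoundClass] = CompoundClass.FLAVONOIDS,
    organ: Optional[Organ] = Organ.BELOWGROUND,
    mode: InoculumMode = InoculumMode.SINGLE,
    genus: Optional[str] = "Rhizophagus",
    treatment: Optional[ArmSummary] = None,
    control: Optional[ArmSummary] = None,
) -> ObservationRecord:
    if variable_kind is not VariableKind.INGREDIENT:
        compound = None
    order = family = None
    if mode is InoculumMode.SINGLE and genus:
        order, family = "Glomerales", "Glomeraceae"
    else:
        genus = None
    return ObservationRecord(
        obs_id=obs_id,
        study_id=study_id,
        plant_species=species,
        variable_kind=variable_kind,
        inoculum_mode=mode,
        treatment=treatment or make_arm(mean=12.0),
        control=control or make_arm(mean=10.0),
        compound_class=compound,
        organ=organ,
        amf_order=order,
        amf_family=family,
        amf_genus=genus,
    )


def make_effect(
    lnrr: float,
    variance: float,
    obs_id: str = "e1",
    **record_kwargs,
) -> EffectSize:
    return EffectSize(
        obs_id=obs_id,
        lnrr=lnrr,
        variance=variance,
        record=make_record(obs_id=obs_id, **record_kwargs),
    )


@pytest.fixture
def small_csv(tmp_path):
    """A tiny well-formed extraction table in the default dialect."""
    text = (
        "obs_id,study_id,plant_species,variable_kind,compound_class,organ,"
        "inoculum_mode,amf_order,amf_family,amf_genus,"
        "mean_t,dispersion_value_t,dispersion_kind_t,n_t,"
        "mean_c,dispersion_value_c,dispersion_kind_c,n_c\n"
        "o1,s1,Salvia miltiorrhiza,INGREDIENT,FLAVONOIDS,BELOWGROUND,SINGLE,"
        "Glomerales,Glomeraceae,Rhizophagus,12.0,1.2,SD,4,10.0,1.0,SD,4\n"
        "o2,s1,Salvia miltiorrhiza,PN,,ABOVEGROUND,SINGLE,"
        "Glomerales,Glomeraceae,Rhizophagus,8.0,0.4,SE,3,5.0,0.2,SE,3\n"
        "o3,s2,Ocimum basilicum,INGREDIENT,PHENOLS,ABOVEGROUND,MULTI,"
        ",,,7.5,,CI95,5,6.0,0.9,CI95,5\n"
    )
    path = tmp_path / "table.csv"
    path.write_text(text)
    return path
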