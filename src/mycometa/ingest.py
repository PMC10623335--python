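"""Reading, validating and harmonizing extraction tables.

The extraction table is a delimited text file with one row per paired
observation. Column names and enum spellings vary between extraction efforts,
so the dialect (column map, synonym maps, delimiter) lives in an
:class:`IngestConfig` which can be loaded from a YAML file.

Dispersion harmonization converts every arm to a standard deviation:
SD passes through, SE is converted via ``SD = SE * sqrt(n)``, and arms
reporting only a 95% CI or nothing at all have SD imputed as one tenth of
the mean (the convention of the synthesis this package reproduces; a
half-width-based conversion is available as an opt-in alternative).
"""
from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .records import (
    ArmSummary,
    CompoundClass,
    DispersionKind,
    InoculumMode,
    ObservationRecord,
    Organ,
    VariableKind,
)


class SchemaError(ValueError):
    """A mandatory column is missing from the input header."""


class NonAnalyzableError(ValueError):
    """The arm cannot enter a log-ratio analysis (non-positive mean)."""


#: logical field -> default column name
DEFAULT_COLUMNS: dict[str, str] = {
    "obs_id": "obs_id",
    "study_id": "study_id",
    "plant_species": "plant_species",
    "variable_kind": "variable_kind",
    "compound_class": "compound_class",
    "organ": "organ",
    "inoculum_mode": "inoculum_mode",
    "amf_order": "amf_order",
    "amf_family": "amf_family",
    "amf_genus": "amf_genus",
    "mean_t": "mean_t",
    "dispersion_value_t": "dispersion_value_t",
    "dispersion_kind_t": "dispersion_kind_t",
    "n_t": "n_t",
    "mean_c": "mean_c",
    "dispersion_value_c": "dispersion_value_c",
    "dispersion_kind_c": "dispersion_kind_c",
    "n_c": "n_c",
}

MANDATORY_FIELDS = (
    "study_id",
    "plant_species",
    "variable_kind",
    "inoculum_mode",
    "mean_t",
    "n_t",
    "mean_c",
    "n_c",
)

DEFAULT_ORGAN_SYNONYMS = {
    "ABOVEGROUND": "ABOVEGROUND",
    "BELOWGROUND": "BELOWGROUND",
    "SHOOT": "ABOVEGROUND",
    "LEAF": "ABOVEGROUND",
    "LEAVES": "ABOVEGROUND",
    "STEM": "ABOVEGROUND",
    "FLOWER": "ABOVEGROUND",
    "AERIAL": "ABOVEGROUND",
    "ROOT": "BELOWGROUND",
    "ROOTS": "BELOWGROUND",
    "RHIZOME": "BELOWGROUND",
    "BULB": "BELOWGROUND",
    "TUBER": "BELOWGROUND",
}

DEFAULT_COMPOUND_SYNONYMS = {
    "PHENOLS": "PHENOLS",
    "PHENOL": "PHENOLS",
    "PHENOLICS": "PHENOLS",
    "FLAVONOIDS": "FLAVONOIDS",
    "FLAVONOID": "FLAVONOIDS",
    "ALKALOIDS": "ALKALOIDS",
    "ALKALOID": "ALKALOIDS",
    "TERPENOIDS": "TERPENOIDS",
    "TERPENOID": "TERPENOIDS",
    "TERPENES": "TERPENOIDS",
    "TERPENE": "TERPENOIDS",
    "ORGANIC_ACIDS": "ORGANIC_ACIDS",
    "ORGANIC_ACID": "ORGANIC_ACIDS",
    "QUINONES": "QUINONES",
    "QUINONE": "QUINONES",
    "OTHER": "OTHER",
    "OTHERS": "OTHER",
}

DEFAULT_VARIABLE_SYNONYMS = {
    "INGREDIENT": "INGREDIENT",
    "ACTIVE_INGREDIENT": "INGREDIENT",
    "TC": "TC",
    "CAROTENOIDS": "TC",
    "CHL_A": "CHL_A",
    "CHLA": "CHL_A",
    "CHL_B": "CHL_B",
    "CHLB": "CHL_B",
    "CHO": "CHO",
    "GS": "GS",
    "PN": "PN",
    "WUE": "WUE",
}

DEFAULT_MODE_SYNONYMS = {
    "SINGLE": "SINGLE",
    "MULTI": "MULTI",
    "MIXED": "MULTI",
    "CONSORTIUM": "MULTI",
}

DEFAULT_DISPERSION_SYNONYMS = {
    "SD": "SD",
    "SE": "SE",
    "SEM": "SE",
    "CI95": "CI95",
    "CI": "CI95",
    "NONE": "NONE",
    "": "NONE",
}


def _norm_token(token: str) -> str:
    return token.strip().upper().replace("-", "_").replace(" ", "_")


@dataclass
class IngestConfig:
    """Dialect of an extraction table: column names, synonyms, delimiter."""

    columns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    delimiter: str = ","
    organ_synonyms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_SYNONYMS)
    )
    compound_synonyms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMPOUND_SYNONYMS)
    )
    variable_synonyms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLE_SYNONYMS)
    )
    mode_synonyms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MODE_SYNONYMS)
    )
    dispersion_synonyms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DISPERSION_SYNONYMS)
    )
    #: "mean_over_10" (as-stated convention) or "half_width" (SD = hw*sqrt(n)/1.96)
    ci95_rule: str = "mean_over_10"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "IngestConfig":
        """Load a dialect file; unspecified keys keep their defaults.

        Synonym maps given in the file are merged on top of the built-in
        ones (normalized to upper-snake tokens), so a file only needs to
        list the project-specific spellings.
        """
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls()
        if "columns" in raw:
            cfg.columns.update({str(k): str(v) for k, v in raw["columns"].items()})
        if "delimiter" in raw:
            cfg.delimiter = str(raw["delimiter"])
        if "ci95_rule" in raw:
            cfg.ci95_rule = str(raw["ci95_rule"])
        for key in (
            "organ_synonyms",
            "compound_synonyms",
            "variable_synonyms",
            "mode_synonyms",
            "dispersion_synonyms",
        ):
            if key in raw:
                target = getattr(cfg, key)
                target.update(
                    {_norm_token(str(k)): _norm_token(str(v)) for k, v in raw[key].items()}
                )
        return cfg


@dataclass(frozen=True)
class Rejection:
    """A data row that failed validation, with a human-readable reason."""

    row_number: int  # 1-based index among data rows
    reason: str


@dataclass
class ParseResult:
    records: list[ObservationRecord]
    rejections: list[Rejection]
    warnings: list[str]
    n_rows: int

    def rejections_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.row_number, r.reason) for r in self.rejections],
            columns=["row_number", "reason"],
        )


def _parse_float(raw: Optional[str]) -> Optional[float]:
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    return float(raw)


def _parse_arm(
    row: dict[str, str], cfg: IngestConfig, suffix: str
) -> ArmSummary:
    """Build one arm from a row; raises ValueError with a rejection reason."""
    col = cfg.columns
    mean_raw = row.get(col[f"mean_{suffix}"])
    n_raw = row.get(col[f"n_{suffix}"])
    try:
        mean = _parse_float(mean_raw)
    except ValueError:
        raise ValueError(f"non-numeric mean_{suffix}: {mean_raw!r}")
    if mean is None:
        raise ValueError(f"missing mean_{suffix}")
    if mean <= 0:
        raise ValueError(
            f"non-positive mean_{suffix} ({mean}); log response ratio undefined"
        )
    if n_raw is None or not n_raw.strip():
        raise ValueError(
            f"missing replicate count n_{suffix} "
            "(inclusion requires an obtainable number of replicates)"
        )
    try:
        n_float = float(n_raw)
    except ValueError:
        raise ValueError(f"non-numeric n_{suffix}: {n_raw!r}")
    if n_float != int(n_float) or int(n_float) < 1:
        raise ValueError(f"invalid replicate count n_{suffix}: {n_raw!r}")
    n = int(n_float)

    value_col = col.get(f"dispersion_value_{suffix}")
    kind_col = col.get(f"dispersion_kind_{suffix}")
    value = None
    if value_col and value_col in row:
        try:
            value = _parse_float(row.get(value_col))
        except ValueError:
            raise ValueError(f"non-numeric dispersion_value_{suffix}")
    kind_token = ""
    if kind_col and kind_col in row and row.get(kind_col):
        kind_token = _norm_token(row[kind_col])
    if value is None:
        kind = DispersionKind.NONE
    else:
        if value < 0:
            raise ValueError(f"negative dispersion_value_{suffix}")
        if not kind_token:
            kind = DispersionKind.SD  # bare dispersion column defaults to SD
        else:
            mapped = cfg.dispersion_synonyms.get(kind_token)
            if mapped is None:
                raise ValueError(f"unknown dispersion kind {kind_token!r}")
            kind = DispersionKind(mapped)
            if kind is DispersionKind.NONE:
                value = None
    return ArmSummary(mean=mean, n=n, dispersion_kind=kind, dispersion_value=value)


def _map_enum(
    token: str, synonyms: dict[str, str], enum_cls, what: str
):
    norm = _norm_token(token)
    mapped = synonyms.get(norm, norm)
    try:
        return enum_cls(mapped)
    except ValueError:
        raise ValueError(f"unknown {what} value {token!r}")


def parse_observations(
    path: Union[str, Path], config: Optional[IngestConfig] = None
) -> ParseResult:
    """Parse a delimited extraction table into validated observation records.

    Every data row is accounted for: it yields either a record or a
    :class:`Rejection` carrying its 1-based row number and the reason.
    A missing mandatory column aborts with :class:`SchemaError`.
    """
    cfg = config or IngestConfig()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=cfg.delimiter)
        header = reader.fieldnames or []
        missing = [
            cfg.columns[f] for f in MANDATORY_FIELDS if cfg.columns[f] not in header
        ]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        rows = list(reader)

    col = cfg.columns
    records: list[ObservationRecord] = []
    rejections: list[Rejection] = []
    warnings: list[str] = []

    for i, row in enumerate(rows, start=1):
        try:
            study_id = (row.get(col["study_id"]) or "").strip()
            if not study_id:
                raise ValueError("empty study_id")
            species = (row.get(col["plant_species"]) or "").strip()
            vkind = _map_enum(
                row.get(col["variable_kind"]) or "",
                cfg.variable_synonyms,
                VariableKind,
                "variable_kind",
            )
            mode = _map_enum(
                row.get(col["inoculum_mode"]) or "",
                cfg.mode_synonyms,
                InoculumMode,
                "inoculum_mode",
            )

            compound = None
            compound_raw = (row.get(col.get("compound_class", ""), "") or "").strip()
            if vkind is VariableKind.INGREDIENT:
                if not compound_raw:
                    raise ValueError("ingredient observation lacks compound_class")
                compound = _map_enum(
                    compound_raw, cfg.compound_synonyms, CompoundClass, "compound_class"
                )
            elif compound_raw:
                warnings.append(
                    f"row {i}: compound_class ignored on physiological record"
                )

            organ = None
            organ_raw = (row.get(col.get("organ", ""), "") or "").strip()
            if organ_raw:
                organ = _map_enum(organ_raw, cfg.organ_synonyms, Organ, "organ")

            order = family = genus = None
            if mode is InoculumMode.SINGLE:
                order = (row.get(col.get("amf_order", ""), "") or "").strip() or None
                family = (row.get(col.get("amf_family", ""), "") or "").strip() or None
                genus = (row.get(col.get("amf_genus", ""), "") or "").strip() or None
            else:
                if any(
                    (row.get(col.get(f, ""), "") or "").strip()
                    for f in ("amf_order", "amf_family", "amf_genus")
                ):
                    warnings.append(
                        f"row {i}: taxonomy fields ignored on multi-AMF record"
                    )

            treatment = _parse_arm(row, cfg, "t")
            control = _parse_arm(row, cfg, "c")

            obs_id = (row.get(col.get("obs_id", ""), "") or "").strip() or f"obs{i:04d}"
            records.append(
                ObservationRecord(
                    obs_id=obs_id,
                    study_id=study_id,
                    plant_species=species,
                    variable_kind=vkind,
                    inoculum_mode=mode,
                    treatment=treatment,
                    control=control,
                    compound_class=compound,
                    organ=organ,
                    amf_order=order,
                    amf_family=family,
                    amf_genus=genus,
                )
            )
        except ValueError as exc:
            rejections.append(Rejection(row_number=i, reason=str(exc)))

    return ParseResult(
        records=records, rejections=rejections, warnings=warnings, n_rows=len(rows)
    )


def harmonize_dispersion(
    arm: ArmSummary, ci95_rule: str = "mean_over_10"
) -> ArmSummary:
    """Return the arm with its dispersion expressed as a standard deviation.

    SD is passed through unchanged; SE becomes ``SE * sqrt(n)``; CI95-only
    and dispersion-free arms get SD imputed as ``mean / 10`` (the as-stated
    convention). With ``ci95_rule="half_width"`` a CI95 arm instead uses
    ``half_width * sqrt(n) / 1.96``. Idempotent.
    """
    if arm.mean <= 0:
        raise NonAnalyzableError(f"non-positive mean {arm.mean}")
    kind = arm.dispersion_kind
    if kind is DispersionKind.SD:
        return arm
    if kind is DispersionKind.SE:
        sd = arm.dispersion_value * math.sqrt(arm.n)
    elif kind is DispersionKind.CI95 and ci95_rule == "half_width":
        sd = arm.dispersion_value * math.sqrt(arm.n) / 1.959963984540054
    else:  # CI95 under the as-stated rule, or no dispersion at all
        sd = abs(arm.mean) / 10.0
    return replace(arm, dispersion_kind=DispersionKind.SD, dispersion_value=sd)


def harmonize_record(
    record: ObservationRecord, ci95_rule: str = "mean_over_10"
) -> ObservationRecord:
    """Harmonize both arms of a record to SD dispersion."""
    return dataclasses.replace(
        record,
        treatment=harmonize_dispersion(record.treatment, ci95_rule),
        control=harmonize_dispersion(record.control, ci95_rule),
    )


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Serialize records to a DataFrame in the default column dialect."""
    rows = []
    for r in records:
        rows.append(
            {
                "obs_id": r.obs_id,
                "study_id": r.study_id,
                "plant_species": r.plant_species,
                "variable_kind": r.variable_kind.value,
                "compound_class": r.compound_class.value if r.compound_class else "",
                "organ": r.organ.value if r.organ else "",
                "inoculum_mode": r.inoculum_mode.value,
                "amf_order": r.amf_order or "",
                "amf_family": r.amf_family or "",
                "amf_genus": r.amf_genus or "",
                "mean_t": r.treatment.mean,
                "dispersion_value_t": (
                    "" if r.treatment.dispersion_value is None else r.treatment.dispersion_value
                ),
                "dispersion_kind_t": r.treatment.dispersion_kind.value,
                "n_t": r.treatment.n,
                "mean_c": r.control.mean,
                "dispersion_value_c": (
                    "" if r.control.dispersion_value is None else r.control.dispersion_value
                ),
                "dispersion_kind_c": r.control.dispersion_kind.value,
                "n_c": r.control.n,
            }
        )
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values()))


def write_observations(
    records: Sequence[ObservationRecord],
    path: Union[str, Path],
    delimiter: str = "\t",
) -> None:
    """Re-emit validated records as a delimited table (default TSV).

    The output uses the default column dialect, so re-parsing it with the
    matching delimiter round-trips to identical records (floats are written
    with ``repr`` precision).
    """
    frame = records_to_frame(records)
    frame.to_csv(path, sep=delimiter, index=False)
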