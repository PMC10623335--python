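import math

import pytest
from hypothesis import given, strategies as st

from mycometa.ingest import (
    IngestConfig,
    NonAnalyzableError,
    SchemaError,
    harmonize_dispersion,
    parse_observations,
    write_observations,
)
from mycometa.records import ArmSummary, DispersionKind, Organ
from mycometa.simulate import SyntheticConfig, generate_records

from conftest import make_arm

HEADER = (
    "obs_id,study_id,plant_species,variable_kind,compound_class,organ,"
    "inoculum_mode,amf_order,amf_family,amf_genus,"
    "mean_t,dispersion_value_t,dispersion_kind_t,n_t,"
    "mean_c,dispersion_value_c,dispersion_kind_c,n_c\n"
)


def write(tmp_path, body, header=HEADER):
    path = tmp_path / "t.csv"
    path.write_text(header + body)
    return path


class TestParsing:
    def test_well_formed_rows_all_parse(self, small_csv):
        result = parse_observations(small_csv)
        assert len(result.records) == 3
        assert result.rejections == []
        assert result.n_rows == 3

    def test_organ_synonym_mapped(self, tmp_path):
        path = write(
            tmp_path,
            "o1,s1,Sp,INGREDIENT,PHENOLS,root,SINGLE,,,Glomus,2,0.2,SD,3,1,0.1,SD,3\n",
        )
        result = parse_observations(path)
        assert len(result.records) == 1
        assert result.records[0].organ is Organ.BELOWGROUND

    def test_missing_replicate_count_rejected(self, tmp_path):
        path = write(
            tmp_path,
            "o1,s1,Sp,INGREDIENT,PHENOLS,root,SINGLE,,,,2,0.2,SD,,1,0.1,SD,3\n",
        )
        result = parse_observations(path)
        assert result.records == []
        assert len(result.rejections) == 1
        assert "replicate" in result.rejections[0].reason

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("obs_id,study_id\no1,s1\n")
        with pytest.raises(SchemaError):
            parse_observations(path)

    @pytest.mark.parametrize(
        "row,fragment",
        [
            ("o1,s1,Sp,INGREDIENT,PHENOLS,canopy,SINGLE,,,,2,,,3,1,,,3", "organ"),
            ("o1,s1,Sp,INGREDIENT,resins,root,SINGLE,,,,2,,,3,1,,,3", "compound"),
            ("o1,s1,Sp,INGREDIENT,,root,SINGLE,,,,2,,,3,1,,,3", "compound_class"),
            ("o1,s1,Sp,INGREDIENT,PHENOLS,root,SINGLE,,,,abc,,,3,1,,,3", "mean_t"),
            ("o1,s1,Sp,INGREDIENT,PHENOLS,root,SINGLE,,,,-2,,,3,1,,,3", "non-positive"),
            ("o1,,Sp,INGREDIENT,PHENOLS,root,SINGLE,,,,2,,,3,1,,,3", "study_id"),
        ],
    )
    def test_invalid_rows_rejected_with_reason(self, tmp_path, row, fragment):
        path = write(tmp_path, row + "\n")
        result = parse_observations(path)
        assert result.records == []
        assert len(result.rejections) == 1
        assert fragment in result.rejections[0].reason

    def test_every_row_accounted_for(self, tmp_path):
        body = (
            "o1,s1,Sp,INGREDIENT,PHENOLS,root,SINGLE,,,,2,0.2,SD,3,1,0.1,SD,3\n"
            "o2,s1,Sp,INGREDIENT,unknownclass,root,SINGLE,,,,2,,,3,1,,,3\n"
            "o3,,Sp,INGREDIENT,PHENOLS,root,SINGLE,,,,2,,,3,1,,,3\n"
            "o4,s2,Sp,GS,,leaf,MULTI,,,,3,0.3,SE,4,2,0.2,SE,4\n"
        )
        result = parse_observations(write(tmp_path, body))
        assert len(result.records) + len(result.rejections) == result.n_rows == 4

    def test_multi_inoculum_taxonomy_dropped_with_warning(self, tmp_path):
        path = write(
            tmp_path,
            "o1,s1,Sp,INGREDIENT,PHENOLS,root,MULTI,Glomerales,Glomeraceae,Glomus,"
            "2,0.2,SD,3,1,0.1,SD,3\n",
        )
        result = parse_observations(path)
        assert len(result.records) == 1
        assert result.records[0].amf_genus is None
        assert any("taxonomy" in w for w in result.warnings)

    def test_custom_dialect_column_names(self, tmp_path):
        cfg = IngestConfig()
        cfg.columns.update({"mean_t": "Xt", "mean_c": "Xc"})
        cfg.delimiter = ";"
        header = HEADER.replace(",", ";").replace("mean_t", "Xt").replace("mean_c", "Xc")
        body = "o1;s1;Sp;INGREDIENT;PHENOLS;root;SINGLE;;;;2;0.2;SD;3;1;0.1;SD;3\n"
        path = tmp_path / "t.csv"
        path.write_text(header + body)
        result = parse_observations(path, cfg)
        assert len(result.records) == 1
        assert result.records[0].treatment.mean == 2.0


class TestHarmonize:
    def test_se_converted_to_sd(self):
        arm = make_arm(mean=10, n=4, kind=DispersionKind.SE, value=0.2)
        out = harmonize_dispersion(arm)
        assert out.dispersion_kind is DispersionKind.SD
        assert out.dispersion_value == pytest.approx(0.4)

    def test_ci_only_imputed_as_tenth_of_mean(self):
        arm = make_arm(mean=5.0, n=4, kind=DispersionKind.CI95, value=1.3)
        out = harmonize_dispersion(arm)
        assert out.dispersion_value == pytest.approx(0.5)

    def test_no_dispersion_imputed_as_tenth_of_mean(self):
        arm = make_arm(mean=5.0, n=4, kind=DispersionKind.NONE)
        assert harmonize_dispersion(arm).dispersion_value == pytest.approx(0.5)

    def test_sd_passes_through(self):
        arm = make_arm(mean=3, n=5, kind=DispersionKind.SD, value=0.3)
        assert harmonize_dispersion(arm) == arm

    def test_ci_half_width_alternative(self):
        arm = make_arm(mean=5.0, n=4, kind=DispersionKind.CI95, value=0.98)
        out = harmonize_dispersion(arm, ci95_rule="half_width")
        assert out.dispersion_value == pytest.approx(0.98 * 2 / 1.959963984540054)

    def test_non_positive_mean_flagged(self):
        arm = ArmSummary(mean=0.0, n=3)
        with pytest.raises(NonAnalyzableError):
            harmonize_dispersion(arm)

    @given(
        mean=st.floats(0.01, 1e4),
        n=st.integers(1, 50),
        kind=st.sampled_from(list(DispersionKind)),
        value=st.floats(0, 100),
    )
    def test_idempotent(self, mean, n, kind, value):
        arm = make_arm(mean=mean, n=n, kind=kind, value=value)
        once = harmonize_dispersion(arm)
        assert harmonize_dispersion(once) == once
        assert once.dispersion_kind is DispersionKind.SD


def test_round_trip_write_then_parse(tmp_path):
    cfg = SyntheticConfig(n_studies=4, n_ingredient_obs=20, seed=7)
    records = generate_records(cfg)
    path = tmp_path / "rt.tsv"
    write_observations(records, path, delimiter="\t")
    reparsed = parse_observations(path, IngestConfig(delimiter="\t"))
    assert reparsed.rejections == []
    assert reparsed.records == records
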