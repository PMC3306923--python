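"""Input-record model, excretion-rate formula, imputation and the cascade."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

import spkdose as s
from spkdose.errors import DomainError, IntervalError, ParseError, ResolutionError


class TestComputeUer:
    def test_worked_example(self):
        rec = s.compute_uer(5.0, 0.2, t_p=21.0, t_c=31.0)
        assert rec.uer_avg == pytest.approx(0.1)
        assert rec.interval == 10.0

    def test_zero_concentration_gives_zero_rate(self):
        assert s.compute_uer(0.0, 0.4, 21.0, 31.0).uer_avg == 0.0

    def test_degenerate_interval_rejected(self):
        with pytest.raises(IntervalError):
            s.compute_uer(5.0, 0.2, 21.0, 21.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            s.compute_uer(-1.0, 0.2, 21.0, 31.0)

    @given(
        conc=st.floats(min_value=0.01, max_value=100.0),
        vol=st.floats(min_value=0.01, max_value=2.0),
        t_p=st.floats(min_value=0.0, max_value=40.0),
        width=st.floats(min_value=0.5, max_value=24.0),
    )
    def test_linear_in_concentration_and_volume(self, conc, vol, t_p, width):
        t_c = t_p + width
        base = s.compute_uer(conc, vol, t_p, t_c).uer_avg
        assert s.compute_uer(2 * conc, vol, t_p, t_c).uer_avg == pytest.approx(2 * base)
        assert s.compute_uer(conc, 2 * vol, t_p, t_c).uer_avg == pytest.approx(2 * base)
        halved = s.compute_uer(conc, vol, t_p, t_p + width / 2).uer_avg
        assert halved == pytest.approx(2 * base)


class TestImputeVoidInterval:
    def test_worked_example(self):
        assert s.impute_void_interval(150.0, 600.0) == pytest.approx(6.0)

    def test_identity_fraction_gives_full_day(self):
        assert s.impute_void_interval(600.0, 600.0) == 24.0

    def test_zero_volume_rejected(self):
        with pytest.raises(DomainError):
            s.impute_void_interval(0.0, 600.0)

    @given(st.floats(min_value=1.0, max_value=599.0), st.floats(min_value=1.0, max_value=300.0))
    def test_strictly_increasing_in_volume(self, v, dv):
        assert s.impute_void_interval(v + dv, 600.0) > s.impute_void_interval(v, 600.0)

    def test_clamp_caps_at_24_hours(self):
        assert s.clamp_interval(s.impute_void_interval(900.0, 600.0)) == 24.0
        assert s.clamp_interval(6.0) == 6.0


class TestResolveDefaults:
    def test_fully_measured_record_unchanged(self, complete_record, tables):
        resolved, subs = s.resolve_defaults(complete_record, 4, "f", tables)
        assert resolved == complete_record
        assert subs == []

    def test_missing_weight_filled_from_reference(self, complete_record, tables):
        rec = dataclasses.replace(complete_record, body_weight=None)
        resolved, subs = s.resolve_defaults(rec, 4, "f", tables)
        assert resolved.body_weight == tables.default_body_weight[(4, "f")]
        assert [x.field for x in subs] == ["body_weight"]
        assert subs[0].tier == "reference-default"

    def test_missing_times_imputed_from_volume(self, complete_record, tables):
        # 150 mL void, 600 mL/24h reference -> 6 h interval ending at the
        # slot's scheduled time (first-morning, 31 h)
        rec = dataclasses.replace(
            complete_record, t_p=None, t_c=None, volume=0.150, uer_avg=None
        )
        resolved, subs = s.resolve_defaults(rec, 5, "m", tables)  # v24 = 600 mL
        assert resolved.t_c == 31.0
        assert resolved.t_p == pytest.approx(25.0)
        assert resolved.t_c - resolved.t_p == pytest.approx(6.0)
        tiers = {x.field: x.tier for x in subs}
        assert tiers["t_c"] == "reference-default"
        assert tiers["t_p"] == "subject-derived"
        # the excretion rate is then recomputed from the raw observation
        assert resolved.uer_avg == pytest.approx(1.0 * 0.150 / 6.0)

    def test_missing_times_without_volume_use_schedule(self, complete_record, tables):
        rec = dataclasses.replace(
            complete_record, t_p=None, t_c=None, volume=None, concentration=None
        )
        resolved, subs = s.resolve_defaults(rec, 4, "f", tables)
        assert resolved.t_c == 31.0
        assert resolved.t_p == 21.0  # scheduled bedtime void precedes first-morning
        assert all(x.tier == "reference-default" for x in subs)

    def test_idempotent(self, complete_record, tables):
        rec = dataclasses.replace(complete_record, body_weight=None, t_p=None)
        once, _ = s.resolve_defaults(rec, 4, "f", tables)
        twice, subs = s.resolve_defaults(once, 4, "f", tables)
        assert twice == once
        assert subs == []

    def test_unfillable_record_names_the_field(self, complete_record, tables):
        rec = dataclasses.replace(
            complete_record, uer_avg=None, concentration=None, volume=None
        )
        with pytest.raises(ResolutionError) as exc:
            s.resolve_defaults(rec, 4, "f", tables)
        assert exc.value.field == "uer_avg"

    def test_unknown_age_fails_resolution(self, complete_record, tables):
        rec = dataclasses.replace(complete_record, body_weight=None)
        with pytest.raises(ResolutionError) as exc:
            s.resolve_defaults(rec, 12, "f", tables)
        assert exc.value.field == "body_weight"


# -- file round trip --------------------------------------------------------

finite_float = st.floats(min_value=0.001, max_value=1000.0, allow_nan=False)


@st.composite
def input_records(draw):
    t_p = draw(st.floats(min_value=0.0, max_value=40.0))
    t_c = t_p + draw(st.floats(min_value=0.25, max_value=24.0))
    return s.InputRecord(
        subject_id=str(draw(st.integers(min_value=1, max_value=999))),
        period=draw(st.sampled_from([s.Season.SUMMER, s.Season.FALL])),
        agricultural=draw(st.booleans()),
        route_code=draw(st.integers(min_value=3, max_value=7)),
        uer_avg=draw(st.one_of(st.none(), finite_float)),
        body_weight=draw(st.one_of(st.none(), finite_float)),
        exposure_start=19.0,
        exposure_end=None,
        t_p=t_p,
        t_c=t_c,
        concentration=draw(st.one_of(st.none(), finite_float)),
        volume=draw(st.one_of(st.none(), finite_float)),
    )


@given(st.lists(input_records(), min_size=1, max_size=6))
def test_write_read_round_trip_is_bit_exact(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("io") / "table.csv"
    s.write_input_table(records, path)
    assert s.read_input_table(path) == records


class TestReadInputTable:
    def test_id_period_parsing(self, complete_record, tmp_path):
        path = tmp_path / "t.csv"
        s.write_input_table([complete_record], path)
        [rec] = s.read_input_table(path)
        assert rec.subject_id == "114"
        assert rec.period == s.Season.SUMMER
        assert rec.label == "114.1"

    def test_malformed_row_reports_row_number(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "id_period,agricultural,uer_avg_mmol_per_hr,body_weight_kg,route_code,"
            "exposure_start_hr,exposure_end_hr,prev_void_hr,curr_void_hr\n"
            "114.1,1,0.0001,17,3,19,,21,31\n"
            "115.9,0,0.0001,17,3,19,,21,31\n"
        )
        with pytest.raises(ParseError) as exc:
            s.read_input_table(path)
        assert exc.value.row == 3

    def test_unknown_route_code_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "id_period,agricultural,uer_avg_mmol_per_hr,body_weight_kg,route_code,"
            "exposure_start_hr,exposure_end_hr,prev_void_hr,curr_void_hr\n"
            "114.1,1,0.0001,17,9,19,,21,31\n"
        )
        with pytest.raises(s.RouteCodeError):
            s.read_input_table(path)

    def test_slot_seven_accepted_as_unassigned_bolus(self, complete_record, tmp_path):
        rec = dataclasses.replace(complete_record, route_code=7)
        path = tmp_path / "t.csv"
        s.write_input_table([rec], path)
        [back] = s.read_input_table(path)
        assert back.route_code == int(s.Slot.UNASSIGNED)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("id_period,agricultural\n114.1,1\n")
        with pytest.raises(ParseError):
            s.read_input_table(path)


def test_reference_tables_yaml_round_trip(tables, tmp_path):
    path = tmp_path / "ref.yaml"
    tables.to_yaml(path)
    back = s.ReferenceTables.from_yaml(path)
    assert back == tables


def test_packaged_reference_tables_match_defaults(tables):
    from importlib import resources

    path = resources.files("spkdose.data").joinpath("reference_tables.yaml")
    with resources.as_file(path) as p:
        shipped = s.ReferenceTables.from_yaml(p)
    assert shipped == tables
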