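"""CSV IO, exclusion rules, law-language grouping, analysis plan."""

import datetime as dt

import pandas as pd
import pytest

import lawbend as lb
from lawbend.ingest import EXCLUSION_REASONS, ExclusionReport


def _event(**overrides):
    base = {
        "state": "IA",
        "injury_date": dt.date(2011, 10, 5),
        "classification": "incident",
        "injury_type": "concussion",
        "recurrent_mechanism_sport": None,
        "ae_linked": True,
    }
    base.update(overrides)
    return base


class TestReadWrite:
    def test_round_trip_of_simulated_records(self, tmp_path):
        cfg = lb.SimulationConfig(n_states=4, stdm_range=(-12, 12), tau1=-6,
                                  tau2=6, seed=17)
        events, exposures, laws = lb.simulate_raw_records(cfg)
        lb.write_surveillance_csv(events, exposures, tmp_path / "e.csv", tmp_path / "x.csv")
        lb.write_law_csv(laws, tmp_path / "l.csv")
        ev, ex = lb.read_surveillance_csv(tmp_path / "e.csv", tmp_path / "x.csv")
        laws2 = lb.read_law_csv(tmp_path / "l.csv")
        assert len(ev) == len(events)
        assert list(ev["state"]) == list(events["state"])
        assert list(ev["injury_date"]) == list(events["injury_date"])
        assert list(ev["classification"]) == list(events["classification"])
        pd.testing.assert_frame_equal(
            ex, exposures, check_dtype=False, check_exact=False
        )
        assert list(laws2["passage_date"]) == list(laws["passage_date"])

    def test_empty_data_sections(self, tmp_path):
        (tmp_path / "e.csv").write_text(
            "state,injury_date,classification,injury_type,recurrent_mechanism_sport\n"
        )
        (tmp_path / "x.csv").write_text(
            "state,academic_year,exposure_week,athlete_exposures\n"
        )
        ev, ex = lb.read_surveillance_csv(tmp_path / "e.csv", tmp_path / "x.csv")
        assert len(ev) == 0 and len(ex) == 0

    def test_malformed_date_becomes_null_not_default(self, tmp_path):
        (tmp_path / "e.csv").write_text(
            "state,injury_date,classification,injury_type,recurrent_mechanism_sport\n"
            "IA,2011-10-05,incident,concussion,\n"
            "IA,not-a-date,incident,concussion,\n"
        )
        (tmp_path / "x.csv").write_text(
            "state,academic_year,exposure_week,athlete_exposures\n"
        )
        ev, _ = lb.read_surveillance_csv(tmp_path / "e.csv", tmp_path / "x.csv")
        assert ev["injury_date"].iloc[0] == dt.date(2011, 10, 5)
        assert ev["injury_date"].iloc[1] is None

    def test_missing_columns_listed_in_error(self, tmp_path):
        (tmp_path / "e.csv").write_text("state,injury_date\nIA,2011-10-05\n")
        (tmp_path / "x.csv").write_text(
            "state,academic_year,exposure_week,athlete_exposures\n"
        )
        with pytest.raises(ValueError, match="classification"):
            lb.read_surveillance_csv(tmp_path / "e.csv", tmp_path / "x.csv")

    def test_exposure_week_out_of_range_rejected(self, tmp_path):
        (tmp_path / "e.csv").write_text(
            "state,injury_date,classification,injury_type,recurrent_mechanism_sport\n"
        )
        (tmp_path / "x.csv").write_text(
            "state,academic_year,exposure_week,athlete_exposures\nIA,2011,53,10\n"
        )
        with pytest.raises(ValueError, match="exposure_week"):
            lb.read_surveillance_csv(tmp_path / "e.csv", tmp_path / "x.csv")


class TestApplyExclusions:
    def test_constructed_fixture_counts(self):
        # 10 records: 2 missing date, 1 type=other, 1 recurrent non-sport.
        records = pd.DataFrame(
            [
                _event(),
                _event(injury_date=None),
                _event(injury_date=None),
                _event(injury_type="other"),
                _event(classification="recurrent", recurrent_mechanism_sport=False),
                _event(classification="recurrent", recurrent_mechanism_sport=True),
                _event(),
                _event(),
                _event(),
                _event(),
            ]
        )
        kept, report = lb.apply_exclusions(records)
        assert (report.n_kept, report.n_excluded) == (6, 4)
        assert report.reasons["missing_date"] == 2
        assert report.reasons["type_other"] == 1
        assert report.reasons["recurrent_nonsport"] == 1

    def test_multiply_flawed_record_counted_once_overall(self):
        records = pd.DataFrame([_event(injury_date=None, state=None)])
        _, report = lb.apply_exclusions(records)
        assert report.n_excluded == 1
        assert report.reasons["missing_date"] == 1
        assert report.reasons["missing_state"] == 1
        assert sum(report.reasons.values()) >= report.n_excluded

    def test_clean_fixture_excludes_nothing(self):
        records = pd.DataFrame([_event() for _ in range(5)])
        kept, report = lb.apply_exclusions(records)
        assert report.n_excluded == 0 and len(kept) == 5

    def test_conservation_and_idempotence(self):
        records = pd.DataFrame(
            [_event(), _event(injury_date=None), _event(classification="unknown"),
             _event(ae_linked=False), _event(injury_type="unknown")]
        )
        kept, report = lb.apply_exclusions(records)
        assert report.n_kept + report.n_excluded == report.n_input
        kept2, report2 = lb.apply_exclusions(kept)
        assert report2.n_excluded == 0
        assert len(kept2) == len(kept)

    def test_all_reasons_reported(self):
        _, report = lb.apply_exclusions(pd.DataFrame([_event()]))
        assert set(report.reasons) == set(EXCLUSION_REASONS)

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError):
            ExclusionReport(n_input=10, n_kept=5, n_excluded=4)


def _law(state, rtp, breadth, education, date="2011-07-01"):
    return {
        "state": state,
        "passage_date": dt.date.fromisoformat(date),
        "rtp_provider": rtp,
        "provider_breadth": breadth,
        "education": education,
    }


class TestClassifyStates:
    def test_landmark_states(self):
        # Rhode Island: physicians-only RTP clearance, education for both;
        # Iowa: athletic trainers may clear, so multiple categories;
        # Illinois: no clearance requirement at passage, grouped with
        # not-specified.
        laws = pd.DataFrame(
            [
                _law("RI", "specified", "physicians_only", "both"),
                _law("IA", "specified", "multiple", "both"),
                _law("IL", "not_specified", "not_applicable", "both"),
            ]
        )
        cls = lb.classify_states(laws).set_index("state")
        assert tuple(cls.loc["RI"]) == ("specified", "physicians_only", "both")
        assert tuple(cls.loc["IA"]) == ("specified", "multiple", "both")
        assert tuple(cls.loc["IL"]) == ("not_specified", "not_applicable", "both")

    def test_group_sizes_partition_states(self):
        cfg = lb.SimulationConfig(n_states=51, seed=1)
        _, laws = lb.simulate_surveillance(cfg)
        cls = lb.classify_states(laws)
        sizes = cls.attrs["group_sizes"]
        assert sum(sizes["rtp_group"].values()) == 51
        assert sum(sizes["education_group"].values()) == 51
        assert sum(sizes["breadth_group"].values()) == sizes["rtp_group"]["specified"]

    def test_duplicate_state_rejected(self):
        laws = pd.DataFrame(
            [_law("IA", "specified", "multiple", "both"),
             _law("IA", "specified", "multiple", "both")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            lb.classify_states(laws)

    def test_inconsistent_breadth_rejected(self):
        laws = pd.DataFrame([_law("IA", "specified", "not_applicable", "both")])
        with pytest.raises(ValueError, match="not_applicable"):
            lb.classify_states(laws)

    def test_education_neither_rejected(self):
        laws = pd.DataFrame([_law("IA", "specified", "multiple", "neither")])
        with pytest.raises(ValueError, match="education"):
            lb.classify_states(laws)


class TestModelPlan:
    def test_plan_has_fourteen_models(self):
        assert len(lb.enumerate_model_plan()) == 14

    def test_overall_pair_and_stratified_quads(self):
        plan = lb.enumerate_model_plan()
        overall = [m for m in plan if m.dimension == "overall"]
        assert sorted(m.classification for m in overall) == ["incident", "recurrent"]
        for dim in ("rtp_group", "breadth_group", "education_group"):
            sub = [m for m in plan if m.dimension == dim]
            assert len(sub) == 4
            assert len({(m.group, m.classification) for m in sub}) == 4

    def test_specs_select_their_stratum(self):
        cfg = lb.SimulationConfig(n_states=20, stdm_range=(-12, 12), tau1=-6,
                                  tau2=6, seed=9)
        cells, _ = lb.simulate_surveillance(cfg)
        for spec in lb.enumerate_model_plan():
            sub = spec.select(cells)
            assert (sub["classification"] == spec.classification).all()
            if spec.group is not None:
                assert (sub[spec.dimension] == spec.group).all()
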