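"""Rules engine: SIRS, organ dysfunction, screen-in, attribution, presets."""

import pandas as pd
import pytest

from sepscreen import (
    EncounterRecord,
    ObservationEvent,
    PRESET_NAMES,
    attribute_class,
    baseline_sbp,
    eval_organ_dysfunction,
    eval_sirs,
    preset,
    resolve_timeline,
    screen_encounter,
)

T0 = pd.Timestamp("2016-05-01 12:00")
SEP2 = preset("sep2_based")
NEAR = preset("near_sep2")
CONS = preset("conservative")


def tl(*triples, eid="E1"):
    """timeline from (concept, value, hours-relative-to-T0) triples"""
    return resolve_timeline(
        [ObservationEvent(eid, c, v, T0 + pd.Timedelta(hours=h)) for c, v, h in triples]
    )


class TestPresets:
    def test_three_presets_load(self):
        assert [preset(n).name for n in PRESET_NAMES] == list(PRESET_NAMES)

    def test_near_sep2_differs_only_in_sbp_drop(self):
        a, b = SEP2.to_dict(), NEAR.to_dict()
        diff = {k for k in a if a[k] != b[k]}
        assert diff == {"name", "sbp_drop_enabled"}
        assert b["sbp_drop_enabled"] is False

    def test_conservative_restrictions(self):
        assert CONS.sbp_drop_enabled is False
        assert CONS.creatinine_delta_required is True
        assert CONS.bilirubin_cap_mg_dL == 10.0
        assert CONS.platelets_inr_enabled is False

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("sep3")


class TestSirs:
    def test_two_criteria_met(self):
        timeline = tl(("temperature_C", 39.0, -1), ("heart_rate_bpm", 95, -2),
                      ("resp_rate_bpm", 16, -1), ("wbc_per_mm3", 9000, -3))
        assert eval_sirs(timeline, T0, SEP2) == {"temperature", "heart_rate"}

    def test_absent_data_meets_nothing(self):
        assert eval_sirs(tl(), T0, SEP2) == set()

    @pytest.mark.parametrize(
        "concept,value,expected",
        [
            ("temperature_C", 38.3, set()),          # strict >38.3
            ("temperature_C", 36.0, set()),          # strict <36.0
            ("temperature_C", 35.9, {"temperature"}),
            ("heart_rate_bpm", 90, set()),           # strict >90
            ("heart_rate_bpm", 91, {"heart_rate"}),
            ("resp_rate_bpm", 20, set()),
            ("resp_rate_bpm", 21, {"resp_rate"}),
            ("wbc_per_mm3", 12000, set()),
            ("wbc_per_mm3", 12001, {"wbc"}),
            ("wbc_per_mm3", 4000, set()),
            ("wbc_per_mm3", 3999, {"wbc"}),
            ("band_pct", 10.0, set()),
            ("band_pct", 10.5, {"wbc"}),
        ],
    )
    def test_thresholds_are_strict(self, concept, value, expected):
        assert eval_sirs(tl((concept, value, -1)), T0, SEP2) == expected

    def test_value_outside_30h_lookback_ignored(self):
        assert eval_sirs(tl(("temperature_C", 39.5, -31)), T0, SEP2) == set()


class TestBaselineSbp:
    def test_earliest_reading_in_window(self):
        timeline = tl(("sbp_mmHg", 150, -20), ("sbp_mmHg", 100, -1))
        assert baseline_sbp(timeline, T0) == 150

    def test_single_reading_is_its_own_baseline(self):
        assert baseline_sbp(tl(("sbp_mmHg", 132, -5)), T0) == 132

    def test_absent_outside_window(self):
        assert baseline_sbp(tl(("sbp_mmHg", 150, -31)), T0) is None


class TestOrganDysfunction:
    def test_sbp_drop_scenario_dependence(self):
        timeline = tl(("sbp_mmHg", 150, -20), ("sbp_mmHg", 105, -1))
        assert eval_organ_dysfunction(timeline, T0, SEP2) == {"sbp_drop"}
        assert eval_organ_dysfunction(timeline, T0, NEAR) == set()

    def test_sbp_drop_of_exactly_40_does_not_trigger(self):
        timeline = tl(("sbp_mmHg", 150, -20), ("sbp_mmHg", 110, -1))
        assert eval_organ_dysfunction(timeline, T0, SEP2) == set()

    def test_lactate_12h_lookback(self):
        assert eval_organ_dysfunction(tl(("lactate_mmol_L", 2.5, -10)), T0, SEP2) == {"lactate"}
        assert eval_organ_dysfunction(tl(("lactate_mmol_L", 2.5, -13)), T0, SEP2) == set()

    def test_bilirubin_cap_under_conservative(self):
        timeline = tl(("bilirubin_mg_dL", 12.0, -1))
        assert eval_organ_dysfunction(timeline, T0, SEP2) == {"bilirubin"}
        assert eval_organ_dysfunction(timeline, T0, CONS) == set()

    def test_creatinine_needs_rise_under_conservative(self):
        flat_high = tl(("creatinine_mg_dL", 2.3, -50), ("creatinine_mg_dL", 2.4, -1))
        rising = tl(("creatinine_mg_dL", 1.2, -50), ("creatinine_mg_dL", 2.4, -1))
        assert eval_organ_dysfunction(flat_high, T0, SEP2) == {"creatinine"}
        assert eval_organ_dysfunction(flat_high, T0, CONS) == set()
        assert eval_organ_dysfunction(rising, T0, CONS) == {"creatinine"}

    def test_creatinine_rise_must_precede_high_value(self):
        # falls from high to low: no rise ending at the qualifying value
        falling = tl(("creatinine_mg_dL", 2.4, -50), ("creatinine_mg_dL", 1.2, -1))
        assert eval_organ_dysfunction(falling, T0, CONS) == set()

    def test_platelets_inr_eliminated_under_conservative(self):
        timeline = tl(("platelets_per_uL", 60_000, -1), ("inr", 2.0, -2))
        assert eval_organ_dysfunction(timeline, T0, SEP2) == {"platelets", "inr"}
        assert eval_organ_dysfunction(timeline, T0, CONS) == set()

    @pytest.mark.parametrize(
        "concept,value,expected",
        [
            ("sbp_mmHg", 90, set()),                   # strict <90
            ("sbp_mmHg", 89, {"sbp_or_map"}),
            ("map_mmHg", 65, set()),
            ("map_mmHg", 64, {"sbp_or_map"}),
            ("lactate_mmol_L", 2.0, set()),            # strict >2.0
            ("lactate_mmol_L", 2.1, {"lactate"}),
            ("bilirubin_mg_dL", 2.0, {"bilirubin"}),   # inclusive >=2.0
            ("bilirubin_mg_dL", 1.9, set()),
            ("creatinine_mg_dL", 2.0, {"creatinine"}),  # inclusive >=2.0
            ("creatinine_mg_dL", 1.9, set()),
            ("platelets_per_uL", 100_000, set()),      # strict <100000
            ("platelets_per_uL", 99_000, {"platelets"}),
            ("inr", 1.5, set()),                       # strict >1.5
            ("inr", 1.6, {"inr"}),
        ],
    )
    def test_threshold_edge_cases(self, concept, value, expected):
        assert eval_organ_dysfunction(tl((concept, value, -1)), T0, SEP2) == expected


class TestAttribution:
    def test_two_systems_is_mods(self):
        assert attribute_class({"lactate", "creatinine"}) == "mods"

    def test_cardiovascular_precedence(self):
        assert attribute_class({"sbp_drop", "lactate"}) == "sbp_drop"
        assert attribute_class({"sbp_or_map", "lactate"}) == "sbp_or_map"

    def test_hematologic_precedence(self):
        assert attribute_class({"platelets", "inr"}) == "platelets"

    def test_singleton(self):
        assert attribute_class({"bilirubin"}) == "bilirubin"

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            attribute_class(set())


class TestScreenEncounter:
    ENC = EncounterRecord("E1", 70, "female", T0 - pd.Timedelta(hours=24),
                          T0 + pd.Timedelta(hours=48), "home_or_other")

    def test_sirs_without_organ_never_flags(self):
        timeline = tl(("temperature_C", 39.5, 0), ("heart_rate_bpm", 120, 0.2))
        result = screen_encounter(self.ENC, timeline, SEP2)
        assert not result.flagged
        assert result.first_alert_time is None and result.attributed_class is None

    def test_organ_without_sirs_never_flags(self):
        result = screen_encounter(self.ENC, tl(("lactate_mmol_L", 4.0, 0)), SEP2)
        assert not result.flagged

    def test_first_joint_instant_is_alert_time(self):
        timeline = tl(
            ("temperature_C", 39.0, 0),
            ("heart_rate_bpm", 120, 1),
            ("lactate_mmol_L", 3.0, 5),
            ("lactate_mmol_L", 4.0, 9),
        )
        result = screen_encounter(self.ENC, timeline, SEP2)
        assert result.flagged
        assert result.first_alert_time == T0 + pd.Timedelta(hours=5)
        assert result.sirs_criteria_met == {"temperature", "heart_rate"}
        assert result.attributed_class == "lactate"

    def test_events_outside_stay_do_not_evaluate(self):
        enc = EncounterRecord("E1", 70, "female", T0, T0 + pd.Timedelta(hours=4),
                              "home_or_other")
        timeline = tl(("temperature_C", 39.0, 6), ("heart_rate_bpm", 120, 6),
                      ("lactate_mmol_L", 3.0, 6))
        assert not screen_encounter(enc, timeline, SEP2).flagged


class TestWorkedExampleScreening:
    def test_lactate_case_flagged_under_all_presets(self, worked_alerts):
        for name in PRESET_NAMES:
            row = worked_alerts[name].set_index("encounter_id").loc["W03"]
            assert row["flagged"] and row["attributed_class"] == "lactate"

    def test_sbp_drop_case_only_under_sep2(self, worked_alerts):
        assert worked_alerts["sep2_based"].set_index("encounter_id").loc["W01", "flagged"]
        assert not worked_alerts["near_sep2"].set_index("encounter_id").loc["W01", "flagged"]

    def test_mods_case_attributed_mods_everywhere(self, worked_alerts):
        for name in PRESET_NAMES:
            row = worked_alerts[name].set_index("encounter_id").loc["W08"]
            assert row["flagged"] and row["attributed_class"] == "mods"

    def test_controls_flagged_by_no_scenario(self, worked_alerts):
        for name in PRESET_NAMES:
            sub = worked_alerts[name].set_index("encounter_id")
            for eid in ("W09", "W10", "W11", "W12"):
                assert not sub.loc[eid, "flagged"]

    def test_nesting_on_worked_example(self, worked_alerts):
        def flagged(name):
            a = worked_alerts[name]
            return set(a.loc[a["flagged"], "encounter_id"])

        assert flagged("conservative") <= flagged("near_sep2") <= flagged("sep2_based")

    def test_attribution_partitions_flagged(self, worked_alerts):
        for name in PRESET_NAMES:
            a = worked_alerts[name]
            fl = a.loc[a["flagged"]]
            assert fl["attributed_class"].notna().all()
            assert fl["attributed_class"].value_counts().sum() == len(fl)
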