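"""Synthetic cohort generator: determinism, planted structure, update noise."""

import numpy as np
import pandas as pd
import pytest

from sepscreen import (
    CohortSpec,
    GroundTruth,
    generate_cohort,
    label_cohort,
    plant_update_noise,
    preset,
    resolve_cohort,
    screen_cohort,
)
from sepscreen.concepts import LAB_CONCEPTS


class TestSpecValidation:
    def test_zero_encounters_is_hard_error(self):
        with pytest.raises(ValueError):
            CohortSpec(n_encounters=0)

    def test_proportions_bounded(self):
        with pytest.raises(ValueError):
            CohortSpec(n_encounters=10, frac_septic_physiology=1.2)

    def test_odds_multipliers_positive(self):
        with pytest.raises(ValueError):
            CohortSpec(n_encounters=10, mortality_or_per_parameter={"lactate": 0.0})

    def test_ground_truth_invariant(self):
        with pytest.raises(ValueError):
            GroundTruth("E1", septic_profile=True, planted_parameters=frozenset(),
                        infected=False, died_or_hospice=False)


class TestDeterminism:
    def test_same_seed_same_tables(self):
        spec = CohortSpec(n_encounters=80, seed=42)
        a, ta = generate_cohort(spec)
        b, tb = generate_cohort(spec)
        for name in ("encounters", "observations", "cultures", "med_admins"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seed_different_tables(self):
        a, _ = generate_cohort(CohortSpec(n_encounters=40, seed=1))
        b, _ = generate_cohort(CohortSpec(n_encounters=40, seed=2))
        assert not a.observations.equals(b.observations)

    def test_update_rate_does_not_perturb_base_draws(self):
        clean, t1 = generate_cohort(CohortSpec(n_encounters=40, seed=5, update_rate=0.0))
        noisy, t2 = generate_cohort(CohortSpec(n_encounters=40, seed=5, update_rate=0.5))
        pd.testing.assert_frame_equal(t1, t2)
        base = noisy.observations.loc[noisy.observations["update_seq"] == 0]
        # every (concept, time) key of the clean stream is present in the base
        key = ["encounter_id", "concept", "event_time"]
        pd.testing.assert_frame_equal(
            clean.observations[key].sort_values(key).reset_index(drop=True),
            base[key].sort_values(key).reset_index(drop=True),
        )


class TestPlantedStructure:
    def test_no_septic_physiology_no_flags(self):
        cohort, _ = generate_cohort(CohortSpec(n_encounters=60, seed=3,
                                               frac_septic_physiology=0.0))
        alerts = screen_cohort(cohort, preset("sep2_based"))
        assert not alerts["flagged"].any()

    def test_all_septic_lactate_only_all_attributed_lactate(self):
        spec = CohortSpec(
            n_encounters=40, seed=4, frac_septic_physiology=1.0,
            frac_multi_organ=0.0, class_weights={"lactate": 1.0},
        )
        cohort, _ = generate_cohort(spec)
        alerts = screen_cohort(cohort, preset("sep2_based"))
        assert alerts["flagged"].all()
        assert (alerts["attributed_class"] == "lactate").all()

    def test_label_recovery_on_small_cohort(self):
        cohort, truth = generate_cohort(CohortSpec(n_encounters=300, seed=6))
        alerts = screen_cohort(cohort, preset("sep2_based"))
        m = alerts.merge(truth, on="encounter_id")
        assert (m["flagged"] == m["septic_profile"]).all()
        flagged = m.loc[m["flagged"]]
        assert (flagged["attributed_class"] == flagged["truth_class"]).all()

    def test_infection_labels_follow_ground_truth(self):
        cohort, truth = generate_cohort(CohortSpec(n_encounters=200, seed=8))
        labels = label_cohort(cohort).set_index("encounter_id")
        expect = truth.set_index("encounter_id")
        assert (labels["suspected_infection"] == expect["infected"]).all()
        assert (labels["died_or_hospice"] == expect["died_or_hospice"]).all()


class TestUpdateNoise:
    def test_rate_zero_is_identity(self):
        cohort, _ = generate_cohort(CohortSpec(n_encounters=30, seed=9, update_rate=0.0))
        spec = CohortSpec(n_encounters=30, seed=9, update_rate=0.0)
        out = plant_update_noise(cohort.observations, spec)
        pd.testing.assert_frame_equal(out, cohort.observations)

    def test_rate_one_doubles_every_lab_event(self):
        cohort, _ = generate_cohort(CohortSpec(n_encounters=30, seed=10, update_rate=1.0))
        obs = cohort.observations
        labs = obs.loc[obs["concept"].isin(LAB_CONCEPTS)]
        versions = labs.groupby(["encounter_id", "concept", "event_time"])["update_seq"].agg(
            ["count", "max"]
        )
        assert (versions["count"] == 2).all()
        assert (versions["max"] == 1).all()

    def test_corrected_value_is_the_truth_consistent_one(self):
        noisy, truth = generate_cohort(CohortSpec(n_encounters=150, seed=12, update_rate=0.6))
        clean, _ = generate_cohort(CohortSpec(n_encounters=150, seed=12, update_rate=0.0))
        noisy_alerts = screen_cohort(noisy, preset("sep2_based"))
        clean_alerts = screen_cohort(clean, preset("sep2_based"))
        pd.testing.assert_frame_equal(noisy_alerts, clean_alerts)


class TestDemographics:
    def test_age_distribution_anchors(self):
        _, _ = generate_cohort(CohortSpec(n_encounters=1, seed=0))  # smoke
        cohort, _ = generate_cohort(CohortSpec(n_encounters=2000, seed=13))
        ages = cohort.encounters["age_years"]
        assert ages.min() >= 18
        assert 60 <= ages.median() <= 70
        q1, q3 = ages.quantile([0.25, 0.75])
        assert 45 <= q1 <= 58 and 70 <= q3 <= 82

    def test_los_median_near_spec(self):
        cohort, _ = generate_cohort(CohortSpec(n_encounters=1000, seed=14))
        los = (cohort.encounters["discharge_time"] - cohort.encounters["admit_time"]).dt.total_seconds() / 86400
        assert 3.0 <= los.median() <= 5.5
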