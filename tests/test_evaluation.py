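"""Evaluation layer: metrics identities, Woolf ORs, logistic fits, report."""

import math

import numpy as np
import pandas as pd
import pytest

from sepscreen import (
    build_report,
    crude_odds_ratio,
    evaluate_scenario,
    fit_mortality_model,
    substitution_analysis,
)


def make_alerts(flagged_ids, classes, scenario, universe):
    cls_map = dict(zip(flagged_ids, classes))
    df = pd.DataFrame(
        {
            "encounter_id": universe,
            "flagged": [e in cls_map for e in universe],
            "first_alert_time": pd.NaT,
            "sirs_met": "",
            "organ_met": "",
            "attributed_class": [cls_map.get(e) for e in universe],
        }
    )
    df.attrs["scenario"] = scenario
    return df


def make_labels(universe, infected, measured=(), died=()):
    return pd.DataFrame(
        {
            "encounter_id": universe,
            "suspected_infection": [e in set(infected) for e in universe],
            "lactate_measured": [e in set(measured) for e in universe],
            "died_or_hospice": [e in set(died) for e in universe],
        }
    )


class TestCrudeOddsRatio:
    def test_symmetry_gives_unity(self):
        or_, lo, hi = crude_odds_ratio(20, 80, 40, 160)
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_continuity_correction(self):
        or_, lo, hi = crude_odds_ratio(0, 10, 5, 5)
        assert 0 < or_ < 1 and 0 < lo < hi

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            crude_odds_ratio(-1, 2, 3, 4)


class TestEvaluateScenario:
    def test_identity_with_reference(self):
        ids = [f"P{i}" for i in range(50)]
        alerts = make_alerts(ids[:20], ["lactate"] * 20, "ref", ids)
        labels = make_labels(ids, infected=ids[:10])
        ev = evaluate_scenario(alerts, labels, alerts)
        assert ev.sensitivity == 1.0
        assert ev.relative_change_vs_reference == 0.0
        assert ev.ppv == pytest.approx(0.5)

    def test_zero_flagged_ppv_absent_not_zero(self):
        ids = [f"P{i}" for i in range(10)]
        alerts = make_alerts([], [], "empty", ids)
        ref = make_alerts(ids[:4], ["inr"] * 4, "ref", ids)
        labels = make_labels(ids, infected=ids[:4])
        ev = evaluate_scenario(alerts, labels, ref)
        assert ev.ppv is None
        assert ev.sensitivity == 0.0

    def test_per_class_counts_partition_flagged(self):
        ids = [f"P{i}" for i in range(30)]
        classes = ["lactate"] * 5 + ["mods"] * 3 + ["inr"] * 2
        alerts = make_alerts(ids[:10], classes, "s", ids)
        labels = make_labels(ids, infected=ids[:6])
        ev = evaluate_scenario(alerts, labels, alerts)
        assert ev.per_class["n_flagged"].sum() == ev.n_flagged

    def test_mismatched_cohorts_rejected(self):
        a = make_alerts(["A"], ["lactate"], "s", ["A"])
        labels = make_labels(["A", "B"], infected=[])
        with pytest.raises(ValueError):
            evaluate_scenario(a, labels, a)


class TestSubstitution:
    def test_identical_death_rates_give_unit_or(self):
        ids = [f"P{i}" for i in range(200)]
        a = make_alerts(ids, ["lactate"] * 200, "ref", ids)
        classes_b = ["creatinine"] * 100 + ["lactate"] * 100
        b = make_alerts(ids, classes_b, "cmp", ids)
        died = ids[:20] + ids[100:120]  # 20% in both groups
        labels = make_labels(ids, infected=ids, died=died)
        sub = substitution_analysis(a, b, labels)
        assert sub.n_dual_membership == 200
        assert sub.n_reclassified == 100
        assert sub.crude_or == pytest.approx(1.0)

    def test_restricted_to_infected_dual_members(self):
        ids = [f"P{i}" for i in range(10)]
        a = make_alerts(ids[:8], ["lactate"] * 8, "ref", ids)
        b = make_alerts(ids[:5], ["inr"] * 5, "cmp", ids)
        labels = make_labels(ids, infected=ids[:4])
        sub = substitution_analysis(a, b, labels)
        assert sub.n_dual_membership == 4
        assert sub.n_reclassified == 4
        assert sub.reclass_distribution == {"inr": 1.0}


def logistic_patients(rng, n, p_exposed, beta0, beta1):
    exposed = rng.random(n) < p_exposed
    logit = beta0 + beta1 * exposed
    died = rng.random(n) < 1 / (1 + np.exp(-logit))
    return pd.DataFrame(
        {
            "encounter_id": [f"P{i}" for i in range(n)],
            "attributed_class": np.where(exposed, "lactate", "inr"),
            "died_or_hospice": died,
        }
    )


class TestMortalityModel:
    def test_unadjusted_fit_equals_closed_form_crude_or(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            df = logistic_patients(rng, 400, 0.4, -1.5, 0.6)
            t = pd.crosstab(df["attributed_class"] == "lactate", df["died_or_hospice"])
            if (t.to_numpy() == 0).any():
                continue
            a, b = int(t.loc[True, True]), int(t.loc[True, False])
            c, d = int(t.loc[False, True]), int(t.loc[False, False])
            closed_form = (a / b) / (c / d)
            res = fit_mortality_model(df, "lactate", adjusted=False)
            assert res.converged
            assert abs(res.adjusted_or - closed_form) < 1e-6

    def test_null_effect_ci_coverage(self):
        rng = np.random.default_rng(2024)
        covered = 0
        for _ in range(100):
            df = logistic_patients(rng, 500, 0.5, -1.2, 0.0)
            res = fit_mortality_model(df, "lactate", adjusted=False)
            if res.converged and res.ci_low <= 1.0 <= res.ci_high:
                covered += 1
        assert covered >= 93

    def test_separation_reported_not_silent(self):
        df = pd.DataFrame(
            {
                "encounter_id": [f"P{i}" for i in range(40)],
                "attributed_class": ["lactate"] * 20 + ["inr"] * 20,
                "died_or_hospice": [True] * 20 + [False] * 20,
            }
        )
        res = fit_mortality_model(df, "lactate", adjusted=False)
        assert not res.converged
        assert res.adjusted_or is None and res.message

    def test_no_contrast_reported(self):
        df = pd.DataFrame(
            {
                "encounter_id": ["P1", "P2"],
                "attributed_class": ["lactate", "lactate"],
                "died_or_hospice": [True, False],
            }
        )
        res = fit_mortality_model(df, "lactate", adjusted=False)
        assert not res.converged


class TestReport:
    def _inputs(self):
        ids = [f"P{i}" for i in range(30)]
        alerts = make_alerts(ids[:10], ["lactate"] * 6 + ["mods"] * 4, "sep2_based", ids)
        labels = make_labels(ids, infected=ids[:8], died=ids[:3])
        ev = evaluate_scenario(alerts, labels, alerts)
        sub = substitution_analysis(alerts, alerts, labels)
        rng = np.random.default_rng(7)
        model = fit_mortality_model(logistic_patients(rng, 300, 0.5, -1.0, 0.5),
                                    "lactate", "sep2_based", adjusted=False)
        return [ev], [sub], [model]

    def test_tables_written_and_deterministic(self, tmp_path):
        evs, subs, models = self._inputs()
        build_report(evs, subs, models, tmp_path / "a")
        build_report(evs, subs, models, tmp_path / "b")
        for name in ("scenario_metrics.csv", "attribution_table.csv",
                     "substitution.csv", "mortality_models.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert (tmp_path / "a" / "forest.svg").exists()

    def test_no_alerts_section_on_empty_cohort(self, tmp_path):
        ids = ["P1", "P2"]
        alerts = make_alerts([], [], "sep2_based", ids)
        labels = make_labels(ids, infected=[])
        ev = evaluate_scenario(alerts, labels, alerts)
        build_report([ev], [], [], tmp_path)
        assert (tmp_path / "NO_ALERTS.txt").exists()
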