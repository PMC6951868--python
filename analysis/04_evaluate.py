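#!/usr/bin/env python
"""Evaluate the scenario trade-off, substitution effects and mortality risk.

Reads the alert, infection and acuity tables, computes per-scenario PPV
and sensitivity against the sep2_based reference, the attribution table,
the cross-scenario substitution analyses with crude odds ratios, and one
adjusted logistic mortality model per attributed class and scenario.
Writes the report bundle (CSV tables + forest plot) under results/report/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sepscreen import (
    PRESET_NAMES,
    build_report,
    evaluate_scenario,
    mortality_models,
    read_cohort,
    substitution_analysis,
)


def read_alerts(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str}, parse_dates=["first_alert_time"])
    df.attrs["scenario"] = name
    return df


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()

    cohort = read_cohort(args.results / "cohort")
    labels = pd.read_csv(args.results / "infection.csv", dtype={"encounter_id": str})
    acuity = pd.read_csv(args.results / "acuity.csv", dtype={"encounter_id": str})
    alerts = {
        name: read_alerts(args.results / f"alerts_{name}.csv", name) for name in PRESET_NAMES
    }
    ref = alerts["sep2_based"]

    evaluations, substitutions, models = [], [], []
    for name in PRESET_NAMES:
        ev = evaluate_scenario(alerts[name], labels, ref)
        evaluations.append(ev)
        print(
            f"{name}: flagged {ev.n_flagged}, PPV {100 * ev.ppv:.0f}%, "
            f"sensitivity {100 * ev.sensitivity:.0f}%"
        )
        if name != "sep2_based":
            sub = substitution_analysis(ref, alerts[name], labels)
            substitutions.append(sub)
            if sub.crude_or is not None:
                print(
                    f"  substitution vs reference: {sub.n_reclassified}/{sub.n_dual_membership} "
                    f"reclassified, mortality OR {sub.crude_or:.2f} "
                    f"({sub.ci_low:.2f}-{sub.ci_high:.2f})"
                )
        patients = (
            alerts[name].loc[alerts[name]["flagged"]]
            .merge(labels, on="encounter_id")
            .merge(acuity, on="encounter_id")
            .merge(cohort.encounters[["encounter_id", "age_years", "sex"]], on="encounter_id")
        )
        patients = patients.loc[patients["suspected_infection"]]
        models.extend(mortality_models(patients, name))

    build_report(evaluations, substitutions, models, args.out)
    print(f"report bundle written to {args.out}")


if __name__ == "__main__":
    main()
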