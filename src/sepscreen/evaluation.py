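"""Cohort-level evaluation of surveillance scenarios.

Three analyses over the per-encounter alert and label tables:

* **Reliability / sensitivity.**  Alert reliability is PPV on suspected
  infection: the fraction of flagged encounters with a qualifying culture
  plus IV anti-infective.  There is no gold-standard sepsis adjudication,
  so condition sensitivity is scored against the all-parameters reference
  scenario: among suspected-infection patients flagged by the reference,
  the fraction also flagged by the comparison scenario (the reference
  scores 1 by construction).
* **Substitution.**  Among suspected-infection patients flagged by both
  scenarios of a pair, how many carry a different attributed parameter
  class, what they became, and the crude mortality odds ratio of
  reclassified vs same-class patients (Woolf log-OR interval).
* **Mortality models.**  Per parameter class, a binary logistic regression
  of death/hospice on class membership (absence of the class among flagged
  suspected-infection patients is the reference), adjusted for age, sex
  and NEWS category.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .concepts import ATTRIBUTION_CLASSES, ORGAN_SYSTEM_OF

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioEvaluation",
    "SubstitutionResult",
    "MortalityModelResult",
    "crude_odds_ratio",
    "evaluate_scenario",
    "substitution_analysis",
    "fit_mortality_model",
    "mortality_models",
    "build_report",
]


@dataclass
class ScenarioEvaluation:
    """Cohort-level reliability/sensitivity summary for one scenario."""

    scenario: str
    n_flagged: int
    n_flagged_infected: int
    ppv: float | None
    sensitivity: float | None
    relative_change_vs_reference: float | None
    lactate_measured_share: float | None
    per_class: pd.DataFrame  # columns: attributed_class, n_flagged, n_infected, pct_infected

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_flagged": self.n_flagged,
            "n_flagged_infected": self.n_flagged_infected,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "relative_change_vs_reference": self.relative_change_vs_reference,
            "lactate_measured_share": self.lactate_measured_share,
        }


@dataclass
class SubstitutionResult:
    """Attribution churn between two scenarios among dual-membership patients."""

    scenario_pair: tuple[str, str]
    n_dual_membership: int
    n_reclassified: int
    reclass_distribution: dict[str, float]
    deaths_reclassified: int
    deaths_same_class: int
    n_same_class: int
    crude_or: float | None
    ci_low: float | None
    ci_high: float | None

    def as_row(self) -> dict:
        return {
            "reference": self.scenario_pair[0],
            "comparison": self.scenario_pair[1],
            "n_dual_membership": self.n_dual_membership,
            "n_reclassified": self.n_reclassified,
            "deaths_reclassified": self.deaths_reclassified,
            "n_same_class": self.n_same_class,
            "deaths_same_class": self.deaths_same_class,
            "crude_or": self.crude_or,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "reclass_distribution": json.dumps(self.reclass_distribution, sort_keys=True),
        }


@dataclass
class MortalityModelResult:
    """One logistic fit: mortality on presence of one attributed class."""

    scenario: str
    parameter_class: str
    adjusted_or: float | None
    ci_low: float | None
    ci_high: float | None
    n: int
    events: int
    converged: bool
    message: str = ""
    covariates: tuple[str, ...] = ("age_years", "sex", "news_category")

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "parameter_class": self.parameter_class,
            "adjusted_or": self.adjusted_or,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "events": self.events,
            "converged": self.converged,
            "message": self.message,
        }


def crude_odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Crude OR with Woolf 95% CI from a 2x2 table.

    ``a``/``b`` are events/non-events in the exposed group, ``c``/``d`` in
    the unexposed group.  Any zero cell gets a 0.5 continuity correction
    applied to all four cells, with a warning.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("2x2 cells must be non-negative")
    if any(x == 0 for x in cells):
        log.warning("zero cell in 2x2 table %s; applying 0.5 continuity correction", cells)
        a, b, c, d = (x + 0.5 for x in cells)
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-1.96 * se), or_ * math.exp(1.96 * se)


def _flagged_ids(alerts: pd.DataFrame) -> set:
    return set(alerts.loc[alerts["flagged"].astype(bool), "encounter_id"])


def evaluate_scenario(
    alerts: pd.DataFrame,
    labels: pd.DataFrame,
    reference_alerts: pd.DataFrame,
) -> ScenarioEvaluation:
    """Confusion-matrix metrics of one scenario against the infection labels.

    ``alerts``/``reference_alerts`` come from ``screen_cohort``; ``labels``
    from ``label_cohort``; all three must cover the same cohort.
    """
    if set(alerts["encounter_id"]) != set(labels["encounter_id"]):
        raise ValueError("alerts and labels must cover the same cohort")
    scenario = alerts.attrs.get("scenario", "scenario")
    infected = set(labels.loc[labels["suspected_infection"].astype(bool), "encounter_id"])
    flagged = _flagged_ids(alerts)
    ref_flagged = _flagged_ids(reference_alerts)

    n_flagged = len(flagged)
    n_fi = len(flagged & infected)
    if n_flagged == 0:
        log.warning("scenario %s flagged no encounters; PPV undefined", scenario)
        ppv = None
    else:
        ppv = n_fi / n_flagged

    denom = ref_flagged & infected
    sensitivity = len(flagged & denom) / len(denom) if denom else None

    n_ref = len(ref_flagged)
    rel = (n_flagged - n_ref) / n_ref if n_ref else None

    lact = None
    if n_fi:
        measured = set(labels.loc[labels["lactate_measured"].astype(bool), "encounter_id"])
        lact = len(flagged & infected & measured) / n_fi

    fa = alerts.loc[alerts["flagged"].astype(bool)]
    rows = []
    for cls in ATTRIBUTION_CLASSES:
        sub = fa.loc[fa["attributed_class"] == cls, "encounter_id"]
        n_cls = len(sub)
        if n_cls == 0:
            continue
        n_inf = len(set(sub) & infected)
        rows.append(
            {
                "attributed_class": cls,
                "n_flagged": n_cls,
                "n_infected": n_inf,
                "pct_infected": n_inf / n_cls,
            }
        )
    per_class = pd.DataFrame(rows, columns=["attributed_class", "n_flagged", "n_infected", "pct_infected"])

    return ScenarioEvaluation(
        scenario=scenario,
        n_flagged=n_flagged,
        n_flagged_infected=n_fi,
        ppv=ppv,
        sensitivity=sensitivity,
        relative_change_vs_reference=rel,
        lactate_measured_share=lact,
        per_class=per_class,
    )


def substitution_analysis(
    alerts_ref: pd.DataFrame,
    alerts_cmp: pd.DataFrame,
    labels: pd.DataFrame,
) -> SubstitutionResult:
    """Attribution changes and mortality among patients flagged by both scenarios.

    Restricted to suspected-infection patients flagged by both the
    reference and the comparison scenario.  The crude OR contrasts death
    among reclassified vs same-class patients.
    """
    infected = set(labels.loc[labels["suspected_infection"].astype(bool), "encounter_id"])
    died = set(labels.loc[labels["died_or_hospice"].astype(bool), "encounter_id"])
    dual = _flagged_ids(alerts_ref) & _flagged_ids(alerts_cmp) & infected

    ref_cls = alerts_ref.set_index("encounter_id")["attributed_class"]
    cmp_cls = alerts_cmp.set_index("encounter_id")["attributed_class"]

    reclassified = {e for e in dual if ref_cls[e] != cmp_cls[e]}
    same = dual - reclassified

    dist: dict[str, float] = {}
    if reclassified:
        counts: dict[str, int] = {}
        for e in reclassified:
            counts[cmp_cls[e]] = counts.get(cmp_cls[e], 0) + 1
        dist = {k: v / len(reclassified) for k, v in sorted(counts.items())}

    d1 = len(reclassified & died)
    d0 = len(same & died)
    if reclassified and same:
        or_, lo, hi = crude_odds_ratio(d1, len(reclassified) - d1, d0, len(same) - d0)
    else:
        log.warning("substitution analysis degenerate: empty group; OR undefined")
        or_ = lo = hi = None

    return SubstitutionResult(
        scenario_pair=(
            alerts_ref.attrs.get("scenario", "reference"),
            alerts_cmp.attrs.get("scenario", "comparison"),
        ),
        n_dual_membership=len(dual),
        n_reclassified=len(reclassified),
        reclass_distribution=dist,
        deaths_reclassified=d1,
        deaths_same_class=d0,
        n_same_class=len(same),
        crude_or=or_,
        ci_low=lo,
        ci_high=hi,
    )


_NEWS_LEVELS = ("0-4", "5-6", "7-8", "9-25")


def _design_matrix(df: pd.DataFrame, cls: str, adjusted: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X[f"class_{cls}"] = (df["attributed_class"] == cls).astype(float)
    if adjusted:
        X["age_years"] = df["age_years"].astype(float)
        X["sex_male"] = (df["sex"] == "male").astype(float)
        for lev in _NEWS_LEVELS[1:]:  # "0-4" is the reference level
            X[f"news_{lev}"] = (df["news_category"] == lev).astype(float)
    return X


def fit_mortality_model(
    patients: pd.DataFrame,
    parameter_class: str,
    scenario: str = "",
    adjusted: bool = True,
) -> MortalityModelResult:
    """Logistic regression of mortality on membership in one attributed class.

    ``patients`` must already be restricted to suspected-infection patients
    flagged by the scenario, with columns ``died_or_hospice``,
    ``attributed_class``, and (when ``adjusted``) ``age_years``, ``sex``,
    ``news_category``.  Maximum-likelihood fit by IRLS, log-likelihood
    tolerance 1e-8; non-convergence or separation is reported, never silent.
    """
    y = patients["died_or_hospice"].astype(float).to_numpy()
    X = _design_matrix(patients, parameter_class, adjusted)
    n, events = len(patients), int(y.sum())
    covs = ("age_years", "sex", "news_category") if adjusted else ()

    def failed(msg: str) -> MortalityModelResult:
        log.warning("mortality model %s/%s failed: %s", scenario, parameter_class, msg)
        return MortalityModelResult(
            scenario, parameter_class, None, None, None, n, events, False, msg, covs
        )

    n_exposed = int(X[f"class_{parameter_class}"].sum())
    if n_exposed == 0 or n_exposed == n:
        return failed("parameter class has no contrast (all or none exposed)")
    try:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200, tol=1e-8)
    except Exception as exc:  # statsmodels raises on perfect separation
        return failed(f"fit error: {exc}")
    if not getattr(res, "converged", True):
        return failed("IRLS did not converge")
    coef = res.params[f"class_{parameter_class}"]
    se = res.bse[f"class_{parameter_class}"]
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 15 or se > 50:
        return failed("quasi-separation: unstable coefficient")
    z = 1.959963984540054
    return MortalityModelResult(
        scenario=scenario,
        parameter_class=parameter_class,
        adjusted_or=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        n=n,
        events=events,
        converged=True,
        covariates=covs,
    )


def mortality_models(
    patients: pd.DataFrame, scenario: str = "", adjusted: bool = True
) -> list[MortalityModelResult]:
    """One model per attributed class present among the patients."""
    out = []
    for cls in ATTRIBUTION_CLASSES:
        if (patients["attributed_class"] == cls).any():
            out.append(fit_mortality_model(patients, cls, scenario, adjusted))
    return out


def _class_group(cls: str) -> str:
    if cls == "mods":
        return "mods"
    return ORGAN_SYSTEM_OF[cls]


def build_report(
    evaluations: list[ScenarioEvaluation],
    substitutions: list[SubstitutionResult],
    models: list[MortalityModelResult],
    out_dir,
) -> dict[str, "object"]:
    """Write machine-readable result tables and a forest plot of ORs.

    Outputs under ``out_dir``: scenario_metrics.csv, attribution_table.csv,
    substitution.csv, mortality_models.csv, forest.svg.  Two runs on the
    same inputs produce byte-identical tables.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "sepscreen"
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    metrics = pd.DataFrame([e.as_row() for e in evaluations])
    metrics.to_csv(out / "scenario_metrics.csv", index=False)

    attr_rows = []
    for e in evaluations:
        t = e.per_class.copy()
        t.insert(0, "scenario", e.scenario)
        attr_rows.append(t)
    attribution = (
        pd.concat(attr_rows, ignore_index=True)
        if attr_rows
        else pd.DataFrame(columns=["scenario", "attributed_class", "n_flagged", "n_infected", "pct_infected"])
    )
    if attribution.empty or attribution["n_flagged"].sum() == 0:
        # degenerate cohorts still get an explicit (empty) section
        log.warning("report: no alerts in any scenario")
        (out / "NO_ALERTS.txt").write_text(
            "No encounter was flagged by any scenario on this cohort.\n"
        )
    attribution.to_csv(out / "attribution_table.csv", index=False)

    pd.DataFrame([s.as_row() for s in substitutions]).to_csv(out / "substitution.csv", index=False)

    mdf = pd.DataFrame([m.as_row() for m in models])
    mdf.to_csv(out / "mortality_models.csv", index=False)

    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.4 * max(1, len(mdf)))))
    ok = mdf.loc[mdf.get("converged", pd.Series(dtype=bool)) == True] if len(mdf) else mdf
    ys, labels_ = [], []
    for i, row in enumerate(ok.itertuples(index=False)):
        ax.plot([row.ci_low, row.ci_high], [i, i], color="0.3", lw=1.2)
        ax.plot([row.adjusted_or], [i], "s", color="C0", ms=5)
        ys.append(i)
        labels_.append(f"{row.scenario}: {row.parameter_class}")
    ax.axvline(1.0, color="0.6", ls="--", lw=0.8)
    ax.set_yticks(ys)
    ax.set_yticklabels(labels_, fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("adjusted odds ratio (log scale)")
    ax.set_title("Mortality risk by parameter class and scenario")
    fig.tight_layout()
    fig.savefig(out / "forest.svg", metadata={"Date": None})
    plt.close(fig)

    return {
        "scenario_metrics": metrics,
        "attribution_table": attribution,
        "substitution": pd.DataFrame([s.as_row() for s in substitutions]),
        "mortality_models": mdf,
    }
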