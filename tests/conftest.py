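import pytest
from hypothesis import HealthCheck, settings

from sepscreen import (
    CohortSpec,
    PRESET_NAMES,
    generate_cohort,
    label_cohort,
    preset,
    resolve_cohort,
    screen_cohort,
    worked_example_cohort,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked():
    """The hand-authored 12-encounter worked example with ground truth."""
    return worked_example_cohort()


@pytest.fixture(scope="session")
def worked_alerts(worked):
    cohort, _ = worked
    timelines = resolve_cohort(cohort)
    return {name: screen_cohort(cohort, preset(name), timelines) for name in PRESET_NAMES}


@pytest.fixture(scope="session")
def big_run():
    """One large generated cohort screened under all presets, shared across
    the cohort-scale checks."""
    spec = CohortSpec(n_encounters=5000, seed=1701)
    cohort, truth = generate_cohort(spec)
    timelines = resolve_cohort(cohort)
    alerts = {name: screen_cohort(cohort, preset(name), timelines) for name in PRESET_NAMES}
    labels = label_cohort(cohort)
    return {
        "spec": spec,
        "cohort": cohort,
        "truth": truth,
        "timelines": timelines,
        "alerts": alerts,
        "labels": labels,
    }
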