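import numpy as np
import pytest

from caseseries import GeneratorConfig, default_battery, generate_cohort


@pytest.fixture(scope="session")
def battery():
    return default_battery()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (46 controls, 64 patients, 22 tests,
    3% missing, 4 planted word-selective cases)."""
    return generate_cohort(GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def complete_cohort():
    """Fully observed default cohort for stages that require completeness."""
    return generate_cohort(GeneratorConfig(missing_rate=0.0), seed=11)


def small_cohort_csv(tmp_path, rows):
    """Write a minimal 2-test cohort CSV and return (path, battery)."""
    from caseseries.cohort import Direction, Measure, TestSpec

    spec = [
        TestSpec("alpha", "word", (Measure("acc", Direction.HIGHER_IS_BETTER),
                                   Measure("rt", Direction.LOWER_IS_BETTER)),
                 in_composite=True),
        TestSpec("beta", "face", (Measure("acc", Direction.HIGHER_IS_BETTER),),
                 in_composite=True),
    ]
    header = ("participant_id,group,age,education,lesion_volume,"
              "time_since_stroke,alpha__acc,alpha__rt,beta__acc")
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path, spec
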