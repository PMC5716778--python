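import numpy as np
import pandas as pd
import pytest

from cdscore import ClinicalTable, Cohort, ExpressionMatrix
from cdscore.simulate import (
    PlantedGene,
    SyntheticTruth,
    generate_survival_cohort,
    probeset_names,
)


@pytest.fixture
def toy_expression():
    """3 probesets x 2 samples with the values 1..6."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=["p1", "p2", "p3"],
            columns=["S1", "S2"],
        )
    )


@pytest.fixture
def small_clinical():
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4", "S5"],
                "os_time": [12.0, 30.5, 7.2, 60.0, 45.1],
                "os_event": [1, 0, 1, 0, 1],
                "ISS": [1, 2, 3, 1, 2],
            }
        )
    )


@pytest.fixture
def two_class_cohort():
    """Deterministic 8+8 cohort for SAM unit tests."""
    rng = np.random.default_rng(42)
    names = probeset_names(30)
    values = 2.0 ** (8 + 0.5 * rng.standard_normal((30, 16)))
    samples = [f"S{i}" for i in range(16)]
    expr = ExpressionMatrix(values, probeset_ids=names, sample_ids=samples)
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "os_time": rng.exponential(40, 16).round(3),
                "os_event": 1,
            }
        )
    )
    labels = pd.Series(["BMPC"] * 8 + ["MMC"] * 8, index=samples)
    return Cohort(expr, clin, class_labels=labels, name="toy_two_class")


@pytest.fixture(scope="session")
def planted_survival_cohort():
    """n=200 cohort with one strongly protective planted gene."""
    ps = probeset_names(20)[0]
    truth = SyntheticTruth(
        planted_prognostic={ps: PlantedGene(cut_quantile=0.5, beta=-np.log(4.0))},
        censor_rate=0.25,
        seed=7,
    )
    cohort, resolved = generate_survival_cohort(200, 20, truth, name="planted")
    return cohort, resolved, ps
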