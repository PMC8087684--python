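import numpy as np
import pandas as pd
import pytest

from ulmomics import CohortDesign, ExpressionMatrix


def make_design(n_a: int, n_b: int, a: str = "HLRCC", b: str = "NS") -> CohortDesign:
    rows = [{"sample_id": f"{a}_{i}", "cohort": a, "patient_id": f"P{i}"} for i in range(n_a)]
    rows += [{"sample_id": f"{b}_{i}", "cohort": b, "patient_id": f"P{n_a + i}"} for i in range(n_b)]
    return CohortDesign(pd.DataFrame(rows).set_index("sample_id"))


def make_matrix(values, features=None, samples=None, layer="protein") -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples), layer)


@pytest.fixture
def design_4_4() -> CohortDesign:
    return make_design(4, 4)


@pytest.fixture
def design_16_12() -> CohortDesign:
    return make_design(16, 12)
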