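import numpy as np
import pandas as pd
import pytest

from heteromap.design import full_factorial
from heteromap.simulate import PhenotypeSet


def factorial_phenos(F, maternal=None, paternal=None, parents=None):
    """PhenotypeSet for a complete a x b factorial given the F1 matrix."""
    F = np.asarray(F, dtype=float)
    a, b = F.shape
    maternal = maternal or [f"M{i + 1}" for i in range(a)]
    paternal = paternal or [f"P{j + 1}" for j in range(b)]
    rows = [
        {"maternal": maternal[i], "paternal": paternal[j], "env": "E1", "value": F[i, j]}
        for i in range(a)
        for j in range(b)
    ]
    if parents is None:
        par = pd.DataFrame(columns=["id", "env", "value"])
    else:
        par = pd.DataFrame(
            {"id": maternal + paternal, "env": "E1", "value": np.asarray(parents, dtype=float)}
        )
    return PhenotypeSet(par, pd.DataFrame(rows))


@pytest.fixture
def design_2x2():
    return full_factorial(2, 2)


@pytest.fixture
def design_3x3():
    return full_factorial(3, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
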