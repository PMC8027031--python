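import numpy as np
import pandas as pd
import pytest

from runxpipe.config import SimulationConfig
from runxpipe.expression import ExpressionMatrix


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=60, n_peaks=70, library_size=70_000,
                            deg_fraction=0.2, seed=11)


@pytest.fixture
def null_config() -> SimulationConfig:
    return SimulationConfig(n_genes=60, n_peaks=70, library_size=70_000,
                            effect_size_log2=0.0, peak_effect_log2=0.0,
                            seed=11)


def make_matrix(rows: list[list[float]], conditions: dict[str, str],
                genes: list[str] | None = None) -> ExpressionMatrix:
    samples = list(conditions)
    genes = genes or [f"g{i}" for i in range(len(rows))]
    return ExpressionMatrix(
        values=pd.DataFrame(rows, index=genes, columns=samples),
        conditions=pd.Series(conditions))


@pytest.fixture
def two_by_two() -> ExpressionMatrix:
    # genes chosen to exercise the hand-computed t / LMR examples
    return make_matrix(
        [[5.0, 5.0, 3.0, 3.0],
         [2.0, 3.0, 1.0, 1.0],
         [2.0, 3.0, 2.0, 3.0]],
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
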