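import numpy as np
import pandas as pd
import pytest

from dmsfit import ExperimentDesign, FitnessTable, Replicate, VariantCountTable


@pytest.fixture
def design3():
    """Three-replicate design over a 3-mer wild type."""
    return ExperimentDesign(
        (
            Replicate("1", "in1", "out1"),
            Replicate("2", "in2", "out2"),
            Replicate("3", "in3", "out3"),
        ),
        "AAA",
    )


@pytest.fixture
def table3(design3):
    """Tiny count table: wild type, two singles, one double, one triple."""
    df = pd.DataFrame(
        {
            "variant_id": ["AAA", "AAC", "ACA", "CCA", "CCC"],
            "in1": [1000, 100, 12, 40, 5],
            "in2": [1100, 90, 3, 35, 4],
            "in3": [900, 110, 15, 30, 6],
            "out1": [1000, 50, 10, 20, 2],
            "out2": [1050, 45, 2, 18, 1],
            "out3": [950, 55, 12, 15, 3],
        }
    )
    return VariantCountTable(df, "AAA", design3.sample_names)


def make_fitness_table(values: np.ndarray, wt_row: int = 0, variance=None) -> FitnessTable:
    """FitnessTable from a raw (variants x replicates) array, for unit tests."""
    values = np.asarray(values, dtype=float)
    idx = [f"v{i}" for i in range(values.shape[0])]
    cols = [str(r + 1) for r in range(values.shape[1])]
    fit = pd.DataFrame(values, index=idx, columns=cols)
    if variance is None:
        variance = np.full_like(values, 0.01)
    var = pd.DataFrame(np.asarray(variance, dtype=float), index=idx, columns=cols)
    n_subs = pd.Series(np.where(np.arange(len(idx)) == wt_row, 0, 1), index=idx)
    return FitnessTable(fit, var, n_subs, idx[wt_row])
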