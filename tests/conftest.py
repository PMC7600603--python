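import numpy as np
import pandas as pd
import pytest

from nrf2screen.signature import ExpressionCohort


def make_cohort(values: dict, labels: dict, name: str = "toy") -> ExpressionCohort:
    """Tiny cohort from {gene: [values...]} and {sample: class}."""
    samples = list(labels)
    df = pd.DataFrame(values, index=samples).T
    df.columns = samples
    return ExpressionCohort(values=df, labels=pd.Series(labels), name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_plate():
    """One CTG plate: 4 negative wells at 100, 4 positive at 0, one compound
    with signals at the control mean, the positive mean and halfway."""
    rows = []
    for i in range(4):
        rows.append(dict(plate="P1", well=f"A{i:02d}", compound="NEG_CTRL",
                         dose_nM=0.0, cell_line="WT", readout="CTG", signal=100.0))
        rows.append(dict(plate="P1", well=f"B{i:02d}", compound="POS_CTRL",
                         dose_nM=0.0, cell_line="WT", readout="CTG", signal=0.0))
    for dose, sig in [(1.0, 100.0), (10.0, 50.0), (100.0, 0.0)]:
        rows.append(dict(plate="P1", well="C01", compound="drugA", dose_nM=dose,
                         cell_line="WT", readout="CTG", signal=sig))
    return pd.DataFrame(rows)
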