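import numpy as np
import pandas as pd
import pytest

from equusage.simulate import gen_ages, gen_methylation
from equusage.types import BetaMatrix, SampleSheet


@pytest.fixture(scope="session")
def blood_cohort():
    """A clock-friendly cohort: 40 samples, 400 sites, 30 informative."""
    ages = gen_ages(40, 0.15, 20.2, seed=11)
    beta, truth = gen_methylation(
        ages,
        n_sites=400,
        frac_clock=30 / 400,
        frac_pacemaker=0.0,
        noise_sd=0.01,
        seed=12,
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": beta.sample_ids,
                "species": "base",
                "tissue": "blood",
                "sex": np.where(np.arange(40) % 2 == 0, "F", "M"),
                "age": ages,
            }
        )
    )
    return sheet, beta, truth


def make_sheet(ages, tissue="blood", prefix="s"):
    ages = np.asarray(ages, float)
    n = ages.size
    tissues = [tissue] * n if isinstance(tissue, str) else list(tissue)
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"{prefix}{i:03d}" for i in range(n)],
                "species": "base",
                "tissue": tissues,
                "sex": "F",
                "age": ages,
            }
        )
    )


def make_beta(values, prefix_site="cg", prefix_sample="s"):
    values = np.asarray(values, float)
    n, m = values.shape
    return BetaMatrix(
        [f"{prefix_sample}{i:03d}" for i in range(n)],
        [f"{prefix_site}{j:03d}" for j in range(m)],
        values,
    )
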