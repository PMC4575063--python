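import numpy as np
import pandas as pd
import pytest

from coexqtl import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (1000 mRNA probes, 3 modules) shared across tests."""
    cfg = synthdata.default_config(
        seed=0, n_mrna=1000, n_mirna=150, n_variants=200,
        mrna_modules=(synthdata.ModuleSpec(300, 0.8, sign=-1),
                      synthdata.ModuleSpec(250, 0.7, sign=-1),
                      synthdata.ModuleSpec(200, 0.6, sign=1)),
        mirna_modules=(synthdata.ModuleSpec(50, 0.7, sign=1),
                       synthdata.ModuleSpec(40, 0.6, sign=1)),
        repression_spec=(synthdata.RepressionSpec(0, 0, 0.6, 12),),
        eqtl_spec=tuple(synthdata.EqtlSpec() for _ in range(4)),
        gwas_spec=synthdata.GwasSpec(n_subjects=400),
    )
    return cfg, synthdata.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_expression(values: np.ndarray, prefix: str = "g") -> pd.DataFrame:
    values = np.atleast_2d(values)
    return pd.DataFrame(values,
                        index=[f"{prefix}{i}" for i in range(values.shape[0])],
                        columns=[f"s{j}" for j in range(values.shape[1])])
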