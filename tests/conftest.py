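import numpy as np
import pytest

import akernel as ak


@pytest.fixture(scope="session")
def planted():
    """Small synthetic study with 15 planted risk compartments (omega=4)."""
    rng = np.random.default_rng(11)
    risk = ak.synthetic.uniform_risk_loci(rng, 300, 15, 4.0)
    spec = ak.SyntheticSpec(
        n_cases=120, n_controls=100, n_snps=300, risk_loci=risk, seed=11,
        missing_rate=0.0,
    )
    m, truth = ak.generate(spec)
    return m, truth


@pytest.fixture(scope="session")
def null_matrix():
    """No-signal study: identical generating frequencies for both cohorts."""
    spec = ak.SyntheticSpec(n_cases=80, n_controls=80, n_snps=250, seed=7,
                            missing_rate=0.0)
    m, _ = ak.generate(spec)
    return m


@pytest.fixture(scope="session")
def table2():
    return ak.table2_fixture()
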