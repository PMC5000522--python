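import numpy as np
import pandas as pd
import pytest

from retrosig import (
    DimensionlessParams,
    amplitudes_table,
    sample_biochemical,
)

#: homogeneous dose-response example parameters used throughout the tests
DOSE_EXAMPLE = dict(a=1.6, b=0.8, c=0.05, e=0.7)
#: homogeneous drug-response example parameters (strong retroactivity)
DRUG_EXAMPLE = dict(a=2.2, b=0.0005, c=5.2, e=5.1)

TEST_SEED = 20160825


@pytest.fixture(scope="session")
def dose_q():
    return DimensionlessParams.homogeneous(n=3, **DOSE_EXAMPLE)


@pytest.fixture(scope="session")
def drug_q():
    return DimensionlessParams.homogeneous(n=3, **DRUG_EXAMPLE)


@pytest.fixture(scope="session")
def medium_scan():
    """A 30k-sample scan shared by the statistical unit tests."""
    samples = sample_biochemical(30_000, seed=TEST_SEED)
    records = amplitudes_table(samples)
    return samples, records


def random_dimensionless(rng, n=3, log_range=2.0, homogeneous=False, d_T=0.0):
    """Random cascade parameters with log-uniform ratios (test helper)."""

    def draw(size=None):
        return 10.0 ** rng.uniform(-log_range, log_range, size)

    if homogeneous:
        a, b, c, e = draw(), draw(), draw(), draw()
        return DimensionlessParams.homogeneous(a=a, b=b, c=c, e=e, n=n, d_T=d_T)
    return DimensionlessParams(
        a=draw(n), b=draw(n), c=draw(n), e=draw(n), d_T=d_T, a_D=draw()
    )


def random_biochemical_frame(rng, n_samples, log_range=2.0):
    """Random sampled-parameter table (columns as the LHS sampler emits)."""
    from retrosig.parameter_sampler import SAMPLED_NAMES

    data = 10.0 ** rng.uniform(-log_range, log_range, (n_samples, len(SAMPLED_NAMES)))
    return pd.DataFrame(data, columns=list(SAMPLED_NAMES))
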