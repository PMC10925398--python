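import numpy as np
import pandas as pd
import pytest

from hepnet import (
    AbundanceMatrix,
    simulate_reference_brain,
    simulate_tmt_plasma,
)


@pytest.fixture(scope="session")
def tmt_study():
    """A small two-set TMT study with planted effects and batch structure."""
    return simulate_tmt_plasma(
        n_sets=2,
        batches_per_set=[2, 2],
        channels_per_batch=[9, 9],
        n_proteins=300,
        n_effect_proteins=40,
        delta_log2=1.0,
        sigma_batch=0.5,
        sigma_channel=0.1,
        sigma_noise=0.2,
        missing_steepness=6.0,
        seed=11,
        missing_rate=0.1,
    )


@pytest.fixture(scope="session")
def brain_net():
    """A small planted reference brain network."""
    return simulate_reference_brain(
        n_modules=8, proteins_per_module=15, n_samples=60, kme_target=0.7, n_grey=40, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_matrix(rng, n_proteins=20, n_samples=8, missing_frac=0.1, scale="raw"):
    """A random abundance matrix with scattered missing cells."""
    if scale == "raw":
        vals = np.exp2(rng.normal(10, 2, size=(n_proteins, n_samples)))
    else:
        vals = rng.normal(0, 1, size=(n_proteins, n_samples))
    if missing_frac:
        mask = rng.random(vals.shape) < missing_frac
        vals = np.where(mask, np.nan, vals)
    proteins = [f"P{i:04d}|G{i:04d}" for i in range(n_proteins)]
    samples = [f"s{j}" for j in range(n_samples)]
    return AbundanceMatrix(pd.DataFrame(vals, index=proteins, columns=samples), scale)
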