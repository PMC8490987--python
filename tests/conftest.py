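import numpy as np
import pandas as pd
import pytest

import compscale as cs
from compscale.simulate import _design_table


@pytest.fixture(scope="session")
def small_config():
    return cs.SynthConfig(n_genes=600, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One shared synthetic study: (annotations, truth, counts, rna design,
    intensities, protein design)."""
    return cs.simulate_study(small_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config, small_study):
    ann, truth, counts, design, intens, pdesign = small_study
    out = tmp_path_factory.mktemp("fixture")
    cs.write_fixture(out, ann, truth, counts, design, intens, pdesign)
    return out


@pytest.fixture
def rna_design():
    return _design_table(2)


@pytest.fixture
def protein_design():
    return _design_table(4)


@pytest.fixture
def null_counts(rna_design):
    """Counts with no planted effects, equal library sizes."""
    rng = np.random.default_rng(5)
    mu = rng.uniform(20, 500, size=200)
    counts = rng.poisson(mu[:, None], size=(200, 8))
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(200)],
                        columns=rna_design["sample"].tolist())
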