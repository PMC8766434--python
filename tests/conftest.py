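import warnings

import numpy as np
import pandas as pd
import pytest

import ibcnet as ib

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_compendium():
    """One planted 100-gene module among 400 genes, 10 lines x 3 replicates."""
    spec = ib.CompendiumSpec(
        seed=11,
        n_genes=400,
        modules=(ib.ModuleSpec(100, 2.0, "IBC"),),
        n_cell_lines_ibc=5,
        n_cell_lines_nibc=5,
        replicates_per_line=3,
        noise_sd=1.0,
    )
    return ib.generate_cell_line_compendium(spec)


@pytest.fixture(scope="session")
def three_module_compendium():
    """The planted-module recovery scenario: 3 x 150 genes, SNR 2."""
    spec = ib.CompendiumSpec(
        seed=7,
        n_genes=1000,
        modules=(
            ib.ModuleSpec(150, 2.0, "IBC"),
            ib.ModuleSpec(150, 2.0, "none"),
            ib.ModuleSpec(150, 2.0, "none"),
        ),
        n_cell_lines_ibc=5,
        n_cell_lines_nibc=5,
        replicates_per_line=3,
        noise_sd=1.0,
    )
    return ib.generate_cell_line_compendium(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_expression(rng):
    genes = [f"g{i:03d}" for i in range(60)]
    samples = [f"s{i:02d}" for i in range(12)]
    return pd.DataFrame(rng.normal(8, 2, size=(60, 12)), index=genes, columns=samples)
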