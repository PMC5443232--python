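import numpy as np
import pandas as pd
import pytest

from pangenet.simulate import PangenomeDesign, generate_pangenome_collection


@pytest.fixture(scope="session")
def toy_matrix() -> pd.DataFrame:
    """Three genomes sharing one family, each with one private family."""
    return pd.DataFrame(
        [[1, 1, 1], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        index=["f1", "f2", "f3", "f4"],
        columns=["A", "B", "C"],
    )


@pytest.fixture(scope="session")
def small_collection():
    """Five genomes x 12 planted families at 90% within-family identity."""
    design = PangenomeDesign(
        n_unassigned=5, core_size=12, within_family_identity=90.0,
        gene_length_range=(80, 160), seed=42)
    return generate_pangenome_collection(design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
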