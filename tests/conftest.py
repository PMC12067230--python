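import numpy as np
import pandas as pd
import pytest

import nucleation_dms as nd


@pytest.fixture(scope="session")
def bri2():
    return nd.reference_peptide("bri2")


@pytest.fixture(scope="session")
def adan():
    return nd.reference_peptide("adan")


@pytest.fixture(scope="session")
def abri():
    return nd.reference_peptide("abri")


@pytest.fixture(scope="session")
def nnk_library(bri2):
    """A small random-extension library: (nt, peptide) pairs, deduplicated nt."""
    spec = nd.NNKExtensionSpec(bri2)
    pairs = nd.sample_nnk_extensions(spec, 600, seed=11)
    seen, out = set(), []
    for nt, pep in pairs:
        if nt not in seen:
            seen.add(nt)
            out.append((nt, pep))
    return out


def make_counts(data: dict) -> pd.DataFrame:
    """Count table from {variant: {(rep, phase): count}}."""
    frame = pd.DataFrame(data).T.fillna(0).astype(int)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["replicate", "phase"])
    frame.index.name = "variant"
    return frame


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
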