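import numpy as np
import pandas as pd
import pytest

from zmeth import mhmgenes, qtlmap, simdata


@pytest.fixture(scope="session")
def gene_table():
    return mhmgenes.load_mhm_gene_table()


@pytest.fixture(scope="session")
def fhm_table():
    return mhmgenes.load_fhm_window_table()


@pytest.fixture(scope="session")
def hotspot_table():
    return mhmgenes.load_hotspot_table()


@pytest.fixture(scope="session")
def small_study():
    """One default-design synthetic study, shared across read-only tests."""
    cfg = simdata.SimConfig(seed=11)
    return simdata.simulate_study(cfg)


@pytest.fixture()
def single_marker_setup():
    """A 60-individual, one-marker design for closed-form regression checks."""
    rng = np.random.default_rng(7)
    n = 60
    ids = [f"i{k}" for k in range(n)]
    samples = pd.DataFrame(
        {
            "sex": np.where(rng.integers(0, 2, n) == 1, "male", "female"),
            "batch": rng.choice(["b1", "b2"], n),
        },
        index=ids,
    )
    g = rng.integers(0, 3, n)
    mmap = qtlmap.MarkerMap(
        pd.DataFrame({"marker": ["mA"], "chrom": ["c1"], "cM": [0.0], "bp": [100]}),
        z_chrom=None,
    )
    gt = qtlmap.GenotypeTable(
        dosages=pd.DataFrame({"mA": g}, index=ids), samples=samples
    )
    return mmap, gt, samples, g
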