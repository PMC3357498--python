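import numpy as np
import pandas as pd
import pytest

from rohmap.hapfreq import estimate_pair_table
from rohmap.io import GenotypePanel, MarkerMap
from rohmap.synth import PopulationModel, generate_panel


def make_panel(geno, chrom=None, pos=None, roles=None, fids=None, iids=None):
    """Hand-built panel: genotype codes (n, m) plus optional marker layout."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else [1000 * (j + 1) for j in range(m)]
    iids = iids if iids is not None else [f"i{k + 1}" for k in range(n)]
    mm = MarkerMap(pd.DataFrame({
        "chrom": [str(c) for c in chrom],
        "marker_id": [f"m{j + 1}" for j in range(m)],
        "pos_bp": pos,
        "cm": [p / 1e6 for p in pos],
        "allele1": "A", "allele2": "B",
    }))
    ind = pd.DataFrame({
        "iid": iids,
        "fid": fids if fids is not None else iids,
        "role": roles if roles is not None else ["control"] * n,
    })
    return GenotypePanel(mm, ind, geno)


@pytest.fixture(scope="session")
def markov_model():
    return PopulationModel(n_chrom=2, markers_per_chrom=300, seed=7)


@pytest.fixture(scope="session")
def control_data(markov_model):
    panel, haps = generate_panel(markov_model, 150, 101)
    table = estimate_pair_table(panel)
    return panel, haps, table


@pytest.fixture(scope="session")
def mosaic_model():
    """The study-condition population used for recovery experiments."""
    return PopulationModel(n_chrom=2, markers_per_chrom=2500, mode="mosaic",
                           seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
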