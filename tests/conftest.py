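import numpy as np
import pandas as pd
import pytest

from panelforge.dataio import GenotypeDataset
from panelforge.synthetic_data import PedigreeDesign, SimConfig, sim_study


def make_dataset(G, chroms=None, positions=None, samples=None, pops=None, **kw):
    """Hand-build a small GenotypeDataset from a dosage matrix."""
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    if chroms is None:
        chroms = ["1"] * m
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"m{j + 1}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    populations = None
    if pops is not None:
        populations = pd.Series(list(pops), index=samples)
    return GenotypeDataset(
        samples=samples, markers=markers, G=G, populations=populations, **kw
    )


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Two clean populations at F = 0.1: strongly but not trivially structured."""
    cfg = SimConfig(
        n_pops=2, n_per_pop=40, n_markers=600, fst=0.1, miss_rate=0.0, seed=42
    )
    ds, freqs, _ = sim_study(cfg)
    return ds


@pytest.fixture(scope="session")
def pedigree_study():
    """Two populations with embedded pedigrees and a truth table (no corruption)."""
    cfg = SimConfig(
        n_pops=2, n_per_pop=1, n_markers=2000, fst=0.1, miss_rate=0.0, seed=7
    )
    design = PedigreeDesign(
        n_parent_offspring=1, n_full_sib=1, n_half_sib=2, n_cousin=2, n_unrelated=15
    )
    return sim_study(cfg, design)
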