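import numpy as np
import pandas as pd
import pytest

from xwing.io import LDPanel
from xwing.simulate import block_spec_for, simulate_ld_panel


@pytest.fixture(scope="session")
def panel_pair():
    """Two small matched-map reference panels (4 blocks x 50 SNPs)."""
    return simulate_ld_panel(n_blocks=4, block_size=50, n_hap=600,
                             ld_decay=0.5, seed=7)


@pytest.fixture(scope="session")
def small_blocks():
    return block_spec_for(4, 50)


@pytest.fixture(scope="session")
def panels_2k():
    """Desk-scale panels: M = 2000 SNPs in 20 LD blocks of 100."""
    return simulate_ld_panel(n_blocks=20, block_size=100, n_hap=1000,
                             ld_decay=0.5, seed=11)


@pytest.fixture(scope="session")
def blocks_2k():
    return block_spec_for(20, 100)


def make_panel(dosages, snp_map=None, **kw):
    """LDPanel from a raw dosage matrix with an auto-generated SNP map."""
    dosages = np.asarray(dosages, dtype=float)
    if snp_map is None:
        m = dosages.shape[1]
        snp_map = pd.DataFrame({
            "snp_id": [f"rs{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(m) * 100 + 50,
            "a1": "A",
            "a2": "G",
        })
    return LDPanel(dosages, snp_map, **kw)
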