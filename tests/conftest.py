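import numpy as np
import pandas as pd
import pytest

from psgkit import mixed_z, synthetic
from psgkit.screen_io import reference_sets_from_iterables


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel: (guide LFCTable, gene LFCTable, truth)."""
    return synthetic.simulate_panel(synthetic.PanelConfig(seed=1234))


@pytest.fixture(scope="session")
def default_zmatrix(default_panel):
    guide, gene, _ = default_panel
    return mixed_z.score_panel(guide, gene)


@pytest.fixture
def small_refs():
    return reference_sets_from_iterables(
        essential=[f"ess{i}" for i in range(20)],
        nonessential=[f"non{i}" for i in range(20)],
        tsg=[f"tsg{i}" for i in range(10)],
        oncogene=[f"onc{i}" for i in range(10)],
    )


@pytest.fixture
def counts_tsv(tmp_path):
    """Tiny 3-guide, 2-sample counts table and matching guide map."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "guide\treference:A:day0\tendpoint:A:day21\n"
        "g1\t100\t400\n"
        "g2\t100\t100\n"
        "g3\t200\t50\n"
    )
    gmap = tmp_path / "map.tsv"
    gmap.write_text("guide\tgene\ng1\tGENE1\ng2\tGENE1\ng3\tGENE2\n")
    return counts, gmap


def make_zmatrix(values, genes=None, screens=None):
    """Wrap a plain array as a MixedZMatrix without fit metadata."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    screens = screens or [f"s{j}" for j in range(values.shape[1])]
    return mixed_z.MixedZMatrix(
        z=pd.DataFrame(values, index=genes, columns=screens), fits={}
    )
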