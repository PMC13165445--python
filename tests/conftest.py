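import numpy as np
import pytest

from msapclade import BandMatrix, PanelConfig, simulate_marker_panel


def make_matrix(rows, sample_ids=None, **kwargs):
    """BandMatrix from a list of per-sample band lists (None = missing)."""
    values = np.array(
        [[-1 if v is None else v for v in row] for row in rows], dtype=np.int8
    )
    n_samples, n_loci = values.shape
    return BandMatrix(
        sample_ids=sample_ids or [f"S{i + 1}" for i in range(n_samples)],
        locus_ids=kwargs.pop("locus_ids", [f"L{j + 1}" for j in range(n_loci)]),
        values=values,
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_panel():
    """Default two-clade study panel (2 + 12 + outgroup), fixed seed."""
    cfg = PanelConfig(seed=11)
    aflp, hpa, msp, truth = simulate_marker_panel(cfg)
    return cfg, aflp, hpa, msp, truth


@pytest.fixture()
def toy_matrix():
    # 3 samples x 4 loci; L1 invariant, L4 has a missing cell
    return make_matrix(
        [
            [1, 1, 0, 1],
            [1, 0, 1, None],
            [1, 1, 1, 0],
        ]
    )
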