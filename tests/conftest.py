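import numpy as np
import pandas as pd
import pytest

from canopyresponse import Phylogeny, SyntheticConfig


def make_plots(nx, ny, cover=None, counts=None):
    """Plot table on an nx x ny lattice; cover may be scalar, array or callable."""
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    if cover is None:
        cover = 50.0
    if callable(cover):
        cov = np.array([cover(x, y) for x, y in zip(ix, iy)], dtype=float)
    else:
        cov = np.broadcast_to(np.asarray(cover, dtype=float), ix.shape).copy()
    df = pd.DataFrame(
        {
            "plot_id": [f"P{i:05d}" for i in range(ix.size)],
            "x_km": ix,
            "y_km": iy,
            "cover_pct": cov,
        }
    )
    if counts:
        for name, vals in counts.items():
            df[name] = vals
    return df


@pytest.fixture
def small_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,D:2);", is_path=False)


@pytest.fixture
def small_config():
    return SyntheticConfig(grid_nx=20, grid_ny=20, n_species=8, seed=11)
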