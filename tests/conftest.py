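import numpy as np
import pytest

from socrisk.synthetic_data import ClusterCapacity, SimConfig, \
    gen_fractions_and_soc, gen_pedoclimate_sites


def single_cluster_config(method, beta, breakpoint=None, *, n=2000, seed=11,
                          **kw):
    return SimConfig(
        n_sites=n,
        n_clusters_true=1,
        seed=seed,
        capacity_params=(ClusterCapacity(method, beta, breakpoint_true=breakpoint),),
        **kw,
    )


@pytest.fixture(scope="session")
def bl_fill():
    """n=2000 points filled under a known linear boundary (soil basis 0.45,
    i.e. 45 g MAOC kg-1 fine fraction)."""
    cfg = single_cluster_config("BL", 0.45)
    return gen_fractions_and_soc(gen_pedoclimate_sites(cfg), cfg), cfg


@pytest.fixture(scope="session")
def nbl_fill():
    cfg = single_cluster_config("NBL", 28.5)
    return gen_fractions_and_soc(gen_pedoclimate_sites(cfg), cfg), cfg


@pytest.fixture(scope="session")
def pbl_fill():
    cfg = single_cluster_config("PBL", 34.0, breakpoint=30.0)
    return gen_fractions_and_soc(gen_pedoclimate_sites(cfg), cfg), cfg


def pinball_grid_oracle(x, y, tau, beta_grid):
    """Exhaustive pinball-loss grid search for a through-origin slope."""
    losses = []
    for b in beta_grid:
        r = y - b * x
        losses.append(np.mean(np.where(r >= 0, tau * r, (tau - 1) * r)))
    return beta_grid[int(np.argmin(losses))]
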