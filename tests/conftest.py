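import numpy as np
import pytest

from pctopo.tissue_graph import TissueGraph


def ring_world(n: int) -> TissueGraph:
    """Minimal valid tissue with one central cell of degree n.

    The centre is surrounded by a ring of n cells, all of which also border
    a single outer cell that closes the neighbourhoods.  Used to measure the
    split law of an isolated division at a prescribed mother degree.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    centre, outer = 0, 1
    ring = list(range(2, 2 + n))
    order = {centre: list(ring), outer: list(reversed(ring))}
    for i, r in enumerate(ring):
        order[r] = [centre, ring[(i - 1) % n], outer, ring[(i + 1) % n]]
    return TissueGraph(order)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def voronoi_fixture():
    """One mid-sized analysed Voronoi frame with ground truth, shared."""
    from pctopo.segmentation_topology import analyse_frame
    from pctopo.synthetic_data import SyntheticFrameSpec, voronoi_frame

    sf = voronoi_frame(SyntheticFrameSpec(n_seeds=150, shape=(400, 400), lloyd=2, seed=7))
    analyse_frame(sf.frame)
    return sf
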