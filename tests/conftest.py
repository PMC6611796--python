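import numpy as np
import pytest

from pktscreen.datatypes import MotilityParams
from pktscreen.synthetic import render_pkt_montage, simulate_prw_path
from pktscreen.synthetic.pkt_render import PKTRenderConfig


def make_disjoint_paths(n: int = 5, seed: int = 10,
                        speed: float = 0.7) -> list[np.ndarray]:
    """PRW paths started far apart and clipped into the field (um)."""
    starts = [(120, 120), (520, 120), (330, 400), (120, 580), (560, 560),
              (330, 120), (120, 330), (560, 330)][:n]
    params = MotilityParams(speed=speed, persistence_time=60.0,
                            track_width=15.0)
    paths = []
    for i, s in enumerate(starts):
        p = simulate_prw_path(params, 140, 3.0, rng_seed=seed + i) + np.array(s)
        paths.append(np.clip(p, 30, 740))
    return paths


@pytest.fixture(scope="session")
def montage_five():
    """Noise-on montage with 5 well-separated single-cell tracks."""
    paths = make_disjoint_paths(5)
    m = render_pkt_montage(paths, track_width_um=15.0, rng_seed=1)
    assert not m.colliding_tracks  # fixture sanity: tracks must be disjoint
    return m


@pytest.fixture(scope="session")
def pure_lawn():
    cfg = PKTRenderConfig(image_shape=(400, 400))
    return render_pkt_montage([], config=cfg, rng_seed=7)
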