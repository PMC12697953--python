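import math

import numpy as np
import pytest

from uatrack.datamodel import Detection, build_forest


def det(id, frame, x=0.0, y=0.0, area=100.0, orientation=0.0):
    return Detection(id=id, frame=frame, x=float(x), y=float(y),
                     area=float(area), orientation=float(orientation))


def random_forest(rng, n_frames=6, n_roots=3, p_div=0.2, p_die=0.1, p_appear=0.15,
                  max_cells=40):
    """A random valid lineage forest with divisions, deaths and appearances."""
    next_id = 0
    dets, edges = [], []
    current = []
    for _ in range(n_roots):
        d = det(next_id, 0, x=rng.uniform(0, 200), y=rng.uniform(0, 200),
                area=rng.uniform(50, 300), orientation=rng.uniform(0, math.pi - 1e-9))
        next_id += 1
        dets.append(d)
        current.append(d)
    for frame in range(1, n_frames):
        nxt = []
        for d in current:
            u = rng.random()
            if u < p_die:
                continue
            n_children = 2 if (u < p_die + p_div and len(nxt) < max_cells - 1) else 1
            for _ in range(n_children):
                c = det(next_id, frame, x=rng.uniform(0, 200), y=rng.uniform(0, 200),
                        area=rng.uniform(50, 300),
                        orientation=rng.uniform(0, math.pi - 1e-9))
                next_id += 1
                dets.append(c)
                edges.append((d.id, c.id))
                nxt.append(c)
        while rng.random() < p_appear and len(nxt) < max_cells:
            c = det(next_id, frame, x=rng.uniform(0, 200), y=rng.uniform(0, 200),
                    area=rng.uniform(50, 300), orientation=rng.uniform(0, math.pi - 1e-9))
            next_id += 1
            dets.append(c)
            nxt.append(c)
        current = nxt
        if not current:
            break
    return build_forest(edges, dets)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
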