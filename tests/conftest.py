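import numpy as np
import pytest

from fluctuodyn import (
    generate_hard_sphere,
    generate_ideal_gas,
    generate_water_like,
)


def brute_force_lsi(config, cutoff=3.7):
    """O(N²) double-loop local-structure-index oracle, independent of the
    k-d tree implementation path."""
    pos, box = config.positions, config.box
    n = pos.shape[0]
    out = {}
    half = min(box) / 2
    for i in range(n):
        d = pos - pos[i]
        d -= box * np.round(d / box)
        dist = np.sqrt((d ** 2).sum(axis=1))
        order = np.lexsort((np.arange(n), dist))
        dist = dist[order]
        dist = dist[dist > 0]
        n_i = int((dist < cutoff).sum())
        if n_i == 0 or len(dist) < n_i + 1 or dist[n_i] > half:
            continue
        gaps = np.diff(dist[: n_i + 1])
        out[i] = float(np.mean((gaps - gaps.mean()) ** 2))
    return out


@pytest.fixture(scope="session")
def ideal_gas_config():
    return generate_ideal_gas(1000, 30.0, seed=1)


@pytest.fixture(scope="session")
def hard_sphere_config():
    # packing fraction 0.2 with R = 1.78 Å in a 30 Å box
    return generate_hard_sphere(229, 30.0, 1.78, seed=1)


@pytest.fixture(scope="session")
def water_like_half():
    return generate_water_like(600, 0.5, jitter=0.05, seed=3)


@pytest.fixture(scope="session")
def saxs_q_grid():
    return np.arange(0.05, 1.2, 0.005)
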