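import hypothesis
import numpy as np
import pytest

import deploysim as ds

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_population():
    """A small population with moderate home attraction, for cheap runs."""
    return ds.MovementParams(v=0.001, a=0.01, n_animals=25)


@pytest.fixture(scope="session")
def strong_tracks():
    """Synthetic coastal tracks with strong home attraction (session-cached)."""
    cfg = ds.synth_config("strong", n_animals=12, n_steps=400, seed=42)
    return ds.generate_synthetic_geotracks(cfg)


@pytest.fixture(scope="session")
def weak_tracks():
    """Synthetic wide-ranging tracks with weak home attraction."""
    cfg = ds.synth_config("weak", n_animals=12, n_steps=400, seed=43)
    return ds.generate_synthetic_geotracks(cfg)


def slow_buffer_simulation(positions, station_xy, radius):
    """Independent step-by-step oracle for the buffer/flush mechanics.

    Walks the trajectory one step and one animal at a time, maintaining the
    stored-package counter explicitly and applying the rules literally:
    generate one package, then flush everything if within <= radius of any
    station.  Returns (transmitted, stored, event_times, event_sizes) and
    checks package conservation at every single step.
    """
    n_total, n_animals, _ = positions.shape
    n_steps = n_total - 1
    stored = [0] * n_animals
    transmitted = [0] * n_animals
    times = [[] for _ in range(n_animals)]
    sizes = [[] for _ in range(n_animals)]
    for t in range(1, n_steps + 1):
        for i in range(n_animals):
            stored[i] += 1  # one package generated this step
            x, y = positions[t, i]
            in_range = any(
                (x - sx) ** 2 + (y - sy) ** 2 <= radius ** 2
                for sx, sy in station_xy
            )
            if in_range:
                times[i].append(t)
                sizes[i].append(stored[i])
                transmitted[i] += stored[i]
                stored[i] = 0
            assert transmitted[i] + stored[i] == t, "conservation broken"
    return (
        np.array(transmitted),
        np.array(stored),
        [np.array(t, dtype=np.int64) for t in times],
        [np.array(s, dtype=np.int64) for s in sizes],
    )
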