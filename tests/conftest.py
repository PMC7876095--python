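import numpy as np
import pytest

from pusim.locus import BinGrid, Origin, Barrier, LocusConfig, SimulationParams


def make_random_small_config(rng: np.random.Generator) -> LocusConfig:
    """A small random locus for engine cross-checks: <=3 origins, <=1 barrier."""
    bs = 100
    n = int(rng.integers(30, 60))
    grid = BinGrid(0, n * bs, bs)
    origins = []
    for i in range(int(rng.integers(1, 4))):
        origins.append(Origin(
            position=float(rng.integers(0, n) * bs),
            efficiency=1.0 if i == 0 else float(rng.uniform(0.5, 1.0)),
            mean_firing_time=float(rng.uniform(0, 3)),
            firing_time_sd=float(rng.uniform(0, 1)),
        ))
    barriers = []
    if rng.random() < 0.8:
        kind = "restart" if rng.random() < 0.5 else "pause"
        offset = 0.0
        if kind == "restart" and rng.random() < 0.5:
            offset = -float(rng.integers(0, 3) * bs)
        barriers.append(Barrier(
            position=float(rng.integers(1, n - 1) * bs),
            blocks_direction="rightward" if rng.random() < 0.5 else "leftward",
            kind=kind,
            arrest_probability=float(rng.uniform(0, 1)),
            delay=float(rng.uniform(0, 5)),
            restart_offset=offset,
        ))
    return LocusConfig(grid=grid, origins=origins, barriers=barriers)


@pytest.fixture
def two_origin_barrier_config():
    """Deterministic closed-form scenario: origins at 0/30 kb firing at t=0,
    restart barrier at 3 kb blocking rightward forks (p=1, D=11 min)."""
    grid = BinGrid(0, 30_000, 300)
    return LocusConfig(
        grid=grid,
        origins=[Origin(0.0), Origin(30_000.0)],
        barriers=[Barrier(3_000.0, "rightward", kind="restart",
                          arrest_probability=1.0, delay=11.0)],
    )


@pytest.fixture
def default_params():
    return SimulationParams()
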