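import numpy as np
import pytest

from myomatrix import GeneratorConfig, VoxelGrid, generate_muscle_volume


def small_config(seed=0, **overrides):
    """A 9-myofibril, ~19-sarcomere configuration that packs into 64x64x512."""
    params = dict(
        grid=VoxelGrid((512, 64, 64), (20.0, 20.0, 20.0)),
        n_myofibrils=9,
        sarcomere_length=500.0,
        srt_gap_thickness=40.0,
        myofibril_radius_mean=80.0,
        cell_margin=40.0,
        p_single=0.25,
        p_multi=0.2,
        multi_multiplicity_pmf={3: 0.6, 4: 0.4},
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture(scope="session")
def branched_volume():
    """One generated volume with mixed split/merge single/multi events."""
    cfg = small_config(seed=3)
    labels, cell, srt, gt = generate_muscle_volume(cfg)
    return cfg, labels, cell, srt, gt


@pytest.fixture
def rng():
    return np.random.default_rng(42)
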