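import logging

import numpy as np
import pytest

from rehoscales.imaging import clean_run
from rehoscales.reho import regional_means, reho_map, zscore_map
from rehoscales.synthdata import (
    SimulationConfig,
    make_atlas,
    make_cohort,
    make_expression_bundle,
    synthetic_effect_map,
)

logging.getLogger("rehoscales").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_config():
    """Small grid / short run for fast structural tests."""
    return SimulationConfig(
        seed=11,
        grid_dims=(12, 12, 12),
        n_timepoints=60,
        n_per_group=(4, 4),
        n_regions=(16, 4, 2),
    )


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config):
    return make_atlas(tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tiny_atlas):
    return make_cohort(tiny_config, tiny_atlas)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config, tiny_atlas):
    tmap = synthetic_effect_map(tiny_atlas, tiny_config.effect_regions, seed=5)
    return make_expression_bundle(tiny_config, tiny_atlas, tmap), tmap


def regional_features(runs, motions, atlas, scale):
    """Clean -> ReHo -> z-score -> regional means, for each subject."""
    rows = []
    for run, motion in zip(runs, motions):
        cleaned = clean_run(run, atlas.mask, motion)
        zmap = zscore_map(reho_map(cleaned, atlas.mask))
        rows.append(regional_means(zmap, atlas, scale).values)
    return np.array(rows)
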