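"""Shared fixtures: small synthetic screens processed through the pipeline.

Fixtures are session-scoped — screens are generated once and reused. The
non-targeting pool is kept at 60 guides even in scaled-down screens because
the guide-vs-control rank test needs a control group that large for its
p-value floor to sit below the 0.001 significance threshold.
"""

import numpy as np
import pytest

import morphoscreen as ms
from morphoscreen.synthetic import ScreenConfig, generate_screen


@pytest.fixture(scope="session")
def small_screen():
    """60-gene screen with defaults otherwise scaled down for speed."""
    cfg = ScreenConfig(
        n_genes=60,
        n_nontargeting=60,
        cells_per_guide_per_plate=15,
        n_features=150,
        seed=5,
    )
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_screen):
    cells, _, _, _ = small_screen
    return ms.profile_pipeline(cells)


@pytest.fixture(scope="session")
def small_caller(small_screen, small_profiles):
    _, feats, _, truth = small_screen
    return ms.EmpiricalFDRHitCaller().fit(
        small_profiles["guide_screen"], feats, truth.zero_tpm_genes
    )


@pytest.fixture(scope="session")
def null_screen():
    """Screen with no gene effects and no cutting signature: a global null."""
    cfg = ScreenConfig(
        n_genes=40,
        n_nontargeting=60,
        cells_per_guide_per_plate=10,
        n_features=150,
        frac_effect_genes=0.0,
        effect_size=0.0,
        cutting_effect_size=0.0,
        seed=11,
    )
    return generate_screen(cfg)
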