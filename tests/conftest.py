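import numpy as np
import pytest

import paleogut as pg


@pytest.fixture(scope="session")
def panel():
    """Small shared reference panel (8 taxa, 3 kb each)."""
    return pg.build_reference_panel(8, seed=11, gc=0.5, length=3000)


@pytest.fixture(scope="session")
def tree(panel):
    return pg.TaxonomyTree.from_panel(panel)


@pytest.fixture(scope="session")
def damaged_sample(panel):
    """One faecal sample with heavy, known damage, plus its truth table."""
    spec = pg.CommunitySpec(
        "brs", "faecal_interior", {t: 1 / 8 for t in panel.taxon_ids}, depth=3000
    )
    params = pg.DamageParams(delta_ss=0.4, delta_ds=0.01, q=0.6, epsilon=0.001)
    rs, truth = pg.simulate_sample(panel, spec, params, seed=3)
    return rs, truth, params


@pytest.fixture
def rng():
    return np.random.default_rng(0)
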