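import warnings

import pytest

from cropshift import synth

# arviz emits a refactor FutureWarning on import; irrelevant to the tests
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def corn_world():
    """Small single-crop world drawn from the model-faithful generator."""
    cfg = synth.GeneratorConfig(crops=("corn",), mode="faithful")
    return synth.simulate(n_counties=40, n_years=20, seed=101, config=cfg)


@pytest.fixture(scope="session")
def multi_world():
    """Three-crop misspecified world used by comparison and allocation tests."""
    cfg = synth.GeneratorConfig(crops=("corn", "soybeans", "wheat"), mode="misspecified")
    return synth.simulate(n_counties=30, n_years=18, seed=202, config=cfg)


@pytest.fixture(scope="session")
def corn_fit(corn_world):
    """A converged small fit of the uniform-variance model on corn_world."""
    from cropshift import hier

    model = hier.build_model(
        corn_world.panel_result.panel, corn_world.covariates, hier.ModelSpec(crop="corn")
    )
    return hier.fit(model, chains=2, warmup=300, draws=400, seed=7)
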