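import numpy as np
import pytest

from mixsurf import datasets


@pytest.fixture(scope="session")
def study():
    """The bundled 17-run nanoemulsion design and response table."""
    return datasets.load_nanoemulsion()


@pytest.fixture(scope="session")
def published_fits(study):
    """The four published model specifications fitted to the bundled data."""
    from mixsurf import fit

    design, resp = study
    models = datasets.published_models()
    return {name: fit(design, resp[name], spec) for name, spec in models.items()}


@pytest.fixture(scope="session")
def observed_range_goals(study):
    """Minimize-all desirability goals bounded by each response's observed range."""
    from mixsurf import DesirabilityGoal

    _, resp = study
    return {
        name: DesirabilityGoal(
            "minimize", float(resp[name].min()), float(resp[name].max())
        )
        for name in datasets.RESPONSES
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
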