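import numpy as np
import pytest

from lepitrend import pipeline, simdata


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but complete simulated scheme shared across tests."""
    rng = np.random.default_rng(1234)
    specs = simdata.default_species_pool(4, rng, annual_trend=np.log(0.98))
    config = simdata.SimConfig(
        species_specs=specs, n_sites=12, n_years=8, seed=1234
    )
    return simdata.simulate_monitoring(config)


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_sim):
    """Completed counts and flight models for the tiny scheme."""
    completed, models, skipped = pipeline.complete_all_species(tiny_sim)
    return {"sim": tiny_sim, "completed": completed, "models": models,
            "skipped": skipped}
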