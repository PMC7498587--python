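import numpy as np
import pytest

import chltrend as ct


@pytest.fixture(scope="session")
def one_region_mask():
    return ct.generate_region_layout(1, (8, 8), seed=11)


@pytest.fixture(scope="session")
def one_region_truth(one_region_mask):
    # fixed, known world: trend +1.2 %/yr, June peak
    return ct.SimulationTruth(
        region_trends={0: 1.2},
        intercepts={0: -1.4},
        seasonal_amplitudes={0: 0.15},
        seasonal_peak_months={0: 6},
        seed=42,
    )


@pytest.fixture(scope="session")
def one_region_field(one_region_truth, one_region_mask):
    return ct.simulate_chl_field(one_region_truth, one_region_mask, 120)


@pytest.fixture(scope="session")
def small_fit(one_region_field, one_region_mask):
    """A shared vague-prior fit on the one-region world (reused to save MCMC time)."""
    design = ct.build_design(one_region_field, one_region_mask, 0, 6)
    cfg = ct.STModelConfig(n_iterations=2000, n_burnin=500, seed=3)
    return ct.fit_st_model(one_region_field, one_region_mask, 0, design, cfg)
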