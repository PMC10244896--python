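import pytest

from sealrep.data import filter_single_season
from sealrep.multistate import McmcConfig, build_design, fit_multistate
from sealrep.simulate import SimConfig, simulate_colony


def filtered_tables(colony):
    """Apply the two-sighting study filter and subset the covariate tables."""
    histories = filter_single_season(colony.histories)
    keep = {h.female_id for h in histories}
    females = colony.female_table[colony.female_table.female_id.isin(keep)]
    pups = colony.pup_table[colony.pup_table.female_id.isin(keep)]
    return histories, females.reset_index(drop=True), pups.reset_index(drop=True)


@pytest.fixture(scope="session")
def default_colony():
    """One study-scale colony at the default generating values."""
    return simulate_colony(SimConfig(), seed=20020)


@pytest.fixture(scope="session")
def small_colony():
    """A small colony for quick fits."""
    cfg = SimConfig(
        n_females=60,
        n_occasions=9,
        recruit_ages=(4, 5, 6),
        recruit_age_probs=(0.3, 0.4, 0.3),
    )
    return simulate_colony(cfg, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_colony):
    """A quick multistate fit shared across diagnostic tests."""
    histories, females, _ = filtered_tables(small_colony)
    design = build_design(histories, females, standardizers=small_colony.standardizers)
    config = McmcConfig(n_chains=2, n_burn=300, n_iter=900, thin=3, seed=42)
    samples = fit_multistate(design, "linear", config)
    return samples, design
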