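import pytest

from oviva_cea import SynthConfig, generate_trial, synth


@pytest.fixture(scope="session")
def unit_costs():
    return synth.default_unit_costs()


@pytest.fixture(scope="session")
def small_trial():
    """A small trial with the preset's missingness and deaths."""
    return generate_trial(SynthConfig.oviva(n_per_arm=40, seed=42))


@pytest.fixture(scope="session")
def complete_trial():
    """A fully observed small trial (no missingness, no deaths)."""
    cfg = SynthConfig.oviva(
        n_per_arm=40, seed=7, death_prob=0.0, resource_missing_prob=0.0,
        missing_prob={d: 0.0 for d in (0, 14, 42, 120, 365)})
    return generate_trial(cfg)
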