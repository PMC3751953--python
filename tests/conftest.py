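import pytest

from fishdemog.simulate import PopulationConfig, simulate_population


@pytest.fixture(scope="session")
def default_sample():
    """A moderately sized two-morph sample shared by read-only tests."""
    return simulate_population(PopulationConfig(n=2000, seed=42))


@pytest.fixture(scope="session")
def plain_only_config():
    """Single-morph (plain) configuration factory."""
    def make(n=4000, seed=0, z=None, selectivity=15.0, **overrides):
        cfg = PopulationConfig(
            n=n, seed=seed,
            morph_proportions={"plain": 1.0},
            selectivity_min_cm=selectivity,
            **overrides,
        )
        cfg.morphs = {"plain": cfg.morphs["plain"]}
        if z is not None:
            cfg.morphs["plain"].z = z
        return cfg
    return make
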