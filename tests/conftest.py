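import pytest

from faersig.synthetic import SimConfig, simulate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic corpus shared across tests."""
    cfg = SimConfig(seed=11, n_reports=600, focal_drug_share=0.25)
    demo, drug, reac, ther, truth = simulate_corpus(cfg)
    return cfg, demo, drug, reac, ther, truth
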