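import pytest

from rhdocall.simulate import SimConfig, simulate_pedigree


@pytest.fixture
def planned_family():
    """A well-powered simulated family: 20 FF + 15 paternal + 15 maternal sites."""
    cfg = SimConfig(
        n_ff_snps=20,
        n_paternal_snps=15,
        n_maternal_snps=15,
        ff_true=0.10,
        depth=5000.0,
        depth_model="fixed",
        seed=42,
        fetus_paternal="H0",
        fetus_maternal="H1",
    )
    return simulate_pedigree(cfg)


@pytest.fixture
def random_family():
    """A family with genotypes drawn from Hardy-Weinberg at MAF 0.4."""
    cfg = SimConfig(n_snps=100, maf=0.4, ff_true=0.12, depth=1000.0, seed=7)
    return simulate_pedigree(cfg)
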