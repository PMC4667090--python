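import pytest

from tetrasnp import simpanel
from tetrasnp.simpanel import RILConfig, SimConfig


@pytest.fixture
def small_cfg() -> SimConfig:
    """A small but feature-complete simulation config."""
    return SimConfig(
        n_loci=30,
        locus_length_bp=400,
        n_varieties=12,
        hsv_rate=1 / 40,
        psv_dup_prob=0.3,
        psv_rate=1 / 40,
        snp_rate=1 / 300,
        sequencing_fail_prob=0.2,
        seed=3,
    )


@pytest.fixture
def clean_cfg() -> SimConfig:
    """No elimination / no sequencing failure: every planted site observable."""
    return SimConfig(
        n_loci=25,
        locus_length_bp=400,
        n_varieties=12,
        hsv_rate=1 / 40,
        psv_dup_prob=0.3,
        psv_rate=1 / 40,
        snp_rate=1 / 300,
        elimination_prob_single=0.0,
        elimination_prob_multi=0.0,
        sequencing_fail_prob=0.0,
        seed=11,
    )


@pytest.fixture
def small_panel(small_cfg):
    loci = simpanel.simulate_progenitors(small_cfg)
    return simpanel.simulate_tetraploid_panel(loci, small_cfg)


@pytest.fixture
def clean_panel(clean_cfg):
    loci = simpanel.simulate_progenitors(clean_cfg)
    return simpanel.simulate_tetraploid_panel(loci, clean_cfg)


@pytest.fixture
def ril_cfg() -> RILConfig:
    return RILConfig(n_lines=142, n_markers=8, selfing_generations=6, seed=5)
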