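import pytest

from isohyl.chem import builtin_registry, builtin_small_molecules
from isohyl.peptides import parse_peptide
from isohyl.simulate import SimConfig, make_proteome, simulate_run


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def small_molecules():
    return builtin_small_molecules()


@pytest.fixture(scope="session")
def collagen():
    """The benchmark collagen peptide with 3x Hyp and the 5-Hyl site."""
    return parse_peptide("GFP[hyp]GTP[hyp]GLP[hyp]GFK[hyl5]GIR", charge=2)


@pytest.fixture(scope="session")
def sim_small():
    """A small seeded proteome + LC-MS run shared across tests."""
    cfg = SimConfig(seed=11, n_proteins=6)
    proteome, truth = make_proteome(cfg)
    run, scan_truth = simulate_run(proteome, truth, cfg)
    return cfg, proteome, truth, run, scan_truth
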