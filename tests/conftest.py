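from pathlib import Path

import pytest

import mammoquant as mq

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def glycolysis_gmt() -> Path:
    return DATA_DIR / "glycolysis.gmt"


@pytest.fixture(scope="session")
def small_experiment():
    """A modest spiked experiment reused across modules."""
    cfg = mq.ProteomicsSimConfig(n_proteins=300, frac_diff=0.05, seed=11)
    peptides, truth = mq.generate_itraq_experiment(cfg)
    return cfg, peptides, truth
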