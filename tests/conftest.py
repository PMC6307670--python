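import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tehop.simulate import default_config, simulate_world  # noqa: E402

EQUAL_RATES = {s: 3.5e-9 for s in ("flyA", "flyB", "bee", "antA", "antB")}


@pytest.fixture(scope="session")
def small_world():
    """A reduced five-species world with one horizontally acquired element
    (focal entry 2.5 Mya) — shared across tests that only read it."""
    cfg = default_config(seed=11, n_nuclear_genes=60, gene_length_codons=200,
                         rates=dict(EQUAL_RATES), max_copies=120,
                         transposition_rate=400.0,
                         include_brother_pairs=False, n_decoy_tes=2,
                         genome_length=120_000, genome_copy_cap=15)
    return simulate_world(cfg)


@pytest.fixture(scope="session")
def brother_world():
    from tehop.simulate import simulate_brother_pairs

    return simulate_brother_pairs(default_config(seed=5))
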