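import pandas as pd
import pytest

from avipurge import GeneRecord, SimulationConfig, simulate_panel


@pytest.fixture
def slc3a2_like() -> GeneRecord:
    # 529-aa canonical reference anchoring the truncation examples
    return GeneRecord("SLC3A2", 529)


@pytest.fixture
def tm_gene() -> GeneRecord:
    return GeneRecord("TMX", 120, tm_spans=((5, 25), (40, 60), (80, 100)))


@pytest.fixture(scope="session")
def mixed_panel():
    """Small panel with all four event types represented."""
    cfg = SimulationConfig(
        n_neoaves=12,
        n_outgroup=4,
        n_genes=30,
        p_loss=0.3,
        p_trunc=0.2,
        p_dup=0.1,
        rng_seed=11,
    )
    return simulate_panel(cfg)


def status_frame(neo_statuses, out_statuses, gene="G1"):
    """Build a one-gene status table from per-species status lists."""
    rows = [
        (f"n{i}", "neoaves", gene, s, 1) for i, s in enumerate(neo_statuses)
    ] + [
        (f"o{i}", "galloanserae" if i % 2 == 0 else "palaeognathae", gene, s, 1)
        for i, s in enumerate(out_statuses)
    ]
    return pd.DataFrame(
        rows, columns=["species", "clade", "gene", "status", "paralog_index"]
    )
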