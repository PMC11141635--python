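import numpy as np
import pandas as pd
import pytest

from complexdep import (
    EmbeddedComplex,
    LineageSpec,
    ParalogPair,
    ScreenConfig,
    generate_screen,
)


@pytest.fixture(scope="session")
def embedded_bundle():
    """Small screen with one embedded selective complex and a redundant
    paralog pair; shared read-only across tests."""
    members = tuple(f"GENE{i:04d}" for i in range(10, 18))
    cfg = ScreenConfig(
        n_genes=400,
        n_common_essential=100,
        lineages=(LineageSpec("neuroblastoma", 15, subgroup=True), LineageSpec("other", 45)),
        embedded_complexes=(EmbeddedComplex("TARGET_COMPLEX", members, 0.8),),
        n_decoy_sets=15,
        paralog_pairs=(ParalogPair("GENE0001", "GENE0002", slope=0.25),),
        seed=11,
    )
    return generate_screen(cfg)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(7)
    genes = [f"g{i:02d}" for i in range(20)]
    lines = [f"l{i:02d}" for i in range(10)]
    return pd.DataFrame(rng.normal(size=(20, 10)), index=genes, columns=lines)
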