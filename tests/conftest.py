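import pytest

import retex as rx


@pytest.fixture(scope="session")
def small_syn():
    """A ~90 kb synthetic genome with the default 12-family mix, no embedded genes."""
    cfg = rx.SyntheticGenomeConfig(
        chrom_lengths={"chr1": 60_000, "chr2": 30_000},
        n_genes=10, embedded_repeat_fraction=0.0, rng_seed=7)
    return rx.make_genome(cfg)


@pytest.fixture(scope="session")
def small_db(small_syn):
    return rx.build_repeat_db(small_syn.genome, small_syn.annotations)


@pytest.fixture(scope="session")
def small_index(small_db):
    return rx.SeedIndex(small_db)


@pytest.fixture(scope="session")
def aligner_cfg():
    return rx.AlignerConfig()
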