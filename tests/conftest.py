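import pytest

from lovis import SimulationConfig, run_pipeline, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """A fast cohort: 200 kb genome, 40 clones, ~20k reads."""
    return SimulationConfig(
        seed=11,
        genome_length=200_000,
        n_genes=30,
        n_clones=40,
        depth=2500,
        n_secondary_clones=10,
        secondary_depth=800,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    ref, truth, reads = simulate(small_cfg)
    return small_cfg, ref, truth, reads


@pytest.fixture(scope="session")
def small_result(small_sim):
    cfg, ref, truth, reads = small_sim
    return run_pipeline(reads, ref.genome, truth.sample_sheet)


@pytest.fixture(scope="session")
def default_sim():
    """The canonical fixture: 2 Mb genome, 300 clones, 8 samples, ~150k reads."""
    cfg = SimulationConfig(seed=13)
    ref, truth, reads = simulate(cfg)
    return cfg, ref, truth, reads


@pytest.fixture(scope="session")
def default_result(default_sim):
    cfg, ref, truth, reads = default_sim
    return run_pipeline(reads, ref.genome, truth.sample_sheet)


def detectable_site_keys(truth, animal):
    """Truth site keys for clones whose emitted read total passes the
    min-count rule (total >= number of samples for the animal)."""
    cols = truth.sample_sheet.index[truth.sample_sheet["animal"] == animal]
    keys = set()
    for cid, c in truth.clones[truth.clones["animal"] == animal].iterrows():
        if truth.emitted.loc[cid, cols].sum() >= len(cols):
            keys.add((c["chrom"], c["pos"], c["strand"], c["index_label"]))
    return keys
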