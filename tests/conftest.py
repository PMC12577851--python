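import pytest

from refweave import FilterConfig, PipelineConfig, run
from refweave.simulate import SimulationConfig, simulate_instance

# a small but complete same-species instance: 60 kb genome, one repeat-embedded
# gap, 25x reads — enough structure for every stage, fast enough for unit tests
SMALL = dict(
    genome_length=60_000,
    repeat_count=2,
    repeat_length=3_000,
    n_gaps=1,
    gap_length=5_000,
    depth=25,
    read_mean_length=6_000,
    read_length_sd=1_000,
)


@pytest.fixture(scope="session")
def small_instance():
    return simulate_instance(SimulationConfig(seed=11, **SMALL))


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(mode="same", filters=FilterConfig(min_output_length=20_000))


@pytest.fixture(scope="session")
def small_result(small_instance, small_config):
    ts = small_instance
    return run(ts.reference, ts.contigs, ts.reads, small_config)
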