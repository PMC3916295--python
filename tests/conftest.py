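import numpy as np
import pytest

from overlapsv.config import PipelineConfig
from overlapsv import simulate as sim
from overlapsv.pipeline import run_pipeline


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


def make_benchmark(
    counts,
    lengths,
    seed,
    coverage=20.0,
    ploidy=1,
    het_fraction=0.0,
    plant_kwargs=None,
):
    """Simulate a reference with planted SVs and an overlapping-read library."""
    rng = np.random.default_rng(seed)
    ref = sim.generate_reference(lengths, seed=rng)
    haps, truth = sim.plant_svs(
        ref, counts, ploidy=ploidy, het_fraction=het_fraction, seed=rng,
        **(plant_kwargs or {}),
    )
    pairs = list(
        sim.simulate_read_pairs(haps, coverage=coverage, seed=rng)
    )
    return ref, haps, truth, pairs


@pytest.fixture(scope="session")
def deletion_benchmark(config):
    """Scaled deletion benchmark: 100 deletions on 1 Mb at coverage 20.

    Shared by the recall, exactness and orientation-invariance checks.
    """
    ref, haps, truth, pairs = make_benchmark({"deletion": 100}, {"chr1": 1_000_000}, seed=42)
    result = run_pipeline(ref, pairs, config)
    return ref, truth, pairs, result
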