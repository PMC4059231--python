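import numpy as np
import pytest

from telenhancer.core import GeneLocus, GenomeModel, Interval
from telenhancer.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Default synthetic dataset (200 enhancers, half tele) with truth."""
    return simulate_dataset(SimConfig(seed=7), tmp_path_factory.mktemp("sim"))


@pytest.fixture()
def rng():
    return np.random.default_rng(11)


@pytest.fixture()
def toy_genome(rng):
    """100 kb single-chromosome genome with two genes and random sequence."""
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100_000))
    genes = [
        GeneLocus(
            "gA", "chr1", "+", 20_000,
            Interval("chr1", 20_000, 30_000, name="gA"),
            [Interval("chr1", 20_000, 21_000), Interval("chr1", 29_000, 30_000)],
        ),
        GeneLocus(
            "gB", "chr1", "-", 70_000,
            Interval("chr1", 60_000, 70_000, name="gB"),
            [Interval("chr1", 60_000, 61_000)],
        ),
    ]
    return GenomeModel(
        chromosomes={"chr1": 100_000},
        genes=genes,
        sequence={"chr1": seq},
        tissue_names=["heart", "brain"],
    )
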