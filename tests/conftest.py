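import numpy as np
import pytest

from nanocon import MethylInstance, SimConfig, simulate_dataset


def make_instance(motif: str = "ACGTACCTACGTA", label: int = 1,
                  chrom: str = "chr1", pos: int = 100, strand: str = "+",
                  read_id: str = "read0", means=None, stds=None,
                  lens=None) -> MethylInstance:
    """Hand-buildable valid instance with sensible defaults."""
    return MethylInstance(
        chrom=chrom, pos=pos, strand=strand, read_id=read_id, motif=motif,
        means=tuple(means) if means is not None else tuple(float(i) for i in range(13)),
        stds=tuple(stds) if stds is not None else (0.5,) * 13,
        lens=tuple(lens) if lens is not None else (8,) * 13,
        label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """400 separable instances (delta=3, sigma=1), session-cached."""
    instances, _ = simulate_dataset(
        SimConfig(n_instances=400, proportion=0.25, delta=3.0,
                  noise_sigma=1.0, seed=7))
    return instances
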