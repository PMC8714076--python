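import numpy as np
import pytest

from chromlink.intervals import GenomicInterval, GeneModel, Peak
from chromlink.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def simdata():
    """Default synthetic dataset without sequence (fast, reused across tests)."""
    return simulate(SimulationConfig(seed=7, with_sequence=False))


@pytest.fixture(scope="session")
def emitted_dataset(tmp_path_factory):
    """Full default dataset (with sequence) written to disk once."""
    from chromlink.simulate import emit

    outdir = tmp_path_factory.mktemp("simdata")
    data = simulate(SimulationConfig(seed=7))
    paths = emit(data, str(outdir))
    return data, paths


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=100_000):
    peaks = []
    for i in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(50, 500))
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, start + width),
                summit=start + int(rng.integers(0, width)),
                pvalue=float(10.0 ** -rng.uniform(0.5, 12)),
                replicate_id=f"rep{int(rng.integers(1, 3))}",
                name=f"p{i}",
            )
        )
    return peaks
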