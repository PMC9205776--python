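import numpy as np
import pytest

from loopscreen.matrixcore import BinnedGenome, ContactMatrix


@pytest.fixture
def tiny_genome():
    return BinnedGenome(("chrT",), (1_000,), 100)  # 10 bins


def make_genome(n_bins: int, resolution: int = 100_000,
                chrom: str = "chrS") -> BinnedGenome:
    return BinnedGenome((chrom,), (n_bins * resolution,), resolution)


def random_sparse_matrix(n_bins: int, seed: int, density: float = 0.5,
                         max_count: int = 50) -> ContactMatrix:
    """Random symmetric raw contact matrix with positive marginals."""
    rng = np.random.default_rng(seed)
    genome = make_genome(n_bins)
    iu, ju = np.triu_indices(n_bins)
    vals = rng.integers(0, max_count, size=iu.size).astype(float)
    vals[rng.random(iu.size) > density] = 0.0
    # guarantee no empty rows so balancing masks nothing by surprise
    diag = iu == ju
    vals[diag] = np.maximum(vals[diag], 1.0)
    keep = vals > 0
    return ContactMatrix(genome, "chrS", iu[keep], ju[keep], vals[keep])
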