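import numpy as np
import pandas as pd
import pytest

from gwaselect.io_formats import GeneticMap, HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(haplotypes: np.ndarray,
               positions=None,
               chrom: str = "1") -> HaplotypePanel:
    """Wrap a raw 0/1 matrix (rows = haplotypes, must be even) as a panel."""
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    n_hap, n_sites = haplotypes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    variants = pd.DataFrame({
        "id": [f"v{j:05d}" for j in range(n_sites)],
        "chrom": chrom,
        "pos": np.asarray(positions, dtype=int),
        "ref": "A",
        "alt": "G",
    })
    samples = [f"s{i:04d}" for i in range(n_hap // 2)]
    return HaplotypePanel(haplotypes=haplotypes, variants=variants,
                          samples=samples)


@pytest.fixture
def small_panel(rng):
    return make_panel(rng.integers(0, 2, size=(20, 12)))


@pytest.fixture
def uniform_map():
    def _make(positions, cm_per_bp=1e-6):
        return GeneticMap.uniform(positions, cm_per_bp)
    return _make
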