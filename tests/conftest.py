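import numpy as np
import pandas as pd
import pytest

from soypop.vcfio import GenotypePanel
from soypop.sim import SimConfig, simulate_structured_genotypes


def make_panel(dosages, groups=None, chrom="Chr01", start=100, spacing=100):
    """Build a GenotypePanel from a raw dosage matrix (rows = samples)."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    samples = [f"s{i:02d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + spacing * np.arange(m),
            "ref": "A",
            "alt": "T",
            "vtype": "SNP",
        }
    )
    if groups is not None:
        groups = {s: g for s, g in zip(samples, groups)}
    return GenotypePanel(samples, variants, d, groups=groups)


@pytest.fixture(scope="session")
def small_structured_panel():
    """3 subgroups x 20 diploids, 2000 variants, F=0.1, 2% missing."""
    cfg = SimConfig(n_per_group=20, n_variants=2000, seed=11)
    return simulate_structured_genotypes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
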