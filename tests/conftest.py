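import numpy as np
import pandas as pd
import pytest

from aseqc.bln import FitConfig
from aseqc.simulate import SimulationConfig, simulate_sample


@pytest.fixture
def quick_config() -> FitConfig:
    """Fit settings sized for fast unit tests (small min_genes)."""
    return FitConfig(min_genes=20)


@pytest.fixture
def small_sample() -> pd.DataFrame:
    """One clean synthetic sample, 400 genes, fixed seed."""
    cfg = SimulationConfig(n_genes=400, mu=0.1, sigma=0.3, seed=11)
    return simulate_sample(cfg, "S1")


@pytest.fixture
def small_cohort() -> pd.DataFrame:
    """Six clean samples plus one heavily contaminated one, 400 genes each."""
    frames = []
    clean = SimulationConfig(n_genes=400, mu=0.1, sigma=0.3, seed=7)
    for rep in range(6):
        frames.append(simulate_sample(clean, f"C{rep}", stream=(0, rep)))
    dirty = SimulationConfig(n_genes=400, mu=0.1, sigma=0.3, seed=7, contamination=0.3)
    frames.append(simulate_sample(dirty, "X0", stream=(1, 0)))
    return pd.concat(frames, ignore_index=True)


def make_gene_records(ref, total, sample_id="S1") -> pd.DataFrame:
    """Assemble a gene-level record table from raw count arrays."""
    ref = np.asarray(ref)
    total = np.asarray(total)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "gene_id": [f"g{i}" for i in range(len(ref))],
            "ref_count": ref,
            "alt_count": total - ref,
            "total_count": total,
        }
    )
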