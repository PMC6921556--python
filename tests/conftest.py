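import numpy as np
import pandas as pd
import pytest

from nidyn.core import CATEGORIES, CountMatrix
from nidyn.simulate import SimulationConfig, make_genome_annotation, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast study-shaped configuration: 60 planted + 140 null genes."""
    return SimulationConfig(
        n_genes=200,
        genome_length=1_000_000,
        n_per_category={c: 10 for c in CATEGORIES},
        n_replicates=3,
        chip_reads_per_sample=50_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def annotation(small_config):
    return make_genome_annotation(small_config)


@pytest.fixture(scope="session")
def counts_truth(annotation, small_config):
    return simulate_counts(annotation, small_config)


def make_count_matrix(mat: np.ndarray, conditions: list[str]) -> CountMatrix:
    """Wrap an array into a CountMatrix; samples named <cond>_r<k>."""
    seen: dict[str, int] = {}
    cols = []
    for cond in conditions:
        seen[cond] = seen.get(cond, 0) + 1
        cols.append(f"{cond}_r{seen[cond]}")
    df = pd.DataFrame(
        np.asarray(mat, dtype=int),
        columns=cols,
        index=pd.Index([f"g{i}" for i in range(len(mat))], name="gene_id"),
    )
    return CountMatrix(counts=df, design=dict(zip(cols, conditions)))
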