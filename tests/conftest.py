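import numpy as np
import pytest

from mfgi.genotype_models import classify_pairs
from mfgi.simulation import (
    PopulationConfig,
    ScenarioConfig,
    mendelian_offspring,
    sample_parents,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240610)


@pytest.fixture
def mendelian_pairs(rng):
    """10^5 mother-offspring genotype pairs obeying Mendelian transmission."""
    cfg = PopulationConfig(n_families=100_000, maf=0.2)
    g_m, g_f = sample_parents(cfg, rng)
    g_o = mendelian_offspring(g_m, g_f, rng)
    return g_m, g_o


@pytest.fixture
def small_dataset(rng):
    """Small phenotype/classification pair for entropy checks (n = 40)."""
    g_m, g_f = sample_parents(PopulationConfig(n_families=40, maf=0.3), rng)
    g_o = mendelian_offspring(g_m, g_f, rng)
    cls = classify_pairs(g_m, g_o)
    y = rng.integers(0, 2, size=40)
    return y, cls


def write_pair_table(path, rows, header):
    path.write_text("\n".join(["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]) + "\n")
    return path
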