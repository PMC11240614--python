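import numpy as np
import pandas as pd
import pytest

from heterogen import (
    GenotypeMatrix,
    SimulationSpec,
    additive_grm,
    build_designs,
    dominance_grm,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def large_panel():
    """2000 x 5000 HWE panel with its design pair, shared across modules."""
    spec = SimulationSpec(n_individuals=2000, n_snps=5000, seed=42)
    g = simulate_genotypes(spec)
    return g, build_designs(g)


@pytest.fixture(scope="session")
def large_grms(large_panel):
    _, designs = large_panel
    return additive_grm(designs), dominance_grm(designs)


@pytest.fixture
def tiny_genotypes():
    """3 samples x 2 SNPs with one planted missing call."""
    snps = pd.DataFrame(
        {
            "id": ["rs1", "rs2"],
            "chrom": ["1", "2"],
            "pos": [100, 200],
            "a1": ["A", "C"],
            "a2": ["G", "T"],
        }
    )
    calls = np.array([[0, 2], [1, -1], [2, 1]], dtype=np.int8)
    return GenotypeMatrix(samples=["s1", "s2", "s3"], snps=snps, calls=calls)


def make_panel(n, m, seed, **kw):
    kw.setdefault("n_qtn", min(20, m))
    spec = SimulationSpec(n_individuals=n, n_snps=m, seed=seed, **kw)
    g = simulate_genotypes(spec)
    return g, build_designs(g)
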