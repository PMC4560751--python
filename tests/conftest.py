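import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import panelforge as pf
from panelforge.types import MISSING, GenotypeMatrix, VariantSite

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(genotype, depth=None, samples=None, sites=None,
                repeat_classes=None, categories=None):
    """Build a GenotypeMatrix from plain nested lists."""
    genotype = np.asarray(genotype, dtype=np.int8)
    n_sites, n_samples = genotype.shape
    if depth is None:
        depth = np.full(genotype.shape, 30, dtype=np.int32)
    if samples is None:
        samples = [f"S{j}" for j in range(n_samples)]
    if sites is None:
        bases = ("A", "C", "G", "T")
        sites = []
        for i in range(n_sites):
            kwargs = {}
            if repeat_classes is not None:
                kwargs["repeat_class"] = pf.RepeatClass(repeat_classes[i])
            if categories is not None:
                kwargs["functional_category"] = pf.FunctionalCategory(
                    categories[i])
            sites.append(VariantSite(chrom="1", pos=100 + i,
                                     ref_allele=bases[i % 4],
                                     alt_allele=bases[(i + 1) % 4], **kwargs))
    return GenotypeMatrix(sites, samples, genotype, np.asarray(depth))


def full_truth(matrix, genotype=None):
    """ArrayTruth covering every cell (defaults to the matrix's genotypes)."""
    g = matrix.genotype if genotype is None else np.asarray(genotype,
                                                            dtype=np.int8)
    return pf.ArrayTruth(g.copy())


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy simulated cohort shared by read-only tests."""
    return pf.simulate_cohort(n_samples=60, n_sites=800, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
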