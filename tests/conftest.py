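import numpy as np
import pytest
from hypothesis import settings

from exomestrat.io import CohortDesign, GenotypeMatrix, Variant

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def make_matrix(genotypes, sample_prefix="S", cohort="A", groups=None):
    """Build a GenotypeMatrix (+ design) from a raw (samples x variants) array.

    ``groups`` maps a group label to the number of consecutive samples in it;
    defaults to all samples in group V.
    """
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_variants = genotypes.shape
    variants = [
        Variant(chrom="1", pos=100 + i, id=f"rs{i}", ref="A", alt="G", gene=f"G{i}")
        for i in range(n_variants)
    ]
    samples = [f"{sample_prefix}{i}" for i in range(n_samples)]
    matrix = GenotypeMatrix(variants=variants, samples=samples, genotypes=genotypes)
    if groups is None:
        groups = {"V": n_samples}
    assignments = {}
    it = iter(samples)
    for g, count in groups.items():
        for _ in range(count):
            assignments[next(it)] = (cohort, g)
    return matrix, CohortDesign(assignments)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-variant single cohort with 5% planted V-K differences."""
    from exomestrat.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_variants=300, frac_planted=0.05, seed=11)
    matrix, design, truth = simulate_cohort(cfg, cohort_label="A")
    return cfg, matrix, design, truth
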