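import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_928)


@pytest.fixture
def small_gm():
    """Tiny two-population genotype matrix with an outgroup sample.

    Five biallelic sites on one chromosome; popA/popB have two diploids
    each, plus one homozygous outgroup individual.
    """
    from drupepop.genomic_io import GenotypeMatrix

    genotypes = np.array([
        # a1 a2 b1 b2 out
        [0, 1, 2, 2, 0],
        [1, 1, 0, 0, 0],
        [2, 2, 2, 2, 0],   # fixed difference vs outgroup
        [0, 0, 1, 0, 2],   # outgroup homozygous alt -> alt ancestral
        [0, 1, 0, 2, 1],   # heterozygous outgroup -> unknown ancestral
    ], dtype=np.int8)
    return GenotypeMatrix.from_arrays(
        chrom=["chr1"] * 5,
        pos=[10, 25, 40, 55, 70],
        ref=list("ACGTA"),
        alt=list("GTACC"),
        genotypes=genotypes,
        sample_ids=["a1", "a2", "b1", "b2", "out1"],
        pop_of={"a1": "popA", "a2": "popA", "b1": "popB", "b2": "popB",
                "out1": "outgroup"},
    )
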