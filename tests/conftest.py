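import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from macrosat._seq import random_dna

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_cpg_reference(n_sites: int, seed: int = 0, spacing: int = 6) -> str:
    """Reference with exactly ``n_sites`` CpGs separated by CpG-free spacers."""
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_sites):
        parts.append(random_dna(spacing, rng).replace("CG", "CA") + "CG")
    parts.append(random_dna(spacing, rng).replace("CG", "CA"))
    return "".join(parts)


def cyclic_equal(a, b) -> bool:
    """Equality of two sequences as circular words (segmentation register
    of a tandem repeat is arbitrary)."""
    a, b = list(a), list(b)
    return len(a) == len(b) and any(a == b[i:] + b[:i] for i in range(len(b)))


@pytest.fixture(scope="session")
def planted_locus():
    """One study-condition locus: 7-monomer array planted in 200 kb."""
    from macrosat import seqsim

    spec = seqsim.default_array_spec(seed=0)
    array, truth = seqsim.generate_array(spec)
    genome, _ = seqsim.plant_features(200_000, [(array, 80_000)], seed=1000)
    return genome, truth.shifted(80_000), spec
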