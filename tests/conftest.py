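import numpy as np
import pytest

from genoenc import GenotypeMatrix, TraitVector


def make_genotypes(columns, oriented=True, sample_prefix="s", marker_prefix="m"):
    """Build a GenotypeMatrix from a list of per-marker category columns."""
    values = np.asarray(columns, dtype=np.int8).T
    n, m = values.shape
    return GenotypeMatrix(
        tuple(f"{sample_prefix}{i}" for i in range(n)),
        tuple(f"{marker_prefix}{j}" for j in range(m)),
        values,
        oriented=oriented,
    )


def make_traits(values, sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return TraitVector(tuple(f"{sample_prefix}{i}" for i in range(len(values))), values)


@pytest.fixture
def toy6():
    """Single marker, categories [0,0,1,1,2,2], traits [1,2,3,5,8,10].

    Group means: E0=1.5, E1(target)=4.0, E2=9.0; overall mean 29/6;
    hybrid-two midpoint 5.25.
    """
    G = make_genotypes([[0, 0, 1, 1, 2, 2]])
    y = make_traits([1, 2, 3, 5, 8, 10])
    return G, y


@pytest.fixture
def toy9():
    """Two markers covering each (a, b) cell once, trait = 3a + b + 1.

    Corner cells map to 1,3,7,9; pooled marginal means give edges
    (1,0)->4, (0,1)->2, (2,1)->8, (1,2)->6 and center 5, which also equal
    the hybrid-two corner averages.
    """
    cats = [(a, b) for a in (0, 1, 2) for b in (0, 1, 2)]
    G = make_genotypes(
        [[a for a, _ in cats], [b for _, b in cats]]
    )
    y = make_traits([3 * a + b + 1 for a, b in cats])
    return G, y
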