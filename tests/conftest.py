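import pytest

from divloc import NullDesign, fixture_binomial, fixture_exponential, realize_discrete


@pytest.fixture(scope="session")
def binom84():
    """Exact Binomial(8, 0.4) pmf over labels 0..8."""
    return fixture_binomial(8, 0.4)


@pytest.fixture(scope="session")
def exp2():
    """Exponential density with rate 2 on (0, inf)."""
    return fixture_exponential(2.0)


@pytest.fixture(scope="session")
def null_design_paper():
    """The designed null-set example: D=10, cZ=0.6, eta1=2, eta2=1/2."""
    return NullDesign.create(D=10.0, cZ=0.6, eta1=2.0, eta2=0.5)


@pytest.fixture(scope="session")
def null_dist(null_design_paper):
    """Its 11-atom discrete realization: four atoms of 0.05, six of 0.1,
    one of 0.2, labeled 1..11."""
    return realize_discrete(null_design_paper)
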