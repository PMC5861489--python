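import numpy as np
import pytest

from spsnet import ExpressionMatrix, PhenotypeAssignment
from spsnet.subnetworks import Subnetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20180319)


@pytest.fixture
def small_expr(rng):
    """20 genes x 8 samples, positive skewed values."""
    values = np.exp(rng.normal(5.0, 0.8, (20, 8)))
    genes = [f"g{i:02d}" for i in range(20)]
    samples = [f"s{j}" for j in range(8)]
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def small_phenotypes(small_expr):
    return PhenotypeAssignment(frozenset(small_expr.samples[:4]),
                               frozenset(small_expr.samples[4:]))


@pytest.fixture
def worked_example():
    """Hand-checkable 6-gene, 8-patient fixture.

    With theta1=1/3, theta2=2/3 and 6 distinct values per sample the fuzzy
    scores by within-sample rank are exactly [1, 1, 0.8, 0.2, 0, 0].
    """
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"p{j}" for j in range(8)]
    # distinct values within each sample so ranks are unambiguous
    values = np.argsort(rng.random((6, 8)), axis=0).astype(float) * 10 + 5
    expr = ExpressionMatrix(genes, samples, values)
    phen = PhenotypeAssignment(frozenset(samples[:4]), frozenset(samples[4:]))
    sub = Subnetwork("toy::g0", "toy", "g0", frozenset(genes))
    return expr, phen, sub
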