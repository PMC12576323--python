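import numpy as np
import pytest

from asymclr.matched_data import DifferenceData, DosageMatrix, MatchedCohort, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dosages(values, chrom="1", spacing=1_000_000):
    """Small helper: dosage matrix from a plain array with auto ids."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = [f"s{i}" for i in range(n)]
    variants = [
        VariantRecord(chrom=chrom, pos=(j + 1) * spacing, id=f"v{j + 1}")
        for j in range(m)
    ]
    return DosageMatrix(samples=samples, variants=variants, values=values)


@pytest.fixture
def small_panel():
    """Two tiny cohorts bound to a 3-variant dosage matrix."""
    values = np.array([
        [0.0, 1.0, 2.0],
        [1.0, 1.0, 0.0],
        [2.0, 0.0, 1.0],
        [0.0, 2.0, 1.0],
        [1.0, 0.0, 0.0],
        [2.0, 1.0, 2.0],
        [0.0, 0.0, 1.0],
        [1.0, 2.0, 0.0],
    ])
    dosages = make_dosages(values)
    cohorts = [
        MatchedCohort("alpha", [("a1", "s0", "s1"), ("a2", "s2", "s3")]),
        MatchedCohort("beta", [("b1", "s4", "s5"), ("b2", "s6", "s7")]),
    ]
    return dosages, cohorts


def normal_diff(rng, n, mean=0.2, sd=1.0):
    return DifferenceData(rng.normal(mean, sd, size=(n, 1)))
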