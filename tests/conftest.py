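import numpy as np
import pytest
from hypothesis import settings

import sdatools as st

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rules():
    return st.build_pairing_rules()


@pytest.fixture(scope="session")
def small_cds():
    """A handful of hand-written CDS with known codon content."""
    return st.CDSSet(
        {
            "met_lys": "ATGAAATGA",
            "arg_rich": "ATGAGAAGACGGTGA",
            "mixed": "ATGGCTGCCAAGAAAGGTTTCTAA",
        }
    )


@pytest.fixture(scope="session")
def null_cohort():
    """A no-effect two-condition cohort shared by read-only tests."""
    return st.generate_cohort(st.SimConfig(seed=11, n_genes=80, mean_cds_codons=150))


@pytest.fixture(scope="session")
def null_matrix(null_cohort):
    return st.cohort_sda_matrix(null_cohort)


def random_sum1_weights(rng, side):
    vals = rng.gamma(2.0, 1.0, size=len(st.SENSE_CODONS))
    vals /= vals.sum()
    return st.CodonWeights(
        side, dict(zip(st.SENSE_CODONS, vals)), st.Normalization.SUM1
    )
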