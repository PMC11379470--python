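import numpy as np
import pytest

import ibdmap as im


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate simulated cohort with a planted causal region.

    Region spans SNP indices 20..29 (positions 1.20-1.29 Mb at 10 kb
    spacing starting at 1 Mb).
    """
    cfg = im.SimConfig(
        n_case=12,
        n_control=12,
        m=80,
        base_rate=0.08,
        enrichment=8.0,
        causal_region=(1_200_000, 1_290_000),
        seed=11,
    )
    return im.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fixture_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    paths = im.write_fixture(d, small_cohort)
    return paths


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    pairs = im.build_pairs(small_cohort.phenotype, small_cohort.segments)
    matrix = im.build_ibd_matrix(small_cohort.segments, small_cohort.panel, pairs)
    return pairs, matrix


@pytest.fixture()
def four_subject_example():
    """Cases {A,B}, controls {C,D}; only pair {A,B} is IBD at the single SNP.

    Exhaustive enumeration over the C(4,2)=6 case labelings gives a
    permutation p of exactly 1/6 (D >= 1 only when {A,B} are the cases).
    """
    pheno = im.Phenotype(
        {"A": "case", "B": "case", "C": "control", "D": "control"}
    )
    seg = im.IBDSegment("A", 1, "B", 2, "1", 100, 200)
    panel = im.SNPPanel(
        "1", ["s1"], np.array([150]), ["A", "B", "C", "D"],
        np.zeros((4, 1), dtype=np.int8),
    )
    pairs = im.build_pairs(pheno, [seg])
    matrix = im.build_ibd_matrix([seg], panel, pairs)
    return pheno, panel, pairs, matrix


def random_sparse_matrix(rng, n_rows, m, density=0.3):
    """Random binary CSR indicator matrix for brute-force comparisons."""
    from scipy import sparse

    dense = (rng.random((n_rows, m)) < density).astype(np.uint8)
    return dense, sparse.csr_matrix(dense)
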