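from collections import Counter

import numpy as np
import pytest
from scipy.stats import chi2, chi2_contingency

import ibdmap as im
from ibdmap.haplotypes import DegenerateTestError


def build_case(pair_specs, n_snps=4, alleles=None):
    """Small hand-built cohort: pair_specs = [(a, b, h_a, h_b, lo, hi)]."""
    subjects = ["A", "B", "C", "D", "E", "F"]
    status = dict(zip(subjects, ["case"] * 3 + ["control"] * 3))
    pheno = im.Phenotype(status)
    positions = np.arange(100, 100 + 10 * n_snps, 10)
    if alleles is None:
        alleles = np.zeros((len(subjects), n_snps, 2), dtype=np.int8)
    panel = im.SNPPanel("1", [f"s{j}" for j in range(n_snps)], positions,
                        subjects, alleles.sum(axis=2).astype(np.int8))
    phased = im.PhasedHaplotypes("1", positions, subjects, alleles)
    segments = [
        im.IBDSegment(a, ha, b, hb, "1", int(positions[lo]), int(positions[hi]))
        for a, b, ha, hb, lo, hi in pair_specs
    ]
    pairs = im.build_pairs(pheno, segments)
    matrix = im.build_ibd_matrix(segments, panel, pairs)
    return pheno, phased, matrix


class TestHaplotypeStructure:
    def test_hand_extraction_uses_named_slot(self):
        alleles = np.zeros((6, 2, 2), dtype=np.int8)
        alleles[0, :, 0] = [0, 1]  # A slot 1
        alleles[0, :, 1] = [1, 1]  # A slot 2 (homolog, must not be counted)
        alleles[1, :, 1] = [0, 1]  # B slot 2
        pheno, phased, matrix = build_case(
            [("A", "B", 1, 2, 0, 1)], n_snps=2, alleles=alleles
        )
        wm = im.window_matrix(matrix, 2)
        counts = im.haplotype_structure(wm, phased, 0)
        assert counts.case_counts == Counter({"01": 2})
        assert counts.control_counts == Counter()

    def test_both_slots_mode_counts_homologs(self):
        alleles = np.zeros((6, 2, 2), dtype=np.int8)
        alleles[0, :, 0] = [0, 1]
        alleles[0, :, 1] = [1, 1]
        alleles[1, :, 1] = [0, 1]
        pheno, phased, matrix = build_case(
            [("A", "B", 1, 2, 0, 1)], n_snps=2, alleles=alleles
        )
        wm = im.window_matrix(matrix, 2)
        counts = im.haplotype_structure(wm, phased, 0, mode="both_slots")
        assert sum(counts.case_counts.values()) == 4
        assert counts.case_counts["11"] == 1  # A's homolog included

    def test_multiset_tally_over_pairs(self):
        alleles = np.zeros((6, 2, 2), dtype=np.int8)
        alleles[0, :, 0] = [0, 1]  # A slot 1 -> "01"
        alleles[1, :, 0] = [0, 1]  # B slot 1 -> "01"
        alleles[2, :, 0] = [1, 1]  # C slot 1 -> "11"
        pheno, phased, matrix = build_case(
            [("A", "B", 1, 1, 0, 1), ("A", "C", 1, 1, 0, 1)],
            n_snps=2, alleles=alleles,
        )
        wm = im.window_matrix(matrix, 2)
        counts = im.haplotype_structure(wm, phased, 0)
        assert counts.case_counts == Counter({"01": 3, "11": 1})

    def test_empty_window_gives_empty_counts(self):
        pheno, phased, matrix = build_case([("A", "B", 1, 2, 0, 0)], n_snps=4)
        wm = im.window_matrix(matrix, 3)
        counts = im.haplotype_structure(wm, phased, 1)  # window 1..3 not IBD
        assert not counts.case_counts and not counts.control_counts

    def test_discordant_pairs_excluded(self):
        pheno, phased, matrix = build_case(
            [("A", "D", 1, 1, 0, 1)], n_snps=2
        )  # A case, D control
        wm = im.window_matrix(matrix, 2)
        counts = im.haplotype_structure(wm, phased, 0)
        assert not counts.case_counts and not counts.control_counts

    def test_uncovered_window_is_error(self):
        pheno, phased, matrix = build_case([("A", "B", 1, 2, 0, 3)], n_snps=4)
        short = im.PhasedHaplotypes(
            "1", phased.positions_bp[:2], phased.subjects,
            phased.alleles[:, :2, :],
        )
        wm = im.window_matrix(matrix, 3)
        with pytest.raises(ValueError, match="cover"):
            im.haplotype_structure(wm, short, 1)

    def test_missing_phased_allele_drops_subject_pair(self):
        alleles = np.zeros((6, 2, 2), dtype=np.int8)
        alleles[0, 1, 0] = -1  # A slot 1 missing at SNP 1
        pheno, phased, matrix = build_case(
            [("A", "B", 1, 1, 0, 1), ("B", "C", 1, 1, 0, 1)],
            n_snps=2, alleles=alleles,
        )
        wm = im.window_matrix(matrix, 2)
        counts = im.haplotype_structure(wm, phased, 0)
        assert sum(counts.case_counts.values()) == 2  # only pair (B, C)


class TestGTest:
    def test_closed_form_value(self):
        res = im.gtest(np.array([[20, 10], [10, 20]]))
        expect_g = 2 * (2 * 20 * np.log(4 / 3) + 2 * 10 * np.log(2 / 3))
        assert res.g == pytest.approx(expect_g, abs=1e-10)
        assert res.g == pytest.approx(6.795964, abs=1e-5)
        assert res.df == 1
        assert res.p == pytest.approx(chi2.sf(expect_g, 1), rel=1e-10)
        assert res.p == pytest.approx(0.00913, abs=5e-5)

    def test_observed_equals_expected_gives_zero(self):
        res = im.gtest(np.array([[5, 10, 15], [5, 10, 15]]))
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_string_degenerate(self):
        counts = im.HaplotypeCounts(0, 2, Counter({"01": 4}), Counter({"01": 2}))
        with pytest.raises(DegenerateTestError):
            im.gtest(counts)

    def test_zero_total_group_row_dropped(self):
        counts = im.HaplotypeCounts(0, 2, Counter({"01": 4, "11": 2}), Counter())
        res = im.gtest(counts)
        assert res.g == pytest.approx(0.0)  # one row left: O == E
        assert res.p == 1.0

    def test_df_modes(self):
        obs = np.array([[5, 9, 2], [7, 1, 6]])
        assert im.gtest(obs, df_mode="as_printed").df == 2
        assert im.gtest(obs, df_mode="contingency").df == 2
        obs3 = np.array([[5, 9, 2, 4], [7, 1, 6, 2]])
        assert im.gtest(obs3, df_mode="as_printed").df == 3

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        obs = rng.integers(1, 30, size=(2, 5))
        g0 = im.gtest(obs).g
        for _ in range(5):
            perm = rng.permutation(5)
            assert im.gtest(obs[:, perm]).g == pytest.approx(g0, rel=1e-12)

    def test_agrees_with_pearson_chi2_for_large_balanced_counts(self):
        # asymptotic equivalence holds near independence: draw both rows
        # from one column distribution so O stays close to E
        rng = np.random.default_rng(8)
        for _ in range(20):
            probs = rng.dirichlet(np.full(4, 20.0))
            obs = np.vstack([rng.multinomial(500, probs) for _ in range(2)])
            if (np.outer(obs.sum(1), obs.sum(0)) / obs.sum() < 20).any():
                continue
            g = im.gtest(obs).g
            chi = chi2_contingency(obs, correction=False).statistic
            if chi > 0:
                assert abs(g - chi) / chi < 0.05

    def test_equal_rows_stay_zero_under_constant_shift(self):
        base = np.array([[3, 7, 5], [3, 7, 5]])
        for c in (1, 10, 100):
            assert im.gtest(base + c).g == pytest.approx(0.0, abs=1e-10)


class TestGTestPermutation:
    def _planted(self):
        alleles = np.zeros((6, 2, 2), dtype=np.int8)
        alleles[0, :, 0] = [0, 1]
        alleles[1, :, 0] = [0, 1]
        alleles[3, :, 0] = [1, 0]
        alleles[4, :, 0] = [1, 0]
        return build_case(
            [("A", "B", 1, 1, 0, 1), ("D", "E", 1, 1, 0, 1)],
            n_snps=2, alleles=alleles,
        )

    def test_identical_counts_give_p_one(self):
        # case strings {01, 10} and control strings {01, 10}: G_obs = 0,
        # and every permuted G >= 0, so the permutation p must be 1
        alleles = np.zeros((6, 2, 2), dtype=np.int8)
        alleles[0, :, 0] = [0, 1]
        alleles[1, :, 0] = [1, 0]
        alleles[3, :, 0] = [0, 1]
        alleles[4, :, 0] = [1, 0]
        pheno, phased, matrix = build_case(
            [("A", "B", 1, 1, 0, 1), ("D", "E", 1, 1, 0, 1)],
            n_snps=2, alleles=alleles,
        )
        wm = im.window_matrix(matrix, 2)
        res = im.gtest_permutation(wm, phased, pheno, 0, n_p=50, seed=1)
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.perm_p == 1.0

    def test_seeded_reproducibility(self):
        pheno, phased, matrix = self._planted()
        wm = im.window_matrix(matrix, 2)
        r1 = im.gtest_permutation(wm, phased, pheno, 0, n_p=100, seed=3)
        r2 = im.gtest_permutation(wm, phased, pheno, 0, n_p=100, seed=3)
        assert r1.perm_p == r2.perm_p and r1.g == r2.g

    def test_sampled_matches_exhaustive(self):
        """Sampled permutation p within 3 SE of the exact enumeration."""
        from itertools import combinations

        pheno, phased, matrix = self._planted()
        wm = im.window_matrix(matrix, 2)
        obs = im.gtest_permutation(wm, phased, pheno, 0, n_p=4000, seed=7)
        # exhaustive oracle over all C(6,3)=20 case labelings, recomputing
        # the G statistic from scratch per labeling
        subjects = list(pheno.status)
        pair_members = [("A", "B"), ("D", "E")]
        strings = {("A", "B"): ["01", "01"], ("D", "E"): ["10", "10"]}
        hits = 0
        total = 0
        for cases in combinations(subjects, 3):
            case_set = set(cases)
            case_cnt, cont_cnt = Counter(), Counter()
            for a, b in pair_members:
                if a in case_set and b in case_set:
                    case_cnt.update(strings[(a, b)])
                elif a not in case_set and b not in case_set:
                    cont_cnt.update(strings[(a, b)])
            counts = im.HaplotypeCounts(0, 2, case_cnt, cont_cnt)
            try:
                g = im.gtest(counts).g
            except DegenerateTestError:
                g = 0.0
            hits += g >= obs.g
            total += 1
        exact = hits / total
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(obs.perm_p - exact) <= 3 * se + 1e-12
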