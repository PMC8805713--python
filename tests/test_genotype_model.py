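"""Genotype space, binomial dosage likelihoods, and the mixture model."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

import polygt as pg
from polygt.genotype_model import _dosage_error_prob, genotype_log_likelihood


def multiset_oracle(n, k):
    """Brute-force multiset enumeration (independent of the implementation)."""
    return set(itertools.combinations_with_replacement(range(n), k))


class TestGenotypeSpace:
    def test_size_matches_brute_force_enumeration(self):
        for n in range(1, 7):
            for k in range(1, 9):
                assert pg.genotype_space_size(n, k) == len(multiset_oracle(n, k))

    @pytest.mark.parametrize("n,k,expected", [(2, 2, 3), (2, 4, 5), (4, 6, 84)])
    def test_size_examples(self, n, k, expected):
        assert pg.genotype_space_size(n, k) == expected

    @pytest.mark.parametrize("n,k", [(0, 2), (2, 0), (-1, 4)])
    def test_size_rejects_nonpositive(self, n, k):
        with pytest.raises(ValueError):
            pg.genotype_space_size(n, k)

    def test_enumerate_matches_size_and_is_unique(self):
        for n in range(1, 7):
            for k in range(1, 9):
                gts = pg.enumerate_genotypes(n, k)
                assert len(gts) == pg.genotype_space_size(n, k)
                assert len(set(gts)) == len(gts)
                assert all(sum(g.dosages) == k for g in gts)

    def test_enumerate_canonical_order(self):
        assert [g.dosages for g in pg.enumerate_genotypes(2, 2)] == [(2, 0), (1, 1), (0, 2)]
        hexa = [g.dosages for g in pg.enumerate_genotypes(2, 6)]
        assert hexa == [(6 - c, c) for c in range(7)]
        assert len(pg.enumerate_genotypes(3, 2)) == 6

    def test_enumerate_cap_instructs_proposal(self):
        with pytest.raises(ValueError, match="proposal"):
            pg.enumerate_genotypes(64, 16)


class TestSiteLikelihood:
    def test_hom_ref_no_alt_reads_is_certain(self):
        assert pg.site_dosage_log_likelihood(0, 50, 0, 4, 0.0) == pytest.approx(0.0)

    def test_matches_log_factorial_oracle(self):
        # independent pmf: log C(78,30) + 30 log .5 + 48 log .5
        lf = [math.lgamma(i + 1) for i in range(79)]
        expected = lf[78] - lf[30] - lf[48] + 78 * math.log(0.5)
        got = pg.site_dosage_log_likelihood(30, 78, 2, 4, 0.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_duplex_beats_simplex_at_38_percent_vaf(self):
        assert pg.site_dosage_log_likelihood(30, 78, 1, 4, 0.0) < pg.site_dosage_log_likelihood(
            30, 78, 2, 4, 0.0
        )

    def test_contradictory_data_at_zero_error_is_impossible(self):
        assert pg.site_dosage_log_likelihood(1, 10, 0, 4, 0.0) == -math.inf
        assert pg.site_dosage_log_likelihood(9, 10, 4, 4, 0.0) == -math.inf

    @pytest.mark.parametrize("depth,ploidy,eps", [(7, 2, 0.0), (23, 4, 0.01), (40, 6, 0.001)])
    def test_pmf_normalizes_over_alt_counts(self, depth, ploidy, eps):
        for c in range(ploidy + 1):
            total = sum(
                math.exp(pg.site_dosage_log_likelihood(x, depth, c, ploidy, eps))
                for x in range(depth + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            pg.site_dosage_log_likelihood(5, 4, 1, 4, 0.0)
        with pytest.raises(ValueError):
            pg.site_dosage_log_likelihood(1, 4, 5, 4, 0.0)


class TestMlSiteGenotype:
    @pytest.mark.parametrize(
        "alt,depth,ploidy,expected",
        [(30, 78, 4, 2), (38, 64, 4, 2), (20, 58, 4, 1), (0, 100, 6, 0)],
    )
    def test_pileup_dosage_calls(self, alt, depth, ploidy, expected):
        assert pg.ml_site_genotype(alt, depth, ploidy, 0.0) == expected

    def test_agrees_with_brute_force_argmax(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            ploidy = int(rng.choice([2, 4, 6]))
            depth = int(rng.integers(1, 201))
            alt = int(rng.integers(0, depth + 1))
            eps = float(rng.choice([0.0, 0.001, 0.02]))
            lls = [
                pg.site_dosage_log_likelihood(alt, depth, c, ploidy, eps)
                for c in range(ploidy + 1)
            ]
            best = max(range(ploidy + 1), key=lambda c: (lls[c], -c))
            assert pg.ml_site_genotype(alt, depth, ploidy, eps) == best

    def test_simplex_duplex_boundary_closed_form(self):
        # boundary VAF where Bin(x; n, 1/4) == Bin(x; n, 1/2)
        boundary = math.log(0.5 / 0.75) / math.log(0.25 / 0.75)
        assert boundary == pytest.approx(0.369, abs=5e-4)
        n = 100_000
        assert pg.ml_site_genotype(int(boundary * n) - 5, n, 4, 0.0) == 1
        assert pg.ml_site_genotype(int(boundary * n) + 5, n, 4, 0.0) == 2

    def test_balanced_het_maximizes_binomial_variance(self):
        for ploidy in (2, 4, 6, 8):
            for eps in (0.0, 0.01):
                var = [
                    _dosage_error_prob(c, ploidy, eps) * (1 - _dosage_error_prob(c, ploidy, eps))
                    for c in range(ploidy + 1)
                ]
                assert int(np.argmax(var)) == ploidy // 2


class TestHaplotypeLikelihood:
    def _hap(self, alleles):
        return pg.Haplotype("blk", 0, len(alleles), tuple(enumerate(alleles)))

    def test_per_site_match_mismatch_terms(self):
        hap = self._hap([0, 1, 0])
        match = pg.ReadObservation((0, 1, 2), (0, 1, 0))
        miss1 = pg.ReadObservation((0, 1, 2), (0, 0, 0))
        assert pg.read_haplotype_log_likelihood(match, hap, 0.01) == pytest.approx(
            3 * math.log(0.99)
        )
        assert pg.read_haplotype_log_likelihood(miss1, hap, 0.01) == pytest.approx(
            2 * math.log(0.99) + math.log(0.01)
        )
        assert pg.read_haplotype_log_likelihood(match, hap, 0.0) == 0.0
        assert pg.read_haplotype_log_likelihood(miss1, hap, 0.0) == -math.inf

    def test_unmapped_site_raises(self):
        hap = self._hap([0, 1])
        read = pg.ReadObservation((0, 5), (0, 1))
        with pytest.raises(KeyError):
            pg.read_haplotype_log_likelihood(read, hap, 0.01)

    def test_single_site_reads_reduce_to_binomial(self):
        """Mixture likelihood == binomial likelihood minus log C(n, x)."""
        rng = np.random.default_rng(7)
        ref_hap = self._hap([0])
        alt_hap = self._hap([1])
        for _ in range(20):
            ploidy = int(rng.choice([2, 4, 6]))
            c = int(rng.integers(0, ploidy + 1))
            depth = int(rng.integers(1, 120))
            alt = int(rng.integers(0, depth + 1))
            eps = float(rng.choice([0.001, 0.05]))
            reads = []
            if alt:
                reads.append(pg.ReadObservation((0,), (1,), weight=alt))
            if depth - alt:
                reads.append(pg.ReadObservation((0,), (0,), weight=depth - alt))
            g = pg.Genotype((ploidy - c, c))
            mix = genotype_log_likelihood(reads, g, [ref_hap, alt_hap], eps)
            binom = pg.site_dosage_log_likelihood(alt, depth, c, ploidy, eps)
            log_comb = float(
                gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
            )
            assert mix == pytest.approx(binom - log_comb, rel=1e-9, abs=1e-9)

    def test_linked_block_rescues_true_dosage(self, linked_block):
        haps, reads = linked_block
        scores = {
            g.dosages: genotype_log_likelihood(reads, g, haps, 0.01)
            for g in pg.enumerate_genotypes(2, 4)
        }
        assert max(scores, key=scores.get) == (3, 1)
        # site-wise maximum likelihood disagrees at the first site
        assert [pg.ml_site_genotype(a, 50, 4, 0.01) for a in (19, 30, 16)] == [2, 2, 1]

    def test_impossible_read_at_zero_error(self):
        haps = [self._hap([0]), self._hap([1])]
        bad = pg.ReadObservation((0,), (2,))
        g = pg.Genotype((2, 2))
        assert genotype_log_likelihood([bad], g, haps, 0.0) == -math.inf

    def test_empty_reads_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert genotype_log_likelihood([], pg.Genotype((1, 1)), [None, None], 0.0) == 0.0


class TestPosteriors:
    def test_equal_likelihoods_split_evenly(self):
        gts = pg.enumerate_genotypes(2, 1)
        post = pg.genotype_posteriors(gts, [math.log(0.5)] * 2)
        assert post.posteriors == pytest.approx([0.5, 0.5])
        assert post.gq == pytest.approx(-10 * math.log10(0.5), abs=0.01)
        assert post.best.dosages == (1, 0)  # canonical tie-break

    def test_single_candidate_hits_cap(self):
        post = pg.genotype_posteriors([pg.Genotype((4, 0))], [-3.0])
        assert post.posteriors == pytest.approx([1.0])
        assert post.gq == pg.genotype_model.GQ_CAP

    def test_all_impossible_raises(self):
        with pytest.raises(ValueError, match="no viable genotype"):
            pg.genotype_posteriors(pg.enumerate_genotypes(2, 2), [-math.inf] * 3)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=-50, max_value=0), min_size=1, max_size=12))
    def test_posteriors_sum_to_one(self, lls):
        gts = [pg.Genotype((i, len(lls) - i)) for i in range(len(lls))]
        post = pg.genotype_posteriors(gts, lls)
        assert float(np.sum(post.posteriors)) == pytest.approx(1.0, abs=1e-9)
        assert post.gq >= 0


class TestCallBlock:
    def test_linked_block_calls_true_pattern(self, linked_block):
        haps, reads = linked_block
        result = pg.call_block(reads, haps, pg.ModelParams(ploidy=4, error_rate=0.01))
        labels = [
            pg.genotype_class_label(sum(result.site_dosages[p][1:]), 4) for p in (0, 1, 2)
        ]
        assert labels == ["AAAa", "Aaaa", "AAAa"]
        assert result.block_length == 3

    def test_clean_hom_ref_site_is_confident(self):
        haps = [
            pg.Haplotype("blk", 0, 1, ((0, 0),)),
            pg.Haplotype("blk", 0, 1, ((0, 1),)),
        ]
        reads = [pg.ReadObservation((0,), (0,), weight=30)]
        result = pg.call_block(reads, haps, pg.ModelParams(ploidy=4, error_rate=0.001))
        assert result.site_dosages[0] == (4, 0)
        assert result.site_gq[0] > 30

    def test_single_site_block_reduces_to_sitewise(self):
        rng = np.random.default_rng(5)
        haps = [
            pg.Haplotype("blk", 0, 1, ((0, 0),)),
            pg.Haplotype("blk", 0, 1, ((0, 1),)),
        ]
        for _ in range(25):
            depth = int(rng.integers(1, 100))
            alt = int(rng.integers(0, depth + 1))
            reads = []
            if alt:
                reads.append(pg.ReadObservation((0,), (1,), weight=alt))
            if depth - alt:
                reads.append(pg.ReadObservation((0,), (0,), weight=depth - alt))
            result = pg.call_block(reads, haps, pg.ModelParams(ploidy=4, error_rate=0.01))
            assert result.site_dosages[0][1] == pg.ml_site_genotype(alt, depth, 4, 0.01)

    def test_requires_haplotypes_and_reads(self):
        with pytest.raises(ValueError):
            pg.call_block([pg.ReadObservation((0,), (0,))], [], pg.ModelParams(ploidy=4))


class TestClassLabels:
    @pytest.mark.parametrize(
        "dosage,ploidy,label", [(2, 4, "AAaa"), (3, 6, "AAAaaa"), (0, 2, "AA"), (4, 4, "aaaa")]
    )
    def test_label_and_parse_round_trip(self, dosage, ploidy, label):
        assert pg.genotype_class_label(dosage, ploidy) == label
        assert pg.parse_genotype_class_label(label) == (dosage, ploidy)

    def test_out_of_range_and_malformed(self):
        with pytest.raises(ValueError):
            pg.genotype_class_label(5, 4)
        with pytest.raises(ValueError):
            pg.parse_genotype_class_label("aAaa")
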