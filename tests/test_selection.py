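"""Densities, baseline tests, Dunn-Sidak correction, Ka/Ks counting."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from allelecall.alleles import call_alleles
from allelecall.errors import PreconditionError
from allelecall.mutations import hybrid_mode_mutations
from allelecall.selection import (
    baseline_test,
    dunn_sidak,
    intensity_ratio,
    ka_ks,
    mutation_density,
    one_sample_baseline_test,
    per_allele_rates,
    round_half_up,
)
from conftest import small_config
from allelecall.simulate import simulate

BASES = "ACGT"


class TestDensity:
    @pytest.mark.parametrize(
        "n,length,expected",
        [(1, 1014, 0.0010), (28, 1305, 0.0215), (0, 500, 0.0)],
    )
    def test_reported_density(self, n, length, expected):
        assert mutation_density(n, length).density_report == expected

    def test_density_zero_iff_no_mutations(self):
        assert mutation_density(0, 100).density == 0
        assert mutation_density(1, 10_000_000).density > 0

    def test_zero_length_rejected(self):
        with pytest.raises(PreconditionError):
            mutation_density(1, 0)


class TestPerAlleleRates:
    def test_planted_counts_divided_by_length(self):
        aln, rm, truth = simulate(
            small_config(seed=6, derived_per_region={"five_prime": 2, "exon": 1})
        )
        alleles = call_alleles(aln, rm)
        catalog = hybrid_mode_mutations(alleles, aln, rm)
        length = rm.aligned_length("five_prime")
        mean, se, rates = per_allele_rates(catalog, alleles, "five_prime", length)
        assert all(rate == pytest.approx(2 / length) for rate in rates.values())
        assert mean == pytest.approx(2 / length)
        assert se == pytest.approx(0.0)

    def test_single_allele_has_undefined_se(self):
        class OneAllele:
            alleles = {"L_a": None}

        mean, se, rates = per_allele_rates([], OneAllele(), "exon", 100)
        assert (mean, se) == (0.0, None)
        assert rates == {"L_a": 0.0}


class TestBaselineTest:
    def test_identical_vectors_degenerate(self):
        res = baseline_test([0.1] * 5, [0.1] * 5)
        assert res.degenerate and res.p_one_tailed == 0.5
        assert res.direction == "none"

    def test_direction_positive_when_elevated(self):
        res = baseline_test(
            [0.0030, 0.0032, 0.0031], [0.0003, 0.0004, 0.0002],
            alpha_prime=0.0169,
        )
        assert res.tail == "greater"
        assert res.significant
        assert res.direction == "positive_selection"

    def test_direction_negative_when_depressed(self):
        res = baseline_test(
            [0.0001, 0.0002, 0.0001], [0.0020, 0.0025, 0.0022],
            alpha_prime=0.05,
        )
        assert res.tail == "less" and res.direction == "negative_selection"

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 0.3, 7), rng.normal(0.8, 0.2, 10)
        res = baseline_test(x, y, alternative="greater")
        ref = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        assert res.t_stat == pytest.approx(ref.statistic)
        assert res.p_one_tailed == pytest.approx(ref.pvalue)

    def test_paired_variant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1, 0.2, 8)
        y = x - rng.normal(0.3, 0.05, 8)
        res = baseline_test(x, y, alternative="greater", paired=True)
        ref = stats.ttest_rel(x, y, alternative="greater")
        assert res.p_one_tailed == pytest.approx(ref.pvalue)

    def test_type_one_error_calibrated(self):
        # under the null (both vectors from one rate distribution) the
        # rejection frequency at alpha' stays within 3 MC s.e. of alpha'
        rng = np.random.default_rng(12)
        alpha_prime = dunn_sidak(0.05, 3)
        reps = 10_000
        x = rng.normal(0.001, 0.0003, size=(reps, 7))
        y = rng.normal(0.001, 0.0003, size=(reps, 10))
        res = stats.ttest_ind(x, y, axis=1, equal_var=False, alternative="greater")
        rejections = int((res.pvalue < alpha_prime).sum())
        # spot-check the package wrapper against the vectorized computation
        for i in range(50):
            mine = baseline_test(x[i], y[i], alternative="greater")
            assert mine.p_one_tailed == pytest.approx(float(res.pvalue[i]))
        se = math.sqrt(alpha_prime * (1 - alpha_prime) / reps)
        assert abs(rejections / reps - alpha_prime) <= 3 * se

    def test_power_against_reference_distribution(self):
        # planted elevated rates: rejection frequency tracks the closed-form
        # power of the one-sample t-test within Monte-Carlo error
        rng = np.random.default_rng(21)
        reps, n, df = 1000, 7, 6
        mu0, mu1, sd = 0.0, 0.8, 1.0
        alpha = 0.05
        hits = 0
        for _ in range(reps):
            sample = rng.normal(mu1, sd, n)
            t = sample.mean() / (sample.std(ddof=1) / math.sqrt(n))
            if stats.t.sf(t, df) < alpha:
                hits += 1
        ncp = (mu1 - mu0) / (sd / math.sqrt(n))
        power = float(stats.nct.sf(stats.t.isf(alpha, df), df, ncp))
        se = math.sqrt(power * (1 - power) / reps)
        assert abs(hits / reps - power) <= 3 * se


class TestOneSampleBaseline:
    def test_elevated_allele_rates_highly_significant(self):
        for rate in (0.0032, 0.0031):
            res = one_sample_baseline_test(
                rate, baseline_mean=0.0003, baseline_se=0.000096, df=6
            )
            assert res.p_one_tailed < 0.001
            assert res.direction == "positive_selection"

    def test_matches_t_distribution(self):
        res = one_sample_baseline_test(0.5, 0.2, 0.1, df=9)
        assert res.t_stat == pytest.approx(3.0)
        assert res.p_one_tailed == pytest.approx(float(stats.t.sf(3.0, 9)))


class TestDunnSidak:
    def test_three_comparisons(self):
        ap = dunn_sidak(0.05, 3)
        assert ap == pytest.approx(1 - 0.95 ** (1 / 3))
        assert math.floor(ap * 1e4) / 1e4 == 0.0169

    def test_identity_at_k_one(self):
        assert dunn_sidak(0.05, 1) == pytest.approx(0.05)

    def test_bounds_against_bonferroni(self):
        for alpha in (0.01, 0.05, 0.1):
            for k in range(2, 30):
                ap = dunn_sidak(alpha, k)
                assert alpha / k <= ap < alpha
                assert ap < dunn_sidak(alpha, k - 1) or k == 1

    def test_invalid_inputs(self):
        with pytest.raises(PreconditionError):
            dunn_sidak(0.05, 0)
        with pytest.raises(PreconditionError):
            dunn_sidak(1.5, 3)


def oracle_kaks(ref_cds, alt_cds):
    """Naive enumeration oracle: per-position synonymous fractions for sites
    and recursive pathway enumeration for changes."""
    def aa(codon):
        return str(Seq(codon).translate())

    syn_sites = nonsyn_sites = 0.0
    syn_changes = nonsyn_changes = 0.0
    for i in range(0, len(ref_cds), 3):
        ref, alt = ref_cds[i : i + 3], alt_cds[i : i + 3]
        for pos in range(3):
            syn_here = sum(
                1
                for b in BASES
                if b != ref[pos] and aa(ref[:pos] + b + ref[pos + 1 :]) == aa(ref)
            )
            syn_sites += syn_here / 3
            nonsyn_sites += (3 - syn_here) / 3

        def paths(current, remaining):
            if not remaining:
                return [(0.0, 0.0)]
            out = []
            for pos in remaining:
                nxt = current[:pos] + alt[pos] + current[pos + 1 :]
                step = (1.0, 0.0) if aa(nxt) == aa(current) else (0.0, 1.0)
                for s, ns in paths(nxt, [p for p in remaining if p != pos]):
                    out.append((step[0] + s, step[1] + ns))
            return out

        diffs = [p for p in range(3) if ref[p] != alt[p]]
        results = paths(ref, diffs)
        syn_changes += sum(s for s, _ in results) / len(results)
        nonsyn_changes += sum(ns for _, ns in results) / len(results)
    return syn_sites, nonsyn_sites, syn_changes, nonsyn_changes


NONSTOP = [
    "".join(c)
    for c in itertools.product(BASES, repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


class TestKaKs:
    def test_identical_sequences(self):
        res = ka_ks("ATGGAA", "ATGGAA")
        assert res.Ka == 0 and res.Ks == 0 and res.ratio is None

    def test_single_synonymous_change(self):
        res = ka_ks("GAG", "GAA")
        assert res.Ka == 0 and res.Ks > 0
        assert res.syn_changes == 1.0 and res.nonsyn_changes == 0.0

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(17)
        cds = "".join(NONSTOP[i] for i in rng.integers(0, len(NONSTOP), 30))
        res = ka_ks(cds, cds)
        assert res.syn_sites + res.nonsyn_sites == pytest.approx(3 * res.n_codons)

    def test_ks_zero_with_ka_positive_is_undefined_not_infinite(self):
        res = ka_ks("ATG", "CTG")  # Met -> Leu, nonsynonymous only
        assert res.Ka > 0 and res.Ks == 0
        assert res.ratio is None and not res.ratio_defined

    def test_mismatched_length_rejected(self):
        with pytest.raises(PreconditionError):
            ka_ks("ATGAAA", "ATG")

    def test_internal_stop_rejected(self):
        with pytest.raises(PreconditionError):
            ka_ks("TAAGAA", "TAAGAA")

    def test_matches_enumeration_oracle_on_random_codon_pairs(self):
        rng = np.random.default_rng(100)
        for _ in range(500):
            ref = NONSTOP[rng.integers(0, len(NONSTOP))]
            alt = list(ref)
            for _ in range(rng.integers(0, 3)):
                alt[rng.integers(0, 3)] = BASES[rng.integers(0, 4)]
            alt = "".join(alt)
            got = ka_ks(alt, ref)
            want = oracle_kaks(ref, alt)
            assert got.syn_sites == pytest.approx(want[0])
            assert got.nonsyn_sites == pytest.approx(want[1])
            assert got.syn_changes == pytest.approx(want[2])
            assert got.nonsyn_changes == pytest.approx(want[3])

    def test_exact_on_all_two_difference_codon_pairs(self):
        for ref in NONSTOP:
            for pos1, pos2 in itertools.combinations(range(3), 2):
                for b1 in BASES:
                    if b1 == ref[pos1]:
                        continue
                    b2 = "A" if ref[pos2] != "A" else "C"
                    alt = list(ref)
                    alt[pos1], alt[pos2] = b1, b2
                    alt = "".join(alt)
                    got = ka_ks(alt, ref)
                    want = oracle_kaks(ref, alt)
                    assert got.syn_changes == pytest.approx(want[2])
                    assert got.nonsyn_changes == pytest.approx(want[3])


class TestIntensityRatio:
    def test_stated_time_depths(self):
        assert intensity_ratio(600_000, 10_000) == pytest.approx(60)
        assert intensity_ratio(600_000, 8_000) == pytest.approx(75)

    def test_equal_depths(self):
        assert intensity_ratio(5, 5) == 1

    def test_nonpositive_rejected(self):
        with pytest.raises(PreconditionError):
            intensity_ratio(0, 10)


class TestRounding:
    def test_half_up_convention(self):
        assert round_half_up(0.00215, 4) == 0.0022
        assert round_half_up(0.021455, 4) == 0.0215
        assert round_half_up(-0.00215, 4) == -0.0022
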