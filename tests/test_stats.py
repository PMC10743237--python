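"""Trend tests, many-to-one comparisons, and mutational spectra."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mthet.calling import HetClass, VarClass, VariantCall
from mthet.errors import InsufficientDataError, ParameterError
from mthet.simulate import random_genome
from mthet.stats import (
    OrderedGroups,
    Spectrum,
    age_correlation,
    chi_squared_2x2,
    cosine_similarity,
    dunnett_many_to_one,
    indel_spectrum,
    jonckheere_terpstra,
    kruskal_wallis,
    load_reference_spectra,
    substitution_spectrum,
)


def groups_of(*lists, labels=None):
    labels = labels or [f"g{i}" for i in range(len(lists))]
    return OrderedGroups(labels=list(labels), values=dict(zip(labels, [list(x) for x in lists])))


def brute_force_jt_p(lists, j_obs):
    """Independent oracle: enumerate every ordering of the pooled values and
    recompute J with a plain double loop."""
    pooled = [v for l in lists for v in l]
    sizes = [len(l) for l in lists]
    hits = total = 0
    for perm in itertools.permutations(pooled):
        gs, i = [], 0
        for n in sizes:
            gs.append(perm[i : i + n])
            i += n
        j = 0.0
        for a, b in itertools.combinations(gs, 2):
            for x in a:
                for y in b:
                    j += (x < y) + 0.5 * (x == y)
        total += 1
        hits += j >= j_obs - 1e-12
    return hits / total


class TestJonckheereTerpstra:
    def test_two_groups_reduce_to_mann_whitney(self):
        g1, g2 = [3.1, 4.0, 1.2, 5.5], [4.4, 6.1, 7.0, 5.9, 8.2]
        groups = groups_of(g1, g2)
        j, p = jonckheere_terpstra(groups, method="exact_permutation")
        u = sps.mannwhitneyu(g2, g1, alternative="greater", method="exact")
        assert j == u.statistic
        assert p == pytest.approx(u.pvalue, rel=1e-9)

    def test_maximal_separation_exact_p(self):
        groups = groups_of([1, 2], [3, 4], [5, 6])
        j, p = jonckheere_terpstra(groups, method="exact_permutation")
        assert j == 12  # every cross-group pair concordant
        assert p == pytest.approx(1 / 90)

    def test_all_identical_degenerate(self):
        groups = groups_of([5, 5], [5, 5], [5, 5])
        j, p = jonckheere_terpstra(groups, method="normal_approx")
        assert j == 6  # n_pairs / 2 with all ties at one half each
        assert p == 1.0

    def test_exact_matches_exhaustive_enumeration(self):
        lists = [[1.0, 4.0, 2.5], [3.0, 6.0], [5.0, 5.0]]
        groups = groups_of(*lists)
        j, p = jonckheere_terpstra(groups, method="exact_permutation")
        assert p == pytest.approx(brute_force_jt_p(lists, j), rel=1e-9)

    def test_monte_carlo_close_to_exact(self):
        lists = [[1.0, 4.0, 2.5], [3.0, 6.0], [5.0, 5.5]]
        groups = groups_of(*lists)
        _, p_exact = jonckheere_terpstra(groups, method="exact_permutation")
        _, p_mc = jonckheere_terpstra(groups, method="permutation", n_perm=20_000, seed=1)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_decreasing_alternative(self):
        inc = groups_of([1, 2], [3, 4], [5, 6])
        j_dec, p_dec = jonckheere_terpstra(inc, alternative="decreasing",
                                           method="exact_permutation")
        assert j_dec == 0
        assert p_dec == pytest.approx(1.0)

    def test_normal_approx_reasonable_at_scale(self):
        rng = np.random.default_rng(0)
        lists = [list(rng.normal(k * 0.8, 1, size=n)) for k, n in enumerate((16, 15, 4, 42))]
        _, p = jonckheere_terpstra(groups_of(*lists), method="normal_approx")
        assert p < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            OrderedGroups(labels=["a", "b"], values={"a": [1.0], "b": []})


class TestDunnett:
    def test_single_comparison_equals_t_test(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 16), rng.normal(0.7, 1, 42)
        groups = groups_of(a, b, labels=["ctl", "trt"])
        p_adj = dunnett_many_to_one(groups, control="ctl", seed=0)["trt"]
        p_t = sps.ttest_ind(b, a).pvalue
        assert p_adj == pytest.approx(p_t, abs=0.002)

    def test_power_for_planted_shift(self):
        # a 2-pooled-SD shift at the cohort's extreme group sizes (16 vs 42)
        # is detected at alpha = 0.01 with power > 0.9
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.normal(0, 1, 16)
            b = rng.normal(2, 1, 42)
            p = sps.ttest_ind(b, a).pvalue  # single-comparison Dunnett == t
            hits += p < 0.01
        assert hits / n_rep > 0.9

    def test_adjusted_p_bounded_and_ordered(self):
        rng = np.random.default_rng(2)
        groups = groups_of(
            rng.normal(0, 1, 16), rng.normal(0, 1, 15),
            rng.normal(0, 1, 4), rng.normal(2, 1, 42),
            labels=["G1", "G2", "G4", "G5"],
        )
        ps = dunnett_many_to_one(groups, control="G1", seed=3)
        assert set(ps) == {"G2", "G4", "G5"}
        assert all(0 <= p <= 1 for p in ps.values())
        assert ps["G5"] < 0.01

    def test_degenerate_variance_rejected(self):
        groups = groups_of([1, 1], [1, 1], labels=["a", "b"])
        with pytest.raises(ParameterError):
            dunnett_many_to_one(groups, control="a")


class TestKruskalWallis:
    def test_identical_groups_contract(self):
        assert kruskal_wallis(groups_of([3, 3], [3, 3])) == (0.0, 1.0)

    def test_hand_ranked_oracle(self):
        # ranks 1..9 -> H = 12/90 * (36 + 225 + 576)/3 - 30 = 7.2
        h, _ = kruskal_wallis(groups_of([1, 2, 3], [4, 5, 6], [7, 8, 9]))
        assert h == pytest.approx(7.2)

    def test_tie_correction_inflates_h(self):
        lists = [[1, 1, 2], [2, 2, 3], [3, 3, 3]]
        h_corrected, _ = kruskal_wallis(groups_of(*lists))
        # uncorrected H from the textbook formula on midranks
        pooled = [v for l in lists for v in l]
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        idx = 0
        h_raw = 0.0
        for l in lists:
            r = ranks[idx : idx + len(l)]
            idx += len(l)
            h_raw += r.sum() ** 2 / len(l)
        h_raw = 12 / (n * (n + 1)) * h_raw - 3 * (n + 1)
        assert h_corrected >= h_raw


class TestChiSquared2x2:
    def test_carrier_table_significant_both_ways(self):
        # 21/61 advanced-stage carriers vs 0/16 early-stage
        table = [[21, 40], [0, 16]]
        _, p_yates = chi_squared_2x2(table, yates=True)
        _, p_raw = chi_squared_2x2(table, yates=False)
        assert p_yates < 0.05 and p_raw < 0.05

    def test_independence(self):
        stat, p = chi_squared_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_uncorrected_matches_textbook_formula(self):
        table = np.array([[21, 40], [0, 16]], dtype=float)
        stat, _ = chi_squared_2x2(table, yates=False)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert stat == pytest.approx(((table - expected) ** 2 / expected).sum())

    def test_zero_marginal_rejected(self):
        with pytest.raises(ParameterError):
            chi_squared_2x2([[0, 0], [5, 5]])


class TestAgeCorrelation:
    def test_monotone_extremes(self):
        ages = [40, 50, 60, 70]
        assert age_correlation(ages, [1, 2, 3, 4])[0] == pytest.approx(1.0)
        assert age_correlation(ages, [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_constant_input_signals(self):
        with pytest.raises(InsufficientDataError):
            age_correlation([40, 50, 60], [1, 1, 1])

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(300):
            ages = rng.normal(60, 10, 77)
            burden = rng.poisson(1.0, 77)
            if burden.std() == 0:
                continue
            ps.append(age_correlation(ages, burden)[1])
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_pearson_available(self):
        rho, _ = age_correlation([1, 2, 3, 4], [2.1, 3.9, 6.2, 8.1], method="pearson")
        assert rho > 0.99


def snv(pos, ref, alt, sample="s1"):
    return VariantCall(sample, pos, ref, alt, 0.01, 10_000, VarClass.SNV,
                       HetClass.HETEROPLASMIC)


class TestSpectrum:
    def test_purine_reference_collapses(self, toy_genome):
        pos = next(p for p in range(2, toy_genome.length) if toy_genome.base(p) == "G")
        spec = substitution_spectrum([snv(pos, "G", "A")], toy_genome, kind="SBS6")
        assert spec.as_dict()["C>T"] == 1
        assert spec.total == 1

    def test_circular_context_at_origin(self, toy_genome):
        ref = toy_genome.base(1)
        alt = "A" if ref != "A" else "C"
        spec = substitution_spectrum([snv(1, ref, alt)], toy_genome, kind="SBS96")
        (label,) = [l for l, c in spec.as_dict().items() if c == 1]
        five, three = label[0], label[-1]
        last, second = toy_genome.base(toy_genome.length), toy_genome.base(2)
        if ref in "CT":
            assert (five, three) == (last, second)
        else:  # reverse-complement collapse flips the flanks
            from mthet.reference import reverse_complement

            assert (five, three) == (
                reverse_complement(second), reverse_complement(last)
            )

    def test_pure_transition_cohort(self, toy_genome):
        t_positions = [p for p in range(1, toy_genome.length) if toy_genome.base(p) == "T"][:50]
        variants = [snv(p, "T", "C") for p in t_positions]
        spec = substitution_spectrum(variants, toy_genome, kind="SBS6")
        assert spec.as_dict()["T>C"] == 50
        assert spec.total == 50

    def test_count_conservation_random(self, toy_genome):
        rng = np.random.default_rng(3)
        variants = []
        for p in rng.choice(toy_genome.length, 200, replace=False) + 1:
            ref = toy_genome.base(int(p))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(snv(int(p), ref, alt))
        for kind in ("SBS6", "SBS96"):
            assert substitution_spectrum(variants, toy_genome, kind).total == 200

    def test_ref_equals_alt_rejected(self, toy_genome):
        pos = next(p for p in range(1, 100) if toy_genome.base(p) == "C")
        with pytest.raises(ParameterError):
            substitution_spectrum([snv(pos, "C", "C")], toy_genome)

    def test_indel_spectrum_conservation(self, toy_genome):
        calls = [
            VariantCall("s", 10, toy_genome.base(10), "+A", 0.01, 1000,
                        VarClass.INSERTION, HetClass.HETEROPLASMIC),
            VariantCall("s", 20, toy_genome.base(20), "-2", 0.01, 1000,
                        VarClass.DELETION, HetClass.HETEROPLASMIC),
        ]
        spec = indel_spectrum(calls, toy_genome)
        assert spec.total == 2


class TestCosineSimilarity:
    def test_self_similarity(self):
        s = Spectrum.zeros("SBS6")
        s.counts = np.array([1, 2, 3, 4, 5, 6.0])
        assert cosine_similarity(s, s) == pytest.approx(1.0)

    def test_orthogonal(self):
        a, b = Spectrum.zeros("SBS6"), Spectrum.zeros("SBS6")
        a.counts[0] = 5
        b.counts[1] = 7
        assert cosine_similarity(a, b) == 0.0

    def test_scale_invariance(self):
        a, b = Spectrum.zeros("SBS6"), Spectrum.zeros("SBS6")
        a.counts = np.array([1, 2, 3, 4, 5, 6.0])
        b.counts = 2 * a.counts
        assert cosine_similarity(a, b) == pytest.approx(1.0)

    def test_class_set_mismatch(self):
        with pytest.raises(ParameterError):
            cosine_similarity(Spectrum.zeros("SBS6"), Spectrum.zeros("SBS96"))

    def test_zero_vector_signals(self):
        with pytest.raises(InsufficientDataError):
            cosine_similarity(Spectrum.zeros("SBS6"), Spectrum.zeros("SBS6"))

    def test_packaged_reference_spectra(self, toy_genome):
        refs = load_reference_spectra()
        assert {"SBS_clocklike_synthetic", "ID_slippage_synthetic"} <= set(refs)
        sbs = refs["SBS_clocklike_synthetic"]
        assert sbs.kind == "SBS96" and sbs.total > 0
        # a synthetic all-transition cohort is closer to the C>T-elevated
        # clock-like stand-in than an orthogonal one-hot profile
        t_positions = [p for p in range(1, toy_genome.length) if toy_genome.base(p) == "C"][:30]
        spec = substitution_spectrum([snv(p, "C", "T") for p in t_positions],
                                     toy_genome, kind="SBS96")
        assert 0 < cosine_similarity(spec, sbs) <= 1
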