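import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dogrose.mfac import (AlleleCombination, MFACError, Thresholds,
                          allele_stats, analyze_mfac, apparent_allele_counts,
                          build_network, categorize_locus_group,
                          combination_frequencies, filter_mfac_groups,
                          mfac_binomial_test, mfac_specificity_test,
                          null_carrier_probability, reports_to_frame)


def enumeration_carrier_probability(alleles, freqs, m):
    """Independent oracle: sum the probability of every ordered draw of m
    alleles whose multiset contains S."""
    sizes = sorted(freqs)
    total = 0.0
    for draw in itertools.product(sizes, repeat=m):
        if set(alleles) <= set(draw):
            total += math.prod(freqs[a] for a in draw)
    return total


class TestNullCarrierProbability:
    def test_two_equifrequent_alleles_diploid(self):
        # of the 4 equally likely ordered draws, 2 contain both alleles
        assert null_carrier_probability((1, 2), {1: 0.5, 2: 0.5}, 2) == \
            pytest.approx(0.5)

    def test_fixed_allele_singleton(self):
        assert null_carrier_probability((1,), {1: 1.0}, 3) == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_inclusion_exclusion_equals_enumeration(self, m, k):
        if k > m:
            pytest.skip("combination larger than draw")
        freqs = {1: 0.4, 2: 0.25, 3: 0.2, 4: 0.1, 5: 0.05}
        s = tuple(range(1, k + 1))
        assert null_carrier_probability(s, freqs, m) == pytest.approx(
            enumeration_carrier_probability(s, freqs, m), abs=1e-12)

    def test_monotone_non_increasing_in_set_size(self):
        freqs = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
        probs = [null_carrier_probability(tuple(range(1, k + 1)), freqs, 5)
                 for k in range(1, 5)]
        assert probs == sorted(probs, reverse=True)

    def test_oversized_set_rejected(self):
        with pytest.raises(MFACError, match="exceeds ploidy"):
            null_carrier_probability((1, 2, 3), {1: 0.5, 2: 0.3, 3: 0.2}, 2)

    def test_unknown_allele_rejected(self):
        with pytest.raises(MFACError, match="absent"):
            null_carrier_probability((9,), {1: 1.0}, 2)


class TestBinomialTest:
    def test_tail_sum_example(self):
        combo = AlleleCombination(locus="L", alleles=(1, 2), carriers=9, n=10)
        freq = allele_stats([(1, 2)] * 9 + [(1,)], "L")
        # force p0 = 0.5 via a synthetic frequency table
        freq.relative_frequency = {1: 0.5, 2: 0.5}
        # p0 for m=2 is 0.5; P(X >= 9 | 10, 0.5) = 11/1024
        p = mfac_binomial_test(combo, freq, 2)
        assert p == pytest.approx(11 / 1024)

    def test_certain_carrier_gives_p_one(self):
        combo = AlleleCombination(locus="L", alleles=(1,), carriers=10, n=10)
        freq = allele_stats([(1,)] * 10, "L")
        assert mfac_binomial_test(combo, freq, 5) == pytest.approx(1.0)


class TestSpecificityTest:
    def test_all_carriers_in_focal_group(self):
        # N=20, K=5, n=10, x=5 -> C(15,5)/C(20,10)
        p = mfac_specificity_test(5, 10, 5, 20)
        assert p == pytest.approx(3003 / 184756)

    def test_proportional_split_not_significant(self):
        assert mfac_specificity_test(5, 10, 10, 20) >= 0.5

    def test_no_carriers_anywhere(self):
        assert mfac_specificity_test(0, 10, 0, 20) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(MFACError):
            mfac_specificity_test(6, 10, 5, 20)

    def test_matches_brute_force_pmf_sum(self):
        n_pool, k_pool, n_focal, x = 30, 12, 10, 7
        brute = sum(
            math.comb(k_pool, i) * math.comb(n_pool - k_pool, n_focal - i)
            / math.comb(n_pool, n_focal)
            for i in range(x, min(k_pool, n_focal) + 1))
        assert mfac_specificity_test(x, n_focal, k_pool, n_pool) == \
            pytest.approx(brute)


class TestAlleleStats:
    def test_prevalence(self):
        entry = allele_stats([(1,), (1,), (2,), (3,)], "L")
        assert entry.prevalence[1] == pytest.approx(0.5)

    def test_relative_frequency_definition(self):
        entry = allele_stats([(1, 2), (1,)], "L")
        assert entry.relative_frequency[1] == pytest.approx(2 / 3)
        assert entry.relative_frequency[2] == pytest.approx(1 / 3)

    @given(st.lists(
        st.sets(st.integers(min_value=1, max_value=8), min_size=1, max_size=5)
        .map(lambda s: tuple(sorted(s))), min_size=1, max_size=20))
    def test_relative_frequencies_sum_to_one(self, phenotypes):
        entry = allele_stats(phenotypes, "L")
        assert sum(entry.relative_frequency.values()) == pytest.approx(1.0)
        assert all(0 < v <= 1 for v in entry.prevalence.values())


class TestApparentAlleleCounts:
    def test_cf_and_median(self):
        counts = apparent_allele_counts([(1, 2), (1, 2, 3), (1, 2, 3),
                                         (1, 2, 3, 4)])
        assert counts["cf"](3) == pytest.approx(0.75)
        assert counts["median"] == pytest.approx(3)

    def test_cf_fraction(self):
        phenos = [tuple(range(4))] * 7 + [tuple(range(2))] * 3
        assert apparent_allele_counts(phenos)["cf"](4) == pytest.approx(0.7)


class TestCombinationFrequencies:
    def test_enumeration_example(self):
        phenos = [(1, 2, 3, 4), (1, 2, 3, 5), (1, 2, 6, 7)]
        top = combination_frequencies(phenos, "L", 3)
        assert top[0].alleles == (1, 2, 3)
        assert top[0].frequency == pytest.approx(2 / 3)

    def test_tie_breaks_lexicographically(self):
        phenos = [(1, 2), (3, 4)]
        top = combination_frequencies(phenos, "L", 2)
        assert top[0].alleles == (1, 2)

    def test_exact_match_mode(self):
        phenos = [(1, 2, 3), (1, 2)]
        top = combination_frequencies(phenos, "L", 2, exact_match=True)
        assert top[0].alleles == (1, 2)
        assert top[0].carriers == 1

    @given(st.lists(
        st.sets(st.integers(min_value=1, max_value=9), min_size=2, max_size=6)
        .map(lambda s: tuple(sorted(s))), min_size=3, max_size=25))
    def test_containment_monotonicity(self, phenotypes):
        """f(S') >= f(S) for S' subset of S: subsets of a co-inherited set
        must be at least as frequent as the full set."""
        top4 = combination_frequencies(phenotypes, "L", 4, top=1000)
        freqs3 = {c.alleles: c.carriers
                  for c in combination_frequencies(phenotypes, "L", 3, top=10**6)}
        for combo in top4:
            for sub in itertools.combinations(combo.alleles, 3):
                assert freqs3[sub] >= combo.carriers


class TestNetwork:
    def combos(self, allele_sets, counts, n=10):
        return [AlleleCombination(locus="L", alleles=a, carriers=c, n=n)
                for a, c in zip(allele_sets, counts)]

    def test_one_allele_difference_gets_edge(self):
        net = build_network(self.combos([(1, 2, 3), (1, 2, 4)], [8, 5]))
        assert net.edges == ((0, 1),)

    def test_two_allele_difference_no_edge(self):
        net = build_network(self.combos([(1, 2, 3), (1, 4, 5)], [8, 5]))
        assert net.edges == ()

    def test_fade_below_threshold(self):
        net = build_network(self.combos([(1, 2)], [1], n=10))  # f = 0.1
        assert net.fade is True

    def test_no_fade_above_threshold(self):
        net = build_network(self.combos([(1, 2)], [5], n=10))
        assert net.fade is False

    def test_mixed_k_rejected(self):
        with pytest.raises(MFACError, match="mixed"):
            build_network(self.combos([(1, 2, 3), (1, 2)], [8, 5]))

    def test_node_sizes_relative_to_mfac(self):
        net = build_network(self.combos([(1, 2), (1, 3)], [8, 4]))
        assert net.node_sizes == (1.0, 0.5)

    def test_counterclockwise_layout(self):
        net = build_network(self.combos([(1, 2), (1, 3), (2, 3), (1, 4)],
                                        [8, 6, 4, 2]))
        angles = [math.atan2(y, x) % (2 * math.pi) for x, y in net.positions]
        # starting at the top, angles increase counter-clockwise with rank
        assert angles[0] == pytest.approx(math.pi / 2)
        assert all(b > a for a, b in zip(angles, angles[1:]))

    def test_graphml_and_dot_export(self, tmp_path):
        from dogrose.mfac import write_network_dot, write_network_graphml
        net = build_network(self.combos([(1, 2, 3), (1, 2, 4)], [8, 5]))
        write_network_graphml(net, tmp_path / "net.graphml")
        write_network_dot(net, tmp_path / "net.dot")
        assert "graphml" in (tmp_path / "net.graphml").read_text()
        assert "n0 -- n1" in (tmp_path / "net.dot").read_text()


class TestCategorization:
    def top(self, spec):
        return {k: [AlleleCombination(locus="L", alleles=a, carriers=c, n=n)
                    for a, c, n in combos]
                for k, combos in spec.items()}

    def test_category_a_for_dominant_nested_ploidy_minus_one_set(self):
        top = self.top({
            4: [((1, 2, 3, 4), 60, 100)],
            3: [((1, 2, 3), 70, 100)],
            2: [((1, 2), 80, 100)],
        })
        cat, rule, chosen = categorize_locus_group(
            top, 5, cf=lambda m: 0.8, p_binomial_of=lambda c: 1e-6,
            thresholds=Thresholds())
        assert cat == "A"
        assert chosen.alleles == (1, 2, 3, 4)

    def test_category_b_when_only_smaller_set_is_frequent(self):
        top = self.top({
            4: [((1, 2, 3, 4), 10, 100)],
            3: [((1, 2, 3), 50, 100)],
            2: [((1, 2), 60, 100)],
        })
        cat, rule, chosen = categorize_locus_group(
            top, 5, cf=lambda m: 0.3, p_binomial_of=lambda c: 1e-6,
            thresholds=Thresholds())
        assert cat == "B"
        assert chosen.alleles == (1, 2, 3)

    def test_category_bc_for_near_equal_faded_candidates(self):
        top = self.top({
            4: [((1, 2, 3, 4), 8, 100), ((1, 2, 3, 5), 8, 100),
                ((1, 2, 3, 6), 8, 100)],
            3: [((1, 2, 3), 90, 100)],
            2: [((1, 2), 95, 100)],
        })
        cat, rule, _ = categorize_locus_group(
            top, 5, cf=lambda m: 0.9, p_binomial_of=lambda c: 1e-6,
            thresholds=Thresholds())
        assert cat == "BC"
        assert rule.startswith("BC1")

    def test_category_bc_for_nesting_inconsistency(self):
        top = self.top({
            4: [((1, 2, 3, 4), 60, 100)],
            3: [((5, 6, 7), 65, 100)],
            2: [((5, 6), 70, 100)],
        })
        cat, rule, _ = categorize_locus_group(
            top, 5, cf=lambda m: 0.8, p_binomial_of=lambda c: 1e-6,
            thresholds=Thresholds())
        assert cat == "BC"
        assert rule.startswith("BC2")

    def test_category_c_when_no_dominant_combination(self):
        top = self.top({
            4: [((1, 2, 3, 4), 8, 100), ((5, 6, 7, 8), 2, 100)],
            3: [((1, 2, 3), 15, 100)],
            2: [((1, 2), 18, 100)],
        })
        cat, rule, _ = categorize_locus_group(
            top, 5, cf=lambda m: 0.9, p_binomial_of=lambda c: 1.0,
            thresholds=Thresholds())
        assert cat == "C"


class TestGroupFiltering:
    def records(self, make_record):
        recs = []
        # pentaploid Caninae: 4 distinct alleles -> estimate 5
        for i in range(3):
            recs.append(make_record(f"c{i}", {"RhAB73": (1, 2, 3, 4)}))
        # hexaploid-looking Caninae: 5 distinct alleles -> estimate 6
        recs.append(make_record("hex", {"RhAB73": (1, 2, 3, 4, 5)}))
        # Vestitae at both ploidies
        recs.append(make_record("v4", {"RhAB73": (1, 2, 3)},
                                subsection="Vestitae"))
        recs.append(make_record("v5", {"RhAB73": (1, 2, 3, 4)},
                                subsection="Vestitae"))
        return recs

    def test_hexaploids_excluded_and_vestitae_split(self, make_record, panel):
        from dogrose.clonality import estimate_ploidies
        recs = self.records(make_record)
        groups = filter_mfac_groups(recs, estimate_ploidies(recs, panel))
        by_label = {g.label: g for g in groups}
        assert "hex" not in by_label["Caninae_5x"].sample_ids
        assert by_label["Vestitae_4x"].sample_ids == ("v4",)
        assert by_label["Vestitae_5x"].sample_ids == ("v5",)

    def test_locus_group_grid_is_28(self, panel):
        from dogrose.mfac import DEFAULT_GROUP_DEFS
        assert len(DEFAULT_GROUP_DEFS) * len(panel.locus_ids) == 28

    def test_dedup_mlg_drops_local_repeats(self, make_record, panel):
        from dogrose.clonality import estimate_ploidies
        recs = [make_record("r1", {"RhAB73": (1, 2, 3, 4)}),
                make_record("r2", {"RhAB73": (1, 2, 3, 4)}),
                make_record("r3", {"RhAB73": (1, 2, 3, 4)}, site_id="S02")]
        ploidies = estimate_ploidies(recs, panel)
        (g, *_) = filter_mfac_groups(recs, ploidies, dedup_mlg=True, panel=panel)
        assert set(g.sample_ids) == {"r1", "r3"}


def test_analyze_mfac_end_to_end(make_record, panel):
    rng = np.random.default_rng(0)
    recs = []
    base = (150, 160, 170, 180)
    for i in range(40):
        # frequent 4-set with occasional one-allele exchange
        ph = list(base)
        if rng.random() < 0.2:
            ph[3] = 182
        recs.append(make_record(f"c{i}", {"RhAB73": tuple(ph)}))
    for i in range(40):
        recs.append(make_record(f"r{i}", {"RhAB73": (151, 161, 171, 181)},
                                subsection="Rubigineae"))
    reports = analyze_mfac(recs, panel, ks=(2, 3, 4))
    by_group = {(r.group, r.locus): r for r in reports}
    rep = by_group[("Caninae_5x", "RhAB73")]
    assert rep.mfac == base
    assert rep.category == "A"
    assert rep.p_binomial <= 0.001
    assert rep.specific  # the Rubigineae MFAC differs
    df = reports_to_frame(reports)
    assert {"group", "locus", "mfac", "category"} <= set(df.columns)
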