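"""Phenotype-frequency scoring, RMPs, profile distances, and comparisons."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gvppanel import (
    AllAbsentProfileError,
    ComparisonCategory,
    DetectionState,
    Genotype,
    GenotypeTable,
    GVPProfile,
    MissenseSNP,
    PhenotypeCategory,
    SampleKey,
    build_profile,
    category_test,
    expected_profile,
    pairwise_compare,
    phenotype_frequency,
    profile_difference,
    rmp,
    rmp_one_in,
)
from gvppanel.profiling import ProfileComparison, comparison_category

CATEGORIES = list(PhenotypeCategory)


def make_snp(snp_id, freqs=(0.49, 0.42, 0.09)):
    return MissenseSNP(snp_id, f"G_{snp_id}", f"P_{snp_id}", 6, "A", "C", freqs)


def make_profile(sample, categories, snps):
    entries = {
        s.snp_id: (c, phenotype_frequency(c, s.genotype_freqs))
        for s, c in zip(snps, categories)
    }
    return GVPProfile(sample=sample, entries=entries)


def key(ind, loc, rep):
    return SampleKey(f"{ind}_{loc}_r{rep}", ind, loc, rep)


triples = st.tuples(
    st.floats(0.01, 0.98), st.floats(0.01, 0.98)
).map(lambda t: (t[0] * (1 - t[1]), t[1], (1 - t[0]) * (1 - t[1])))
# (f_major_hom, f_het, f_minor_hom) with the three summing to 1


class TestPhenotypeFrequency:
    def test_single_gvp_sum_rule(self):
        assert phenotype_frequency(PhenotypeCategory.minor_only, (0.49, 0.42, 0.09)) == pytest.approx(0.51)
        assert phenotype_frequency(PhenotypeCategory.major_only, (0.49, 0.42, 0.09)) == pytest.approx(0.91)

    def test_both_scores_heterozygote_frequency(self):
        assert phenotype_frequency(PhenotypeCategory.both, (0.49, 0.42, 0.09)) == pytest.approx(0.42)

    def test_absent_scores_nothing(self):
        assert phenotype_frequency(PhenotypeCategory.absent, (0.49, 0.42, 0.09)) is None

    @given(triples)
    @settings(max_examples=200, deadline=None)
    def test_sum_rule_identity(self, freqs):
        # major_only + minor_only - both = total probability mass = 1
        total = (
            phenotype_frequency(PhenotypeCategory.major_only, freqs)
            + phenotype_frequency(PhenotypeCategory.minor_only, freqs)
            - phenotype_frequency(PhenotypeCategory.both, freqs)
        )
        assert total == pytest.approx(1.0)


class TestRMP:
    def test_product_of_frequencies(self):
        snps = [make_snp("rs1", (0.25, 0.5, 0.25)), make_snp("rs2", (0.25, 0.5, 0.25))]
        p = make_profile(key("I1", "head", 1), [PhenotypeCategory.both] * 2, snps)
        assert rmp(p) == pytest.approx(0.25)
        assert rmp_one_in(rmp(p)) == 4

    def test_locus_at_frequency_one_is_neutral(self):
        snps = [make_snp("rs1", (0.0, 1.0, 0.0)), make_snp("rs2", (0.25, 0.5, 0.25))]
        p = make_profile(key("I1", "head", 1), [PhenotypeCategory.both] * 2, snps)
        assert rmp(p) == pytest.approx(0.5)

    def test_absent_locus_skipped(self):
        snps = [make_snp("rs1", (0.25, 0.5, 0.25)), make_snp("rs2", (0.25, 0.5, 0.25))]
        p = make_profile(
            key("I1", "head", 1),
            [PhenotypeCategory.both, PhenotypeCategory.absent],
            snps,
        )
        assert rmp(p) == pytest.approx(0.5)

    def test_all_absent_is_distinct_error(self):
        snps = [make_snp("rs1")]
        p = make_profile(key("I1", "head", 1), [PhenotypeCategory.absent], snps)
        with pytest.raises(AllAbsentProfileError):
            rmp(p)

    def test_eight_locus_hand_product(self):
        freqs = [(0.49, 0.42, 0.09)] * 4 + [(0.64, 0.32, 0.04)] * 4
        snps = [make_snp(f"rs{i}", f) for i, f in enumerate(freqs)]
        cats = [
            PhenotypeCategory.major_only,
            PhenotypeCategory.minor_only,
            PhenotypeCategory.both,
            PhenotypeCategory.major_only,
            PhenotypeCategory.both,
            PhenotypeCategory.minor_only,
            PhenotypeCategory.major_only,
            PhenotypeCategory.major_only,
        ]
        p = make_profile(key("I1", "head", 1), cats, snps)
        hand = 0.91 * 0.51 * 0.42 * 0.91 * 0.32 * 0.36 * 0.96 * 0.96
        assert rmp(p) == pytest.approx(hand, abs=1e-12)

    def test_order_invariance_and_monotonicity(self):
        snps = [make_snp(f"rs{i}", (0.25, 0.5, 0.25)) for i in range(3)]
        cats = [PhenotypeCategory.both, PhenotypeCategory.major_only, PhenotypeCategory.minor_only]
        forward = make_profile(key("I1", "head", 1), cats, snps)
        backward = make_profile(
            key("I1", "head", 1), list(reversed(cats)), list(reversed(snps))
        )
        assert rmp(forward) == pytest.approx(rmp(backward))
        # appending a locus with frequency < 1 strictly decreases the RMP
        extended = make_profile(
            key("I1", "head", 1),
            cats + [PhenotypeCategory.both],
            snps + [make_snp("rs_extra", (0.25, 0.5, 0.25))],
        )
        assert rmp(extended) < rmp(forward)


class TestExpectedProfile:
    def test_genotype_category_map(self):
        snps = [make_snp("rs1"), make_snp("rs2"), make_snp("rs3")]
        genotypes = GenotypeTable(
            {
                ("I1", "rs1"): Genotype.major_hom,
                ("I1", "rs2"): Genotype.het,
                ("I1", "rs3"): Genotype.minor_hom,
            }
        )
        p = expected_profile("I1", genotypes, snps)
        assert p.category("rs1") is PhenotypeCategory.major_only
        assert p.category("rs2") is PhenotypeCategory.both
        assert p.category("rs3") is PhenotypeCategory.minor_only

    def test_het_everywhere_rmp_is_product_of_het_freqs(self):
        snps = [make_snp(f"rs{i}", (0.49, 0.42, 0.09)) for i in range(4)]
        genotypes = GenotypeTable({("I1", s.snp_id): Genotype.het for s in snps})
        assert rmp(expected_profile("I1", genotypes, snps)) == pytest.approx(0.42**4)

    def test_genotype_differences_give_equal_profile_distance(self):
        snps = [make_snp(f"rs{i}") for i in range(5)]
        g1 = GenotypeTable({("I1", s.snp_id): Genotype.major_hom for s in snps})
        entries2 = {("I2", s.snp_id): Genotype.major_hom for s in snps}
        entries2[("I2", "rs0")] = Genotype.het
        entries2[("I2", "rs3")] = Genotype.minor_hom
        g2 = GenotypeTable(entries2)
        d = profile_difference(
            expected_profile("I1", g1, snps), expected_profile("I2", g2, snps)
        )
        assert d == 2


class TestProfileDifference:
    def test_identity_and_symmetry_and_triangle_exhaustive(self):
        """Metric axioms verified exhaustively on the 3-locus category space."""
        snps = [make_snp(f"rs{i}") for i in range(3)]
        sample = key("I1", "head", 1)
        vectors = list(itertools.product(CATEGORIES, repeat=3))
        profiles = [make_profile(sample, v, snps) for v in vectors]
        for i, a in enumerate(profiles):
            assert profile_difference(a, a) == 0
        for a, b in itertools.combinations(profiles, 2):
            d_ab = profile_difference(a, b)
            assert d_ab == profile_difference(b, a) > 0
        # triangle inequality over all ordered triples of category vectors
        diffs = {
            (i, j): profile_difference(profiles[i], profiles[j])
            for i in range(len(profiles))
            for j in range(len(profiles))
        }
        for i, j, k in itertools.product(range(len(profiles)), repeat=3):
            assert diffs[(i, k)] <= diffs[(i, j)] + diffs[(j, k)]

    def test_absent_vs_detected_counts_as_difference(self):
        snps = [make_snp("rs1")]
        a = make_profile(key("I1", "head", 1), [PhenotypeCategory.absent], snps)
        b = make_profile(key("I1", "head", 2), [PhenotypeCategory.major_only], snps)
        assert profile_difference(a, b) == 1

    def test_mismatched_panels_rejected(self):
        a = make_profile(key("I1", "head", 1), [PhenotypeCategory.both], [make_snp("rs1")])
        b = make_profile(key("I1", "head", 2), [PhenotypeCategory.both], [make_snp("rs2")])
        with pytest.raises(ValueError, match="panels"):
            profile_difference(a, b)


def brute_force_pairs(samples):
    """Independent pair enumerator with category assignment by definition."""
    out = {"replicate": 0, "within_individual": 0, "between_individual": 0}
    for a, b in itertools.combinations(samples, 2):
        if a.individual_id == b.individual_id:
            if a.body_location == b.body_location:
                out["replicate"] += 1
            else:
                out["within_individual"] += 1
        else:
            out["between_individual"] += 1
    return out


class TestPairwiseCompare:
    def _design_profiles(self, n_ind=3, locations=("head", "arm", "pubic"), n_rep=4):
        snps = [make_snp("rs1")]
        return [
            make_profile(key(f"I{i}", loc, r), [PhenotypeCategory.both], snps)
            for i in range(1, n_ind + 1)
            for loc in locations
            for r in range(1, n_rep + 1)
        ]

    def test_full_design_comparison_partition(self):
        profiles = self._design_profiles()
        comparisons, summary = pairwise_compare(profiles)
        assert len(comparisons) == 630
        counts = {
            cat.value: sum(1 for c in comparisons if c.category is cat)
            for cat in ComparisonCategory
        }
        assert counts == {
            "replicate": 54,
            "within_individual": 144,
            "between_individual": 432,
        }
        assert counts == brute_force_pairs([p.sample for p in profiles])
        assert summary["replicate"]["n"] == 54

    @pytest.mark.parametrize("n_ind,n_loc,n_rep", [(2, 2, 2), (3, 3, 4), (4, 2, 3), (1, 3, 2)])
    def test_category_counts_match_combinatorial_formulas(self, n_ind, n_loc, n_rep):
        locations = [f"L{j}" for j in range(n_loc)]
        snps = [make_snp("rs1")]
        profiles = [
            make_profile(
                SampleKey(f"I{i}_{loc}_r{r}", f"I{i}", loc, r),
                [PhenotypeCategory.both],
                snps,
            )
            for i in range(n_ind)
            for loc in locations
            for r in range(1, n_rep + 1)
        ]
        comparisons, _ = pairwise_compare(profiles)
        counts = {
            cat.value: sum(1 for c in comparisons if c.category is cat)
            for cat in ComparisonCategory
        }
        c2 = lambda n: n * (n - 1) // 2
        assert counts["replicate"] == n_ind * n_loc * c2(n_rep)
        assert counts["within_individual"] == n_ind * (c2(n_loc * n_rep) - n_loc * c2(n_rep))
        assert counts["between_individual"] == c2(n_ind) * (n_loc * n_rep) ** 2
        assert sum(counts.values()) == c2(n_ind * n_loc * n_rep)

    def test_two_replicates_single_comparison(self):
        snps = [make_snp("rs1")]
        profiles = [
            make_profile(key("I1", "head", 1), [PhenotypeCategory.both], snps),
            make_profile(key("I1", "head", 2), [PhenotypeCategory.major_only], snps),
        ]
        comparisons, summary = pairwise_compare(profiles)
        (c,) = comparisons
        assert c.category is ComparisonCategory.replicate
        assert c.n_differences == 1
        assert summary["replicate"] == {"mean": 1.0, "sd": 0.0, "n": 1}


class TestCategoryTest:
    def _comparisons(self, groups):
        """groups: {(ind_a, ind_b, category): list of difference counts}."""
        out = []
        for (ia, ib, cat), values in groups.items():
            for i, v in enumerate(values):
                out.append(
                    ProfileComparison(
                        sample_a=key(ia, "head", i + 1),
                        sample_b=SampleKey(f"{ib}_arm_r{i+1}x", ib, "arm", i + 1),
                        category=ComparisonCategory(cat),
                        n_differences=v,
                    )
                )
        return out

    def test_identical_values_no_significant_pairs(self):
        comparisons = self._comparisons(
            {
                ("I1", "I1", "replicate"): [2, 2, 2],
                ("I1", "I2", "between_individual"): [2, 2, 2],
                ("I2", "I3", "between_individual"): [2, 2, 2],
            }
        )
        result = category_test(comparisons)
        assert result.pvalue == 1.0
        assert not any(r["significant"] for r in result.posthoc)

    def test_extreme_separation_detected(self):
        comparisons = self._comparisons(
            {
                ("I1", "I1", "replicate"): [0] * 12,
                ("I1", "I2", "between_individual"): [5] * 12,
                ("I2", "I3", "between_individual"): [5] * 12,
            }
        )
        result = category_test(comparisons)
        assert result.pvalue < 0.05
        flagged = {
            frozenset((r["group_a"], r["group_b"])) for r in result.posthoc if r["significant"]
        }
        assert frozenset(("replicate", "between:I1-I2")) in flagged
        assert frozenset(("replicate", "between:I2-I3")) in flagged
        assert frozenset(("between:I1-I2", "between:I2-I3")) not in flagged

    def test_small_group_excluded_with_warning(self, caplog):
        comparisons = self._comparisons(
            {
                ("I1", "I1", "replicate"): [0, 1, 0, 1],
                ("I1", "I2", "between_individual"): [4, 5, 6, 5],
                ("I1", "I1", "within_individual"): [1],
            }
        )
        with caplog.at_level("WARNING"):
            result = category_test(comparisons)
        assert result.excluded == ["within_individual"]
        assert "within_individual" not in result.group_sizes

    def test_realistic_effect_sizes_detected_reliably(self):
        """At realistic effect sizes the between groups separate from replicates
        in at least 95% of simulation runs."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            comparisons = self._comparisons(
                {
                    ("I1", "I1", "replicate"): list(rng.poisson(1.17, 54)),
                    ("I1", "I1x", "within_individual"): list(rng.poisson(1.06, 144)),
                    ("I1", "I2", "between_individual"): list(rng.normal(4.92, 0.84, 144).round().clip(0, 8).astype(int)),
                    ("I2", "I3", "between_individual"): list(rng.normal(5.11, 0.92, 144).round().clip(0, 8).astype(int)),
                    ("I1", "I3", "between_individual"): list(rng.normal(2.79, 0.71, 144).round().clip(0, 8).astype(int)),
                }
            )
            result = category_test(comparisons)
            significant = {
                frozenset((r["group_a"], r["group_b"]))
                for r in result.posthoc
                if r["significant"]
            }
            wanted = {
                frozenset(("replicate", "between:I1-I2")),
                frozenset(("replicate", "between:I2-I3")),
                frozenset(("replicate", "between:I1-I3")),
            }
            if result.pvalue < 0.05 and wanted <= significant:
                hits += 1
        assert hits / n_runs >= 0.95


class TestProfileValidation:
    def test_frequency_presence_tied_to_category(self):
        with pytest.raises(ValueError, match="iff"):
            GVPProfile(
                sample=key("I1", "head", 1),
                entries={"rs1": (PhenotypeCategory.absent, 0.5)},
            )
        with pytest.raises(ValueError, match="iff"):
            GVPProfile(
                sample=key("I1", "head", 1),
                entries={"rs1": (PhenotypeCategory.both, None)},
            )

    def test_build_profile_marks_missing_states_absent(self):
        snps = [make_snp("rs1"), make_snp("rs2")]
        states = [DetectionState("I1_head_r1", "rs1", True, False)]
        p = build_profile(key("I1", "head", 1), states, snps)
        assert p.category("rs1") is PhenotypeCategory.major_only
        assert p.category("rs2") is PhenotypeCategory.absent
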