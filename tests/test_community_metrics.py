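import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufalakes.community_metrics import (
    abundance_fa_weighted,
    community_responses,
    count_rich_taxa,
    fa_abundance_weighted,
    fa_x_abundance,
    loglog_richness_regression,
    richness,
)
from pufalakes.data_model import TaxonPufaProfile
from pufalakes.synthetic_data import GeneratorConfig, generate_survey

from conftest import make_sample


def profile(taxon, ara_class, mean_ara=1.0):
    """Minimal profile whose ARA class/mean are controlled."""
    return TaxonPufaProfile(
        taxon=taxon, n_lakes=2,
        mean_ara=mean_ara, sd_ara=0.1, class_ara=ara_class,
        mean_epa=1.0, sd_epa=0.1, class_epa=2,
        mean_dha=1.0, sd_dha=0.1, class_dha=2,
    )


TWO_TAXA = [profile("A", 2, 1.0), profile("B", 5, 5.0)]


class TestRichness:
    def test_counts_present_taxa(self, simple_sample):
        assert richness(simple_sample) == 2

    def test_empty_mapping(self):
        assert richness({"A": 0, "B": 0}) == 0

    def test_survey_contract(self):
        samples = generate_survey(GeneratorConfig(n_lakes=20, seed=4))
        assert all(5 <= richness(s) <= 46 for s in samples)


class TestWeightedIndices:
    def test_abundance_fa_weighted_direct(self):
        sample = {"A": 2, "B": 3}
        # FA (mass fractions) = (1, 5): (2*1 + 3*5) / (1 + 5)
        value = abundance_fa_weighted(sample, TWO_TAXA, "ara", fa_score="mean")
        assert value == pytest.approx(17 / 6)

    def test_weights_cancel_for_single_taxon(self):
        value = abundance_fa_weighted({"A": 10}, [profile("A", 3, 2.0)], "ara", fa_score="mean")
        assert value == pytest.approx(10.0)

    def test_all_absent_gives_zero(self):
        assert abundance_fa_weighted({"A": 0, "B": 0}, TWO_TAXA, "ara") == 0.0

    def test_fa_abundance_weighted_direct(self):
        value = fa_abundance_weighted({"A": 2, "B": 3}, TWO_TAXA, "ara", fa_score="mean")
        assert value == pytest.approx(17 / 5)

    def test_weighted_mean_of_constant_scores(self):
        same = [profile("A", 2, 3.0), profile("B", 2, 3.0)]
        value = fa_abundance_weighted({"A": 7, "B": 13}, same, "ara", fa_score="mean")
        assert value == pytest.approx(3.0)

    def test_empty_community_weighted_mean_undefined(self):
        with pytest.raises(ValueError, match="undefined weighted mean"):
            fa_abundance_weighted({"A": 0, "B": 0}, TWO_TAXA, "ara")

    def test_fa_x_abundance_direct(self):
        assert fa_x_abundance({"A": 2, "B": 3}, TWO_TAXA, "ara", fa_score="mean") == pytest.approx(17.0)
        assert fa_x_abundance({"A": 0, "B": 0}, TWO_TAXA, "ara") == 0.0

    def test_missing_taxon_policy(self):
        with pytest.raises(KeyError, match="Zorapteran"):
            fa_x_abundance({"A": 1, "Zorapteran": 2}, TWO_TAXA, "ara")
        with pytest.warns(UserWarning, match="dropping"):
            value = fa_x_abundance(
                {"A": 1, "Zorapteran": 2}, TWO_TAXA, "ara", fa_score="mean", missing="drop"
            )
        assert value == pytest.approx(1.0)

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.floats(0.0, 10.0), st.integers(1, 5)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_product_identity_and_permutation_invariance(self, rows):
        profiles = []
        counts = {}
        for i, (count, mean, _) in enumerate(rows):
            taxon = f"T{i}"
            cls = 1 if mean == 0.0 else 2
            profiles.append(
                TaxonPufaProfile(
                    taxon=taxon, n_lakes=1,
                    mean_ara=mean, sd_ara=None, class_ara=cls,
                    mean_epa=1.0, sd_epa=None, class_epa=2,
                    mean_dha=1.0, sd_dha=None, class_dha=2,
                )
            )
            counts[taxon] = count
        total_fa = sum(p.mean_ara for p in profiles)
        if total_fa <= 0:
            return
        lhs = fa_x_abundance(counts, profiles, "ara", fa_score="mean")
        rhs = abundance_fa_weighted(counts, profiles, "ara", fa_score="mean") * total_fa
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)
        # taxon order must not matter
        reordered = list(reversed(profiles))
        shuffled_counts = dict(reversed(list(counts.items())))
        assert fa_x_abundance(shuffled_counts, reordered, "ara", fa_score="mean") == pytest.approx(lhs)

    def test_weighted_mean_bounded_by_present_scores(self, reference_profiles):
        sample = generate_survey(GeneratorConfig(n_lakes=2, seed=9))[0]
        for pufa in ("ara", "epa", "dha"):
            value = fa_abundance_weighted(sample, reference_profiles, pufa)
            present = [
                p.class_for(pufa)
                for p in reference_profiles
                if sample.abundances.get(p.taxon, 0) > 0
            ]
            assert min(present) <= value <= max(present)


class TestRichTaxonCounts:
    def test_direct_counts(self):
        profiles = [profile(t, c) for t, c in zip("ABCD", (5, 4, 3, 2))]
        counts = {t: 1 for t in "ABCD"}
        assert count_rich_taxa(counts, profiles, "ara", 3) == (2, 0.5)
        assert count_rich_taxa(counts, profiles, "ara", 4) == (1, 0.25)

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            count_rich_taxa({"A": 1}, [profile("A", 5)], "ara", 2)

    def test_empty_community(self):
        assert count_rich_taxa({"A": 0}, [profile("A", 5)], "ara", 3) == (0, 0.0)

    def test_pufa_rich_reference_community(self, profile_table):
        # the five taxa reported as PUFA-rich across all three fatty acids
        rich_taxa = [
            "Heteroptera/Corixidae",
            "Oligochaeta",
            "Amphipoda/Pallasidae",
            "Platyhelminthes",
            "Odonata/Zygoptera",
        ]
        sample = make_sample({t: 10 for t in rich_taxa})
        for pufa in ("ara", "epa", "dha"):
            count, pct = count_rich_taxa(sample, profile_table, pufa, 3)
            assert count == 5 and pct == 1.0

    def test_counts_nest_within_richness(self, reference_profiles):
        sample = generate_survey(GeneratorConfig(n_lakes=2, seed=11))[0]
        r = community_responses(sample, reference_profiles)
        for pufa in ("ara", "epa", "dha"):
            assert r.count_gt4[pufa] <= r.count_gt3[pufa] <= r.richness


class TestLogLogRegression:
    def test_exactly_collinear(self):
        abundance = np.array([10.0, 100.0, 1000.0, 5000.0])
        rich = 2.0 * abundance**0.3
        slope, intercept, r2 = loglog_richness_regression(rich, abundance)
        assert slope == pytest.approx(0.3)
        assert intercept == pytest.approx(math.log(2.0))
        assert r2 == pytest.approx(1.0)

    def test_constant_richness(self):
        slope, _, r2 = loglog_richness_regression([7, 7, 7, 7], [10, 50, 100, 500])
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_recovers_known_slope(self):
        rng = np.random.default_rng(42)
        abundance = np.exp(rng.uniform(math.log(11), math.log(1899), 200))
        rich = np.exp(0.3 * np.log(abundance) + 0.5 + rng.normal(0, 0.05, 200))
        slope, _, r2 = loglog_richness_regression(rich, abundance)
        se = 0.05 / (np.log(abundance).std() * math.sqrt(200))
        assert abs(slope - 0.3) < 3 * se
        assert r2 > 0.9

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            loglog_richness_regression([0, 2, 3], [1, 2, 3])
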