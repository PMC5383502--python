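import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from troph import (
    DietComposition,
    IndividualDiet,
    StomachRecord,
    ValidationError,
    aquatic_overlap,
    coarse_diet_groups,
    individual_diet,
    levins_breadth,
    percent_prey_abundance,
    percentage_overlap,
    proportional_similarity,
    specialization_prevalence,
    surface_fraction,
)
from troph.diet_metrics import coarsen_records


def comp(site="S01", species="salmon", **pct):
    return DietComposition(site, species, dict(pct), n_fish=5, n_nonempty=5)


class TestPercentPreyAbundance:
    def test_population_fullness_ratio(self, make_stomach):
        a = make_stomach("a", {"mayfly": 30.0, "midge": 20.0})
        b = make_stomach("b", {"mayfly": 10.0})
        res = percent_prey_abundance([a, b])
        assert res.percent_abundance["mayfly"] == pytest.approx(100 * 40 / 60)
        assert res.percent_abundance["midge"] == pytest.approx(100 * 20 / 60)

    def test_single_prey_is_100(self, make_stomach):
        res = percent_prey_abundance([make_stomach("a", {"midge": 15.0})])
        assert res.percent_abundance == {"midge": pytest.approx(100.0)}

    def test_identical_fish_match_individual_proportions(self, make_stomach):
        fish = [make_stomach(i, {"x": 30.0, "y": 10.0}) for i in "ab"]
        res = percent_prey_abundance(fish)
        assert res.percent_abundance["x"] == pytest.approx(75.0)
        assert res.percent_abundance["y"] == pytest.approx(25.0)

    def test_empty_stomachs_counted_but_ignored(self, make_stomach):
        fish = [
            make_stomach("a", {"x": 40.0}),
            StomachRecord("b", "S01", "salmon", 80.0, 0.0, {}),
        ]
        res = percent_prey_abundance(fish)
        assert res.n_fish == 2 and res.n_nonempty == 1
        assert res.percent_abundance["x"] == pytest.approx(100.0)

    def test_all_empty_is_error(self):
        fish = [StomachRecord("a", "S01", "salmon", 80.0, 0.0, {})]
        with pytest.raises(ValidationError, match="empty"):
            percent_prey_abundance(fish)

    def test_composition_is_fullness_weighted_mean_of_individuals(self, make_stomach):
        fish = [
            make_stomach("a", {"x": 60.0, "y": 20.0}),
            make_stomach("b", {"x": 10.0, "z": 10.0}),
        ]
        res = percent_prey_abundance(fish)
        weights = np.array([80.0, 20.0]) / 100.0
        inds = [individual_diet(f).proportions for f in fish]
        for taxon in ("x", "y", "z"):
            expected = 100 * sum(w * d.get(taxon, 0) for w, d in zip(weights, inds))
            assert res.percent_abundance.get(taxon, 0.0) == pytest.approx(expected)


class TestPercentageOverlap:
    def test_identical_is_100(self):
        a = comp(x=60.0, y=40.0)
        assert percentage_overlap(a, a) == pytest.approx(100.0)

    def test_disjoint_is_0(self):
        assert percentage_overlap(comp(x=100.0), comp(y=100.0)) == 0.0

    def test_hand_example(self):
        assert percentage_overlap(comp(x=60.0, y=40.0), comp(x=20.0, y=80.0)) == pytest.approx(60.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            percentage_overlap(comp(x=60.0), comp(x=100.0))

    @given(
        st.lists(st.floats(0.01, 1), min_size=2, max_size=8),
        st.lists(st.floats(0.01, 1), min_size=2, max_size=8),
    )
    def test_symmetric_and_bounded(self, wa, wb):
        taxa = [f"t{i}" for i in range(max(len(wa), len(wb)))]
        a = comp(**{t: 100 * w / sum(wa) for t, w in zip(taxa, wa)})
        b = comp(**{t: 100 * w / sum(wb) for t, w in zip(taxa, wb)})
        o1, o2 = percentage_overlap(a, b), percentage_overlap(b, a)
        assert o1 == pytest.approx(o2)
        assert -1e-9 <= o1 <= 100 + 1e-9

    def test_coarse_grouping_never_lowers_overlap(self, taxonomy, make_stomach):
        sal = [make_stomach("a", {"Baetis": 40.0, "Chironomidae": 10.0})]
        bul = [make_stomach("b", {"Ephemerella": 25.0, "Simuliidae": 25.0}, species="bullhead")]
        fine = percentage_overlap(percent_prey_abundance(sal), percent_prey_abundance(bul))
        coarse = percentage_overlap(
            percent_prey_abundance(coarsen_records(sal, taxonomy)),
            percent_prey_abundance(coarsen_records(bul, taxonomy)),
        )
        assert coarse >= fine - 1e-9
        # fine taxa are disjoint; coarse groups share Ephemeroptera (80 vs 50)
        # and Diptera (20 vs 50), so sum-of-minima is 50 + 20 = 70
        assert fine == 0.0 and coarse == pytest.approx(70.0)


class TestAquaticOverlap:
    def test_reduces_to_total_without_surface_prey(self, taxonomy, make_stomach):
        sal = [make_stomach("a", {"Baetis": 30.0, "Chironomidae": 30.0})]
        bul = [make_stomach("b", {"Baetis": 50.0}, species="bullhead")]
        total = percentage_overlap(percent_prey_abundance(sal), percent_prey_abundance(bul))
        assert aquatic_overlap(sal, bul, taxonomy) == pytest.approx(total)

    def test_renormalization_observable(self, taxonomy, make_stomach):
        # salmon half surface prey: after renormalization its aquatic diet is
        # pure mayfly, so aquatic overlap is 100 while total overlap is 50
        sal = [make_stomach("a", {"spider": 25.0, "Baetis": 25.0})]
        bul = [make_stomach("b", {"Baetis": 60.0}, species="bullhead")]
        total = percentage_overlap(percent_prey_abundance(sal), percent_prey_abundance(bul))
        assert total == pytest.approx(50.0)
        assert aquatic_overlap(sal, bul, taxonomy) == pytest.approx(100.0)

    def test_pure_surface_diet_is_error(self, taxonomy, make_stomach):
        sal = [make_stomach("a", {"spider": 20.0})]
        bul = [make_stomach("b", {"Baetis": 60.0}, species="bullhead")]
        with pytest.raises(ValidationError, match="surface"):
            aquatic_overlap(sal, bul, taxonomy)


class TestLevinsBreadth:
    def test_monophagy_is_1(self):
        assert levins_breadth(comp(x=100.0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_uniform_is_k(self, k):
        c = comp(**{f"t{i}": 100.0 / k for i in range(k)})
        assert levins_breadth(c) == pytest.approx(k)

    def test_hand_example(self):
        c = comp(x=50.0, y=25.0, z=25.0)
        assert levins_breadth(c) == pytest.approx(1 / 0.375)

    def test_empty_composition_error(self):
        with pytest.raises(ValidationError):
            levins_breadth(DietComposition("S01", "salmon", {}, 3, 0))

    @given(st.lists(st.floats(0.01, 1), min_size=1, max_size=10))
    def test_bounded_and_label_invariant(self, w):
        pct = {f"t{i}": 100 * v / sum(w) for i, v in enumerate(w)}
        b = levins_breadth(comp(**pct))
        relabeled = levins_breadth(comp(**{f"u{i}": v for i, v in enumerate(pct.values())}))
        assert 1 - 1e-9 <= b <= len(w) + 1e-9
        assert relabeled == pytest.approx(b)


class TestProportionalSimilarity:
    def test_average_individual_scores_1(self):
        pop = comp(x=50.0, y=50.0)
        ind = IndividualDiet("a", {"x": 0.5, "y": 0.5})
        assert proportional_similarity(ind, pop) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "proportions, expected",
        [({"x": 1.0}, 0.5), ({"x": 0.8, "y": 0.2}, 0.7)],
    )
    def test_hand_examples(self, proportions, expected):
        pop = comp(x=50.0, y=50.0)
        assert proportional_similarity(IndividualDiet("a", proportions), pop) == pytest.approx(expected)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            proportional_similarity(IndividualDiet("a", {"x": 0.7}), comp(x=100.0))

    @given(
        st.lists(st.floats(0.01, 1), min_size=1, max_size=6),
        st.lists(st.floats(0.01, 1), min_size=1, max_size=6),
    )
    def test_in_unit_interval(self, wi, wp):
        ind = IndividualDiet("a", {f"t{i}": v / sum(wi) for i, v in enumerate(wi)})
        pop = comp(**{f"t{i}": 100 * v / sum(wp) for i, v in enumerate(wp)})
        psi = proportional_similarity(ind, pop)
        assert 0 < psi <= 1 + 1e-9


class TestSpecializationPrevalence:
    def test_identical_individuals_have_zero_prevalence(self, make_stomach):
        fish = [make_stomach(i, {"x": 20.0, "y": 20.0}) for i in "abc"]
        res = specialization_prevalence(fish)
        assert res.prevalence == pytest.approx(0.0, abs=1e-12)
        assert res.mean_psi == pytest.approx(1.0)

    def test_two_full_specialists(self, make_stomach):
        fish = [make_stomach("a", {"x": 30.0}), make_stomach("b", {"y": 30.0})]
        res = specialization_prevalence(fish)
        assert res.psi_values["a"] == pytest.approx(0.5)
        assert res.psi_values["b"] == pytest.approx(0.5)
        assert res.prevalence == pytest.approx(0.5)
        assert res.prevalence == pytest.approx(1 - res.mean_psi)

    def test_single_nonempty_stomach_is_error(self, make_stomach):
        fish = [
            make_stomach("a", {"x": 30.0}),
            StomachRecord("b", "S01", "salmon", 80.0, 0.0, {}),
        ]
        with pytest.raises(ValidationError, match=">= 2"):
            specialization_prevalence(fish)


class TestSurfaceAndGroups:
    def test_no_surface_taxa_is_zero(self, taxonomy, make_stomach):
        fish = [make_stomach("a", {"Baetis": 30.0})]
        assert surface_fraction(fish, taxonomy) == 0.0

    def test_all_surface_is_100(self, taxonomy, make_stomach):
        fish = [make_stomach("a", {"spider": 10.0, "terrestrial_insect": 10.0})]
        assert surface_fraction(fish, taxonomy) == pytest.approx(100.0)

    def test_mixed_fraction(self, taxonomy, make_stomach):
        fish = [make_stomach("a", {"spider": 25.0, "Baetis": 75.0})]
        assert surface_fraction(fish, taxonomy) == pytest.approx(25.0)

    def test_single_group_collapse(self, taxonomy, make_stomach):
        c = percent_prey_abundance([make_stomach("a", {"Baetis": 40.0})])
        groups = coarse_diet_groups(c, taxonomy)
        assert groups["Ephemeroptera"] == pytest.approx(100.0)
        assert sum(groups.values()) == pytest.approx(100.0)

    def test_fifty_fifty_split(self, taxonomy, make_stomach):
        c = percent_prey_abundance([make_stomach("a", {"Baetis": 20.0, "Chironomidae": 20.0})])
        groups = coarse_diet_groups(c, taxonomy)
        assert groups["Ephemeroptera"] == pytest.approx(50.0)
        assert groups["Diptera"] == pytest.approx(50.0)

    def test_group_sums_are_additive(self, taxonomy, make_stomach):
        c = percent_prey_abundance(
            [make_stomach("a", {"Baetis": 10.0, "Ephemerella": 20.0,
                                "Chironomidae": 5.0, "spider": 15.0})]
        )
        groups = coarse_diet_groups(c, taxonomy)
        assert groups["Ephemeroptera"] == pytest.approx(
            c.percent_abundance["Baetis"] + c.percent_abundance["Ephemerella"]
        )
        assert sum(groups.values()) == pytest.approx(100.0)

    def test_unmapped_taxon_listed(self, taxonomy):
        c = comp(martian=100.0)
        with pytest.raises(ValidationError, match="martian"):
            coarse_diet_groups(c, taxonomy)
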