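"""Unit and property tests for the exact single-cross machinery."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from matdrive import (
    ALL_GENOTYPES,
    Allele,
    DriveParams,
    Genotype,
    cross,
    gametes,
    germline_convert,
    maternal_zygotic_effect,
    parse_genotype,
    round_percent,
)
from matdrive.model import gamete_pool

F = Fraction

probs = st.integers(0, 100).map(lambda k: F(k, 100))
genotypes = st.sampled_from(ALL_GENOTYPES)


def dist_labels(dist):
    return {k: v for k, v in dist.labels().items()}


class TestGermlineConvert:
    def test_perfect_homing_fixes_drive(self):
        out = germline_convert(parse_genotype("GD/WT"), 1)
        assert dist_labels(out) == {"GD/GD": F(1)}

    def test_partial_homing_splits_hdr_vs_nhej(self):
        out = dist_labels(germline_convert(parse_genotype("GD/WT"), F(95, 100)))
        assert out == {"GD/GD": F(19, 20), "GD/R": F(1, 20)}

    @pytest.mark.parametrize("geno", ["R/WT", "WT/WT", "R/R*"])
    def test_no_drive_no_conversion(self, geno):
        g = parse_genotype(geno)
        assert germline_convert(g, F(1, 2)).p(g) == 1

    def test_resistant_allele_immune_to_homing(self):
        # target site destroyed: GD/R stays GD/R at any x
        g = parse_genotype("GD/R")
        assert germline_convert(g, F(3, 4)).p(g) == 1

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            germline_convert(parse_genotype("GD/WT"), F(3, 2))


class TestGametes:
    @pytest.mark.parametrize(
        "geno,expected",
        [
            ("GD/GD", {Allele.GD: F(1)}),
            ("GD/R", {Allele.GD: F(1, 2), Allele.R: F(1, 2)}),
            # provenance label resets at meiosis: R* transmitted as R
            ("R*/R*", {Allele.R: F(1)}),
            ("GD/R*", {Allele.GD: F(1, 2), Allele.R: F(1, 2)}),
        ],
    )
    def test_mendelian_segregation(self, geno, expected):
        assert dict(gametes(parse_genotype(geno))) == expected

    def test_marginal_gamete_pool_after_homing(self):
        # x + (1-x)/2 drive gametes, (1-x)/2 resistant, at x = 0.95
        pool = gamete_pool(parse_genotype("GD/WT"), F(95, 100))
        assert dict(pool) == {Allele.GD: F(39, 40), Allele.R: F(1, 40)}


class TestMaternalZygoticEffect:
    def test_identity_without_drive_mother(self):
        z = parse_genotype("GD/WT")
        assert maternal_zygotic_effect(z, False, F(87, 100)).p(z) == 1

    def test_single_wt_allele_bernoulli(self):
        out = dist_labels(
            maternal_zygotic_effect(parse_genotype("GD/WT"), True, F(87, 100))
        )
        assert out == {"GD/WT": F(13, 100), "GD/R*": F(87, 100)}

    def test_two_wt_alleles_act_independently(self):
        out = dist_labels(
            maternal_zygotic_effect(parse_genotype("WT/WT"), True, F(87, 100))
        )
        y = F(87, 100)
        assert out == {
            "WT/WT": (1 - y) ** 2,
            "R*/WT": 2 * y * (1 - y),
            "R*/R*": y**2,
        }

    def test_non_wt_alleles_untouched(self):
        z = parse_genotype("GD/R")
        assert maternal_zygotic_effect(z, True, F(1)).p(z) == 1


class TestCross:
    def test_wildtype_cross_trivial(self, paper_params):
        out = cross(parse_genotype("WT/WT"), parse_genotype("WT/WT"), paper_params)
        assert dist_labels(out) == {"WT/WT": F(1)}

    def test_drive_mother_worked_example(self, paper_params):
        out = dist_labels(
            cross(parse_genotype("GD/WT"), parse_genotype("WT/WT"), paper_params)
        )
        assert out == {
            "GD/WT": F(507, 4000),   # (1+x)/2 * (1-y) = 0.12675
            "GD/R*": F(3393, 4000),  # (1+x)/2 * y     = 0.84825
            "R/WT": F(13, 4000),     # (1-x)/2 * (1-y) = 0.00325
            "R/R*": F(87, 4000),     # (1-x)/2 * y     = 0.02175
        }

    def test_drive_father_no_maternal_effect(self, paper_params):
        out = dist_labels(
            cross(parse_genotype("WT/WT"), parse_genotype("GD/WT"), paper_params)
        )
        assert out == {"GD/WT": F(39, 40), "R/WT": F(1, 40)}

    def test_fitness_hook_reweights(self, paper_params):
        lethal = {parse_genotype("GD/R*").canonical(): F(0)}
        out = cross(parse_genotype("GD/WT"), parse_genotype("WT/WT"),
                    paper_params, fitness=lethal)
        labels = dist_labels(out)
        assert "GD/R*" not in labels
        assert sum(labels.values()) == 1

    def test_percent_rendering_round_half_even(self, paper_params):
        out = cross(parse_genotype("GD/WT"), parse_genotype("WT/WT"), paper_params)
        assert round_percent(out.p_label("GD/R*"), 1) == 84.8
        assert round_percent(F(25, 1000), 1) == 2.5
        assert round_percent(F(125, 10000), 1) == 1.2  # ties to even


class TestInvariants:
    @given(g=genotypes, x=probs)
    def test_germline_distribution_sums_to_one(self, g, x):
        assert sum(germline_convert(g, x).values()) == 1

    @given(mother=genotypes, father=genotypes, x=probs, y=probs)
    def test_cross_sums_to_one_exactly(self, mother, father, x, y):
        out = cross(mother, father, DriveParams(x, y))
        assert sum(out.values()) == 1

    @given(mother=genotypes, father=genotypes, x=probs)
    def test_no_maternal_mutation_without_y(self, mother, father, x):
        out = cross(mother, father, DriveParams(x, F(0)))
        assert all(Allele.RSTAR not in g for g in out)

    @given(mother=genotypes, father=genotypes, x=probs)
    def test_parent_symmetry_when_y_zero(self, mother, father, x):
        params = DriveParams(x, F(0))
        assert (cross(mother, father, params).labels()
                == cross(father, mother, params).labels())

    def test_perfect_homing_wt_mother_yields_no_resistance(self):
        out = cross(parse_genotype("WT/WT"), parse_genotype("GD/WT"),
                    DriveParams(F(1), F(87, 100)))
        assert all(not a.resistant for g in out for a in g)

    @given(mother=genotypes, father=genotypes, x=probs, y=probs)
    def test_allele_frequencies_sum_to_one(self, mother, father, x, y):
        out = cross(mother, father, DriveParams(x, y))
        assert sum(out.allele_frequencies().values()) == 1


class TestParsing:
    @pytest.mark.parametrize("text", ["GD/WT", "R*/R", "RSTAR/WT", "+/+"])
    def test_roundtrip(self, text):
        g = parse_genotype(text)
        assert parse_genotype(g.label).canonical() == g.canonical()

    def test_unordered_equality_of_labels(self):
        assert parse_genotype("WT/GD").label == parse_genotype("GD/WT").label == "GD/WT"

    @pytest.mark.parametrize("bad", ["GD", "GD/WT/R", "XX/WT"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_genotype(bad)

    def test_ordered_pair_preserves_parental_origin(self):
        g = Genotype(Allele.WT, Allele.GD)
        assert g.maternal is Allele.WT and g.paternal is Allele.GD
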