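"""Lipid shorthand grammar, class aggregation, QC rules and transformation network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from liquidmet.lipidomics import (
    AnnotationRecord,
    Chain,
    LipidMatrix,
    LipidParseError,
    LipidSpecies,
    aggregate_classes,
    annotation_qc,
    class_network_zscores,
    normalize_median_autoscale,
    odd_even_ratio,
    parse_lipid_shorthand,
)

#: every species name printed in the study's figures and text
PRINTED_NAMES = [
    "FA 16:0", "FA 18:1", "FA 21:0", "LPC 18:3",
    "DG 16:0_18:1", "DG 16:0_18:2", "DG 18:0_18:1", "DG 18:1_18:2",
    "DG 18:1_20:4", "PE 18:0_22:5", "PC O-18:1_20:4",
    "Cer 18:1;20/24", "SM 18:2;20/24:3",
]


class TestParser:
    def test_single_chain_fatty_acid(self):
        sp = parse_lipid_shorthand("FA 16:0")
        assert sp.class_code == "FA"
        assert sp.chains == (Chain(16, 0, 0),)
        assert sp.annotation_level == "molecular_species"

    def test_two_chain_diacylglycerol(self):
        sp = parse_lipid_shorthand("DG 18:1_20:4")
        assert sp.class_code == "DG"
        assert sp.chains == (Chain(18, 1, 0), Chain(20, 4, 0))
        assert sp.separators == ("_",)

    def test_ether_prefix_becomes_distinct_class(self):
        sp = parse_lipid_shorthand("PC O-18:1_20:4")
        assert sp.ether_prefix == "O"
        assert sp.class_key == "PC-O"

    def test_sphingoid_oxygen_spellings_equivalent(self):
        letter = parse_lipid_shorthand("Cer 18:1;2O/24")
        digit = parse_lipid_shorthand("Cer 18:1;20/24")
        assert letter.chains == digit.chains
        assert letter.chains[0].extra_oxygens == 2
        assert digit.chains[0].ambiguous_oxygen and not letter.chains[0].ambiguous_oxygen

    def test_chain_without_double_bond_count(self):
        sp = parse_lipid_shorthand("Cer 18:1;2O/24")
        assert sp.chains[1] == Chain(24, 0, 0)

    @pytest.mark.parametrize("name", PRINTED_NAMES)
    def test_printed_names_round_trip_byte_identically(self, name):
        assert parse_lipid_shorthand(name).format() == name

    @pytest.mark.parametrize("bad", ["XX 16:0", "FA", "FA 0:1", "PC 18:1_", "FA 16:0;5",
                                     "FA 16:0_18:1"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises((LipidParseError, ValueError)):
            parse_lipid_shorthand(bad)

    def test_parse_error_carries_position(self):
        with pytest.raises(LipidParseError) as err:
            parse_lipid_shorthand("DG 18:1_xx")
        assert err.value.pos > 0

    @given(st.data())
    def test_grammar_generated_names_round_trip(self, data):
        """format(parse(x)) == x and parse(format(s)) == s over the grammar."""
        cls = data.draw(st.sampled_from(["PC", "PE", "PI", "DG", "Cer", "SM"]))
        n_chains = data.draw(st.integers(1, 3))
        prefix = data.draw(st.sampled_from(["", "O", "P"])) if cls == "PC" else ""
        chains = tuple(
            Chain(data.draw(st.integers(1, 30)), data.draw(st.integers(0, 6)),
                  data.draw(st.sampled_from([0, 0, 1, 2, 3])))
            for _ in range(n_chains))
        seps = tuple(data.draw(st.sampled_from(["_", "/"])) for _ in range(n_chains - 1))
        sp = LipidSpecies(class_code=cls, ether_prefix=prefix, chains=chains,
                          separators=seps,
                          annotation_level="molecular_species" if n_chains > 1 else "species")
        text = sp.format()
        back = parse_lipid_shorthand(text)
        assert back.chains == sp.chains
        assert back.class_key == sp.class_key
        assert back.format() == text


def matrix_from(data: dict, groups=None, **kw) -> LipidMatrix:
    return LipidMatrix(concentrations=pd.DataFrame(data).set_index("species"),
                       groups=groups, **kw)


class TestAggregation:
    def test_single_class_composition_100(self):
        m = matrix_from({"species": ["FA 16:0", "FA 18:1"], "s1": [1.0, 2.0]})
        comp = aggregate_classes(m)
        assert comp.composition.loc["FA", "s1"] == pytest.approx(100.0)

    def test_three_to_one_split(self):
        m = matrix_from({"species": ["FA 16:0", "DG 16:0_18:1"], "s1": [3.0, 1.0]})
        comp = aggregate_classes(m)
        assert comp.composition.loc["FA", "s1"] == pytest.approx(75.0)
        assert comp.composition.loc["DG", "s1"] == pytest.approx(25.0)

    def test_compositions_sum_to_100_and_totals_conserved(self, rng):
        names = ["PC 16:0_18:1", "PC O-16:0_18:1", "FA 16:0", "SM 18:1;2O/16:0"]
        vals = rng.uniform(0.1, 5.0, size=(4, 3))
        m = matrix_from({"species": names, "a": vals[:, 0], "b": vals[:, 1], "c": vals[:, 2]})
        comp = aggregate_classes(m)
        np.testing.assert_allclose(comp.composition.sum(axis=0), 100.0)
        np.testing.assert_allclose(comp.totals.sum(axis=0), vals.sum(axis=0))

    def test_ether_fold_flag_moves_species_once(self):
        names = ["PC 16:0_18:1", "PC O-16:0_18:1"]
        m_split = matrix_from({"species": names, "s1": [3.0, 1.0]})
        m_fold = matrix_from({"species": names, "s1": [3.0, 1.0]}, fold_ether=True)
        assert set(aggregate_classes(m_split).totals.index) == {"PC", "PC-O"}
        folded = aggregate_classes(m_fold).totals
        assert set(folded.index) == {"PC"}
        assert folded.loc["PC", "s1"] == pytest.approx(4.0)


class TestOddEven:
    def test_all_even_is_zero(self):
        m = matrix_from({"species": ["FA 16:0", "DG 16:0_18:1"], "s1": [1.0, 1.0]})
        assert odd_even_ratio(m) == pytest.approx(0.0)

    def test_equal_concentration_half_odd(self):
        m = matrix_from({"species": ["FA 21:0", "FA 16:0"], "s1": [1.0, 1.0]})
        assert odd_even_ratio(m, weighting="concentration") == pytest.approx(50.0)

    def test_species_count_weighting(self):
        m = matrix_from({"species": ["FA 21:0", "FA 16:0", "FA 18:1", "FA 18:0"],
                         "s1": [1.0, 5.0, 5.0, 5.0]})
        assert odd_even_ratio(m, weighting="species_count") == pytest.approx(25.0)


class TestAnnotationQc:
    def rec(self, ppm, score):
        theo = 760.5851
        return AnnotationRecord("PC 16:0_18:1", theo, theo * (1 + ppm * 1e-6), score)

    def test_ppm_30_rejected(self):
        accepted, _ = annotation_qc([self.rec(30.0, 95.0)])
        assert accepted == []

    @pytest.mark.parametrize("score", [79.0, 80.0])
    def test_score_at_or_below_80_rejected(self, score):
        accepted, _ = annotation_qc([self.rec(4.3, score)])
        assert accepted == []

    def test_good_record_accepted_with_mean_ppm(self):
        accepted, mean_ppm = annotation_qc([self.rec(4.30, 96.7), self.rec(0.0, 99.0)])
        assert len(accepted) == 2
        assert mean_ppm == pytest.approx(2.15, abs=1e-6)

    def test_exact_match_zero_ppm(self):
        accepted, mean_ppm = annotation_qc([self.rec(0.0, 90.0)])
        assert len(accepted) == 1 and mean_ppm == pytest.approx(0.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            AnnotationRecord("x", -1.0, 1.0, 90.0)


class TestNormalization:
    def test_hand_computed_2x2(self):
        # columns /median -> (0.5,1.5) and (0.4,1.6); rows autoscale to +/- 1/sqrt(2)
        m = matrix_from({"species": ["FA 16:0", "FA 18:1"], "s1": [1.0, 3.0],
                         "s2": [2.0, 8.0]})
        out, degenerate = normalize_median_autoscale(m)
        r = 1.0 / np.sqrt(2.0)
        np.testing.assert_allclose(out.to_numpy(), [[r, -r], [-r, r]], atol=1e-12)
        assert degenerate == []

    def test_rows_standardized(self, rng):
        vals = rng.lognormal(0, 1, size=(6, 5))
        m = matrix_from({"species": ["PC 16:0_18:1", "PC 16:0_18:2", "FA 16:0",
                                     "FA 18:1", "DG 16:0_18:1", "SM 18:1;2O/16:0"],
                         **{f"s{i}": vals[:, i] for i in range(5)}})
        out, _ = normalize_median_autoscale(m)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_sample_scale_invariance(self, rng):
        vals = rng.lognormal(0, 1, size=(4, 3))
        names = ["FA 16:0", "FA 18:1", "DG 16:0_18:1", "PC 16:0_18:1"]
        m1 = matrix_from({"species": names, **{f"s{i}": vals[:, i] for i in range(3)}})
        scaled = vals.copy()
        scaled[:, 1] *= 7.5
        m2 = matrix_from({"species": names, **{f"s{i}": scaled[:, i] for i in range(3)}})
        np.testing.assert_allclose(normalize_median_autoscale(m1)[0],
                                   normalize_median_autoscale(m2)[0], atol=1e-9)

    def test_zero_variance_row_flagged_centered_only(self):
        m = matrix_from({"species": ["FA 16:0", "FA 18:1", "DG 16:0_18:1"],
                         "s1": [2.0, 1.0, 3.0], "s2": [4.0, 1.0, 9.0]})
        out, degenerate = normalize_median_autoscale(m)
        # FA 16:0 / sample-median is 1 in both samples -> zero variance
        assert degenerate == ["FA 16:0"]
        np.testing.assert_allclose(out.loc["FA 16:0"], 0.0, atol=1e-12)


def network_matrix(cer_a, cer_b):
    """Six-sample SM/Cer matrix with SM pinned at 1 (log-ratio = ln Cer)."""
    names = ["SM 18:1;2O/16:0", "Cer 18:1;2O/16:0"]
    data = {"species": names}
    groups = {}
    for i, v in enumerate(cer_a):
        data[f"a{i}"] = [1.0, v]
        groups[f"a{i}"] = "AML"
    for i, v in enumerate(cer_b):
        data[f"b{i}"] = [1.0, v]
        groups[f"b{i}"] = "HD"
    return matrix_from(data, groups=groups)


class TestNetwork:
    ADJ = (("SM", "Cer"),)

    def test_hand_computed_3v3_z(self):
        """log-ratios 1,2,3 vs 0,0,1: pooled-SE standardized difference = 2.5."""
        m = network_matrix(np.exp([1, 2, 3]), np.exp([0, 0, 1]))
        net = class_network_zscores(m, adjacency=self.ADJ, group_order=("AML", "HD"))
        assert net.edges[0].z == pytest.approx(2.5, abs=1e-9)
        assert net.edges[0].mean_log_ratio["AML"] == pytest.approx(2.0, abs=1e-12)

    def test_identical_groups_give_zero(self):
        m = network_matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        net = class_network_zscores(m, adjacency=self.ADJ)
        assert net.edges[0].z == pytest.approx(0.0, abs=1e-12)

    def test_swapping_groups_negates_z(self):
        m = network_matrix(np.exp([1, 2, 3]), np.exp([0, 0.5, 1]))
        z_ab = class_network_zscores(m, adjacency=self.ADJ, group_order=("AML", "HD"))
        z_ba = class_network_zscores(m, adjacency=self.ADJ, group_order=("HD", "AML"))
        assert z_ab.edges[0].z == pytest.approx(-z_ba.edges[0].z, abs=1e-12)

    def test_sample_scale_invariance(self):
        m1 = network_matrix(np.exp([1, 2, 3]), np.exp([0, 0.5, 1]))
        conc = m1.concentrations.copy()
        conc["a0"] *= 13.0  # multiply one whole sample
        m2 = LipidMatrix(concentrations=conc, groups=m1.groups)
        z1 = class_network_zscores(m1, adjacency=self.ADJ).edges[0].z
        z2 = class_network_zscores(m2, adjacency=self.ADJ).edges[0].z
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_missing_class_raises(self):
        m = network_matrix([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="absent"):
            class_network_zscores(m, adjacency=(("PC", "DG"),))

    def test_export_shapes(self):
        m = network_matrix(np.exp([1, 2, 3]), np.exp([0, 0, 1]))
        net = class_network_zscores(m, adjacency=self.ADJ)
        assert net.to_networkx().number_of_edges() == 1
        assert list(net.to_frame().columns[:3]) == ["reactant", "product", "z"]
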