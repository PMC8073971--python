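from collections import namedtuple

import pytest

from omseval.evaluate import (
    classify_color,
    color_fraction_curves,
    compute_fdr,
    delta_m_group,
    evaluate_psms,
    lipr,
    strategy_specific_sets,
    summarize_colors,
    summarize_scores,
    threshold_at_fdr,
)
from omseval.masses import MONOISOTOPIC, peptide_mass
from omseval.proteome import Peptide
from omseval.realign import best_shift
from omseval.spectra import generate_spectrum
from omseval.synthetic import EditSpec, plant_edits

from _oracles import naive_raw_lipr

FakePsm = namedtuple("FakePsm", "score hit_origin delta_m")

# cumulative (target, decoy) counts per minimum raw SPC, Strategy1
STRATEGY1_ROWS = {
    7: (268589, 186815), 8: (188951, 119607), 9: (114435, 41436),
    10: (95188, 34633), 11: (61560, 11824), 12: (52784, 11414),
    13: (37403, 1260), 14: (31769, 1219), 15: (25307, 398),
    16: (21177, 391), 17: (17160, 70), 18: (14241, 68),
    19: (11498, 52), 20: (9467, 51),
}
# cumulative (target, decoy) counts per minimum shift SPC, Strategy2
# (odd cutoffs only; shift SPC is even so consecutive rows agree)
STRATEGY2_ROWS = {
    7: (282487, 172917), 9: (273353, 160257), 11: (268572, 155711),
    13: (259622, 146571), 15: (227627, 120264), 17: (114222, 26147),
    19: (73529, 3364), 21: (57784, 534),
}


def psms_from_cumulative(rows):
    """Expand a cumulative score table into one stand-in PSM per count."""
    scores = sorted(rows)
    psms = []
    for i, s in enumerate(scores):
        t, d = rows[s]
        if i + 1 < len(scores):
            t -= rows[scores[i + 1]][0]
            d -= rows[scores[i + 1]][1]
        psms += [FakePsm(s, "target", 1.0)] * t + [FakePsm(s, "decoy", 1.0)] * d
    return psms


class TestFdr:
    @pytest.mark.parametrize(
        "target,decoy,expected_percent",
        [(17160, 70, 0.41), (268589, 186815, 41.02), (57784, 534, 0.92)],
    )
    def test_decoy_over_total_formula(self, target, decoy, expected_percent):
        psms = [FakePsm(10, "target", 1.0)] * target + [FakePsm(10, "decoy", 1.0)] * decoy
        row = compute_fdr(psms, 0)
        assert row.total_target == target and row.total_decoy == decoy
        assert round(100 * row.fdr, 2) == expected_percent

    def test_no_decoys_means_zero_fdr(self):
        assert compute_fdr([FakePsm(8, "target", 0.0)] * 5, 0).fdr == 0

    def test_empty_restriction_has_no_fdr(self):
        row = compute_fdr([FakePsm(8, "target", 0.0)], min_score=9)
        assert row.fdr is None

    def test_counts_split_by_group_and_conserved(self):
        psms = [
            FakePsm(8, "target", 0.0), FakePsm(8, "decoy", 2.0),
            FakePsm(9, "target", -1.0), FakePsm(9, "target", 3.0),
        ]
        row = compute_fdr(psms, 0)
        assert row.counts[("G1", "target")] == 1
        assert row.counts[("G2", "decoy")] == 1
        assert row.counts[("G3", "target")] == 1
        assert sum(row.counts.values()) == row.total_target + row.total_decoy == 4


class TestThresholdAtFdr:
    def test_strategy1_published_distribution_gives_17(self):
        psms = psms_from_cumulative(STRATEGY1_ROWS)
        assert threshold_at_fdr(psms, 0.01) == 17

    def test_strategy2_published_distribution_gives_21(self):
        psms = psms_from_cumulative(STRATEGY2_ROWS)
        assert threshold_at_fdr(psms, 0.01) == 21

    def test_all_target_input_returns_smallest_score(self):
        psms = [FakePsm(s, "target", 1.0) for s in (9, 12, 8)]
        assert threshold_at_fdr(psms, 0.01) == 8

    def test_unreachable_alpha_returns_none(self):
        psms = [FakePsm(8, "decoy", 1.0)]
        assert threshold_at_fdr(psms, 0.01) is None
        with pytest.raises(ValueError):
            threshold_at_fdr(psms, 1.5)


def delta(bait, hit):
    return peptide_mass(bait) - peptide_mass(hit)


class TestClassification:
    @pytest.mark.parametrize(
        "bait,hit,expected",
        [
            # one serine inserted at a known location -> unambiguous
            ("PEPSTIDEK", "PEPTIDEK", "Green"),
            # EPPNPE deleted from the hit: content read off the hit
            ("TESTPTIDEK", "TESTEPPNPEPTIDEK", "Green"),
            # VH insertion: VH and HV share the mass -> order ambiguous
            ("PEPVHTIDEK", "PEPTIDEK", "Orange"),
            # same mass, different sequences: no realignment possible
            ("LESGAEEK", "LEGSAEEK", "Red"),
        ],
    )
    def test_contract_scenarios(self, bait, hit, expected):
        assert classify_color(bait, hit, delta(bait, hit)) == expected

    @pytest.mark.parametrize(
        "bait,hit,expected",
        [
            ("PEPLTIDEK", "PEPTIDEK", "Orange"),  # L insertion: could be I
            ("PEPTIDEGGK", "PEPTIDEK", "Orange"),  # dipeptide insertion
            ("PEPTIDEK", "PEPTIDEGGK", "Green"),  # GG deletion
            ("PEPTIEEK", "PEPTIDEK", "Green"),  # D->E substitution, unique mass
            ("PEPTIIEK", "PEPTVDEK", "Orange"),  # compound local edit
            ("AEPTIDEG", "PEPTIDEK", "Red"),  # edits at both termini
            ("WEPTIWEK", "PEPTIDEK", "Red"),  # two separated substitutions
        ],
    )
    def test_planted_edit_varieties(self, bait, hit, expected):
        assert classify_color(bait, hit, delta(bait, hit)) == expected

    def test_substitution_with_ambiguous_replacement_is_orange(self):
        bait, hit = "PEPTIDEK", "PEPTGDEK"  # G -> I, but I and L share the mass
        assert classify_color(bait, hit, delta(bait, hit)) == "Orange"

    def test_delta_inconsistent_with_edit_is_red(self):
        assert classify_color("PEPSTIDEK", "PEPTIDEK", MONOISOTOPIC["W"]) == "Red"

    def test_delta_zero_always_red(self):
        assert classify_color("ABC", "CBA", 0.0) == "Red"

    def test_agrees_with_construction_truth_on_small_alphabet(self):
        sources = [Peptide.from_sequence(s) for s in
                   ("GASPVGAK", "PSVGAPSVK", "AAGSPVVGSK", "VSPGAVSPGAK")]
        for kind in ("insert1", "insertK", "delete", "substitute", "twoSite"):
            baits, truth = plant_edits(
                sources, EditSpec(kind=kind, n_baits=20, seed=3, residues="GASPV")
            )
            for bait, row in zip(baits, truth.itertuples()):
                got = classify_color(row.bait, row.source, delta(row.bait, row.source))
                assert got == row.expected_color, (kind, row.bait, row.source)


class TestLipr:
    def test_zero_when_all_shared_masses_agree_in_sequence(self):
        a, b = generate_spectrum("AAADIGGK"), generate_spectrum("AAADIGGR")
        assert lipr(a, b) == 0.0

    def test_internal_swap_fixture_matches_brute_force(self):
        a, b = generate_spectrum("LESGAEEK"), generate_spectrum("LEGSAEEK")
        assert lipr(a, b) == pytest.approx(8 / 14)
        assert lipr(a, b) == pytest.approx(naive_raw_lipr("LESGAEEK", "LEGSAEEK"))

    def test_symmetric_for_equal_mass_pairs(self):
        a, b = generate_spectrum("LESGAEEK"), generate_spectrum("LEGSAEEK")
        assert lipr(a, b) == lipr(b, a)

    def test_correct_realignment_has_zero_lipr(self, worked_example_spectra):
        bait, hit = worked_example_spectra
        alignment = best_shift(bait, hit, MONOISOTOPIC["D"])
        assert lipr(bait, hit, alignment) == 0.0

    def test_bounded_and_decoys_less_informative(self, planted_study):
        evaluations = evaluate_psms(
            planted_study["best2"],
            planted_study["bait_spectra"],
            planted_study["db_spectra"],
        )
        assert all(0 <= e.lipr <= 1 for e in evaluations)
        target = [e.lipr for e in evaluations if e.psm.hit_origin == "target"]
        decoy = [e.lipr for e in evaluations if e.psm.hit_origin == "decoy"]
        assert decoy, "study fixture yields no decoy best PSMs"
        assert sum(decoy) / len(decoy) > sum(target) / len(target)


class TestGroupsAndReports:
    def test_delta_m_group_signs(self):
        assert delta_m_group(0.0) == "G1"
        assert delta_m_group(MONOISOTOPIC["D"]) == "G2"
        assert delta_m_group(-MONOISOTOPIC["G"]) == "G3"

    def test_equal_composition_peptides_land_exactly_in_g1(self):
        assert delta_m_group(delta("LESGAEEK", "LEGSAEEK")) == "G1"

    def test_score_table_counts_are_conserved(self):
        psms = [FakePsm(7, "target", 0.0)] * 6 + [FakePsm(9, "decoy", -1.0)] * 4
        table = summarize_scores(psms)
        first = table.iloc[0]
        assert first["total_target"] + first["total_decoy"] == 10
        group_cols = [c for c in table.columns if c.startswith("dm")]
        assert first[group_cols].sum() == 10

    def test_strategy_specific_sets_have_equal_size(self, planted_study):
        ss1, ss2 = strategy_specific_sets(
            planted_study["best1"], planted_study["best2"]
        )
        assert len(ss1) == len(ss2)
        assert all(p.strategy == 1 for p in ss1)
        assert all(p.strategy == 2 for p in ss2)
        assert {p.bait_id for p in ss1} == {p.bait_id for p in ss2}

    def test_empty_input_gives_empty_reports(self):
        assert len(summarize_scores([])) == 0
        summary = summarize_colors([], label="empty")
        assert summary.iloc[0]["total"] == 0
        assert summary.iloc[0]["mean_lipr_percent"] is None

    def test_color_fractions_sum_to_one(self, planted_study):
        evaluations = evaluate_psms(
            planted_study["best2"][:50],
            planted_study["bait_spectra"],
            planted_study["db_spectra"],
        )
        curves = color_fraction_curves(evaluations)
        sums = curves[["frac_green", "frac_orange", "frac_red"]].sum(axis=1)
        assert ((sums - 1).abs() < 1e-6).all()
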