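"""Strict-majority walk, origin/HGT/gain/loss reporting, phenotype tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import paleofam as pf
from paleofam.inference import l1_median, maximal_credited

from conftest import make_record, random_records


def l1_oracle(values):
    """Brute force: smallest integer minimising sum |x - v|."""
    best, best_cost = None, None
    for x in range(0, max(values) + 1):
        cost = sum(abs(x - v) for v in values)
        if best_cost is None or cost < best_cost:
            best, best_cost = x, cost
    return best


def tree_for(counts, sequenced=None):
    """One genus with len(counts) species children."""
    sequenced = sequenced or [True] * len(counts)
    recs = [
        make_record(f"s{i}", count=c, sequenced=sq)
        for i, (c, sq) in enumerate(zip(counts, sequenced))
    ]
    return pf.build_taxonomy(recs)


def genus_assignment(counts, sequenced=None):
    root = tree_for(counts, sequenced)
    amap = pf.assign_ancestral_counts(root)
    genus = root.find("G")
    return amap[genus]


class TestL1Median:
    @given(st.lists(st.integers(min_value=1, max_value=40), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force(self, values):
        assert l1_median(values) == l1_oracle(values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            l1_median([])


class TestMajorityWalk:
    def test_single_child_is_a_strict_majority(self):
        a = genus_assignment([3])
        assert a.majority_passed and a.inferred_count == 3

    def test_one_of_three_fails_majority(self):
        a = genus_assignment([2, 0, 0])
        assert not a.majority_passed and a.inferred_count is None

    @pytest.mark.parametrize(
        "counts,expected",
        [([2, 5, 6], 5), ([1, 3], 1), ([1, 5, 6, 7], 5), ([5, 2], 2)],
    )
    def test_l1_median_of_bearing_children(self, counts, expected):
        a = genus_assignment(counts)
        assert a.majority_passed and a.inferred_count == expected

    def test_unsurveyed_children_ignored_entirely(self):
        # two unsequenced zero-count species must not dilute the majority
        a = genus_assignment([4, 0, 0], sequenced=[True, False, False])
        assert a.surveyed_children == 1
        assert a.majority_passed and a.inferred_count == 4

    def test_counts_must_be_attached(self):
        root = tree_for([1])
        root.species()[0].observed_count = None
        with pytest.raises(ValueError, match="observed"):
            pf.assign_ancestral_counts(root)

    def test_majority_soundness_and_median_oracle_on_random_trees(self):
        rng = np.random.default_rng(202)
        for _ in range(60):
            root = pf.build_taxonomy(random_records(rng))
            amap = pf.assign_ancestral_counts(root)
            for node, a in amap.items():
                if node.is_species():
                    continue
                surveyed = [c for c in node.children if c.surveyed]
                supporting = [
                    c for c in surveyed
                    if amap[c].majority_passed and (amap[c].inferred_count or 0) > 0
                ]
                assert a.surveyed_children == len(surveyed)
                assert a.supporting_children == len(supporting)
                if node.rank == "root":
                    continue
                assert a.majority_passed == (2 * len(supporting) > len(surveyed))
                if a.majority_passed:
                    assert a.inferred_count == l1_oracle(
                        [amap[c].inferred_count for c in supporting]
                    )


class TestOriginAndHgt:
    def test_survey_origin_is_thermoplasmata(self, survey_tree):
        amap = pf.assign_ancestral_counts(survey_tree)
        origin = pf.find_origin(survey_tree, amap)
        assert origin.name == "Thermoplasmata" and origin.rank == "class"

    def test_family_confined_to_one_genus(self):
        recs = [
            make_record("a", count=2),
            make_record("b", count=1),
            make_record("c", genus="G2", count=0),
            make_record("d", klass="C2", order="O2", family="F2", genus="G3",
                        count=0),
        ]
        root = pf.build_taxonomy(recs)
        amap = pf.assign_ancestral_counts(root)
        origin = pf.find_origin(root, amap)
        assert origin.name == "G" and origin.rank == "genus"
        assert pf.detect_hgt(root, amap, origin) == []

    def test_no_homologues_is_family_absent(self):
        root = tree_for([0, 0])
        amap = pf.assign_ancestral_counts(root)
        assert pf.find_origin(root, amap) is None

    def test_survey_hgt_candidates(self, survey_tree):
        report, _ = pf.build_event_report(survey_tree)
        assert set(report.hgt_candidates) == {
            "Sulfolobales",
            "Thermofilaceae",
            "Caldivirga",
            "Thermoproteus",
            "Pyrobaculum sp. 1860",
        }
        assert report.origin not in report.hgt_candidates

    def test_bearers_partition_into_reported_clades(self):
        # origin + candidates cover every homologue-bearing species once
        rng = np.random.default_rng(77)
        for _ in range(40):
            root = pf.build_taxonomy(random_records(rng))
            amap = pf.assign_ancestral_counts(root)
            clades = maximal_credited(root, amap)
            for tip in root.species():
                covering = [
                    c for c in clades if tip in list(c.walk())
                ]
                assert len(covering) <= 1  # maximal clades are disjoint
                if (tip.observed_count or 0) > 0:
                    assert len(covering) == 1

    def test_raising_a_count_never_uncredits_a_clade(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            recs = random_records(rng)
            bearers = [r for r in recs if r.homologue_count > 0]
            if not bearers:
                continue
            root = pf.build_taxonomy(recs)
            amap = pf.assign_ancestral_counts(root)
            before = {n.name for n, a in amap.items() if a.majority_passed}
            victim = bearers[int(rng.integers(len(bearers)))]
            bumped = [
                r if r is not victim
                else pf.SpeciesRecord(
                    name=r.name, lineage=r.lineage,
                    homologue_count=r.homologue_count + 3,
                    genome_sequenced=r.genome_sequenced,
                )
                for r in recs
            ]
            root2 = pf.build_taxonomy(bumped)
            amap2 = pf.assign_ancestral_counts(root2)
            after = {n.name for n, a in amap2.items() if a.majority_passed}
            assert before <= after


class TestGainsLosses:
    def test_uniform_counts_give_no_events(self):
        root = tree_for([2, 2, 2])
        report, _ = pf.build_event_report(root)
        assert report.gains == [] and report.losses == []
        assert report.complete_losses == []

    def test_lineage_specific_expansion_flagged_as_gain(self):
        # Caldivirga-style: one genus at 3 against a background of 1
        recs = [
            make_record("bg1", genus="G1", count=1),
            make_record("bg2", genus="G2", count=1),
            make_record("expanded", genus="G3", count=3),
        ]
        report, _ = pf.build_event_report(pf.build_taxonomy(recs))
        gains = {(e.taxon, e.child_count, e.parent_count) for e in report.gains}
        assert ("G3", 3, 1) in gains or ("expanded", 3, 1) in gains
        assert all(e.child_count > e.parent_count for e in report.gains)

    def test_complete_loss_reported_separately(self):
        # genus credited at 2 by a 2/3 majority; the zero-count species is a
        # complete loss, kept apart from paralogue reductions
        report, _ = pf.build_event_report(tree_for([2, 2, 0]))
        assert [e.taxon for e in report.complete_losses] == ["s2"]
        assert all(0 < e.child_count < e.parent_count for e in report.losses)

    def test_events_match_exhaustive_pair_scan(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            root = pf.build_taxonomy(random_records(rng))
            amap = pf.assign_ancestral_counts(root)
            report, _ = pf.build_event_report(root)
            expected_gains, expected_losses = set(), set()
            for node in root.walk():
                if not amap[node].majority_passed:
                    continue
                for child in node.children:
                    if not child.surveyed or amap[child].inferred_count is None:
                        continue
                    c, p = amap[child].inferred_count, amap[node].inferred_count
                    if c > p:
                        expected_gains.add((child.name, c, p))
                    elif 0 < c < p:
                        expected_losses.add((child.name, c, p))
            assert {
                (e.taxon, e.child_count, e.parent_count) for e in report.gains
            } == expected_gains
            assert {
                (e.taxon, e.child_count, e.parent_count) for e in report.losses
            } == expected_losses


class TestPhenotypeCrosstab:
    def test_hand_tallied_toy_table(self):
        recs = [
            make_record("a", count=1, hyper=True, acid=True),
            make_record("b", count=2, hyper=False, acid=True),
            make_record("c", count=0, hyper=True, acid=True),
            make_record("d", count=0, hyper=True, acid=None),
            make_record("e", count=0, hyper=False, acid=False),
        ]
        ct = pf.phenotype_crosstab(recs)
        assert ct.bearers_not_hyperthermophilic == ["b"]
        assert ct.thermoacidophiles_without_homologue == ["c"]
        # presence x hyperthermophily: 5 known cells
        assert int(ct.hyperthermophile.to_numpy().sum()) == 5
        assert int(ct.hyperthermophile.loc[True, True]) == 1
        # unknown acidophily excluded from the acid table
        assert int(ct.acidophile.to_numpy().sum()) == 4

    def test_all_bearers_thermoacidophilic_gives_empty_list(self):
        recs = [make_record("a", count=1, hyper=True, acid=True)]
        assert pf.phenotype_crosstab(recs).bearers_not_hyperthermophilic == []

    def test_survey_violators(self, survey_records):
        ct = pf.phenotype_crosstab(survey_records)
        assert "Thermoplasma acidophilum" in ct.bearers_not_hyperthermophilic
        for name in ("Pyrolobus fumarii", "Methanocaldococcus jannaschii"):
            assert name in ct.thermoacidophiles_without_homologue
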