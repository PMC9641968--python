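import pytest

import ancsite as ac
from ancsite.combination_space import Combination
from ancsite.site_panel import VariableSiteSet


def _combo(residues, rank=1, joint=0.5):
    return Combination(
        residues=tuple(residues),
        joint=joint,
        ratio_to_top=1.0,
        rank=rank,
        per_site=tuple((i + 1, r, joint) for i, r in enumerate(residues)),
    )


class TestExtractProfiles:
    def test_toy_direct_indexing(self):
        aln = ac.Alignment(ids=["s1", "s2", "s3"], rows=["ARNDC", "AYNDC", "ARWDC"])
        profile = ac.extract_profiles(aln, (2, 4), ["s1", "s2", "s3"])
        assert profile.tuples == {
            "s1": ("R", "D"),
            "s2": ("Y", "D"),
            "s3": ("R", "D"),
        }
        assert profile.aggregate[("R", "D")] == 2

    def test_gap_sequence_excluded_and_reported(self):
        aln = ac.Alignment(ids=["ok", "gap"], rows=["ARND", "A-ND"])
        profile = ac.extract_profiles(aln, (2,), ["ok", "gap"])
        assert profile.n_scorable == 1
        assert profile.excluded == [("gap", "gap/unknown at column(s) [2]")]

    def test_counts_conserve_scorable_total(self):
        aln, clades = ac.make_extant_fixture(seed=5)
        profile = ac.extract_profiles(
            aln, (348, 495, 496, 576, 603), aln.ids, clade_map=clades
        )
        assert sum(profile.aggregate.values()) == profile.n_scorable == len(aln.ids)

    def test_empty_ingroup_errors(self):
        aln = ac.Alignment(ids=["a"], rows=["AR"])
        with pytest.raises(ValueError, match="empty ingroup"):
            ac.extract_profiles(aln, (1,), [])


class TestClassify:
    def _profile(self, tuples, clades=None):
        aln = ac.Alignment(
            ids=[f"s{i}" for i in range(len(tuples))],
            rows=["".join(t) for t in tuples],
        )
        cols = tuple(range(1, len(tuples[0]) + 1))
        cmap = {f"s{i}": c for i, c in enumerate(clades)} if clades else None
        return ac.extract_profiles(aln, cols, aln.ids, clade_map=cmap)

    def test_rare_between_one_and_two_occurrences(self):
        profile = self._profile([tuple("AATGG"), tuple("AATGG"), tuple("LMNGG")])
        records, _ = ac.classify([_combo("AATGG")], profile)
        assert records[0].residue_status == "rare"
        assert records[0].residue_count == 2

    def test_type_common_residue_absent(self):
        # ten sequences share the type tuple but never the exact residues
        profile = self._profile([("G", "L")] * 10)
        records, _ = ac.classify([_combo(("A", "M"))], profile)
        assert records[0].residue_status == "absent"
        assert records[0].type_status == "common"
        assert records[0].type_count == 10

    def test_empty_profile_all_absent(self):
        profile = self._profile([("W", "W")])
        profile.tuples.clear()
        profile.aggregate.clear()
        profile.aggregate_type.clear()
        records, summary = ac.classify([_combo(("A", "M")), _combo(("A", "K"), rank=2)], profile)
        assert all(r.residue_status == "absent" and r.type_status == "absent" for r in records)
        assert summary["residue_present_fraction"] == 0.0
        assert summary["type_absent_fraction"] == 1.0

    def test_exact_match_implies_type_match(self):
        profile = self._profile([tuple("AATGG")] * 4 + [tuple("LMNGG")])
        records, _ = ac.classify(
            [_combo("AATGG"), _combo("LMNGG", rank=2), _combo("QATGG", rank=3)], profile
        )
        for r in records:
            if r.residue_status == "common":
                assert r.type_status != "absent"

    def test_summary_fraction_denominators(self):
        profile = self._profile(
            [tuple("AATGG"), tuple("GGSAA"), tuple("GGSAA"), tuple("KKTGG")]
        )
        combos = [
            _combo("AATGG"),          # residue rare; type common (AATGG + 2x GGSAA)
            _combo("AGTAG", rank=2),  # residue absent; same type tuple, common
            _combo("WWWWW", rank=3),  # absent at both levels
        ]
        records, summary = ac.classify(combos, profile)
        assert summary["n_combinations"] == 3
        present = summary["type_present"]
        assert summary["type_rare_among_present_fraction"] == pytest.approx(
            summary["type_rare_among_present"] / present
        )
        assert summary["type_absent_fraction"] == pytest.approx(
            summary["type_absent"] / 3
        )

    def test_clades_of_type_matches_reported(self):
        profile = self._profile(
            [tuple("AATGG"), tuple("GGSAA")], clades=["Divergent", "NifI"]
        )
        records, _ = ac.classify([_combo("AATGG")], profile)
        # both extant tuples recode to the same tiny/small-hydroxyl pattern
        assert records[0].matching_clades == ("Divergent", "NifI")


class TestCoOccurrence:
    def test_absent_pair_counts_zero(self):
        aln = ac.Alignment(ids=["s1", "s2"], rows=["AM", "LA"])
        profile = ac.extract_profiles(aln, (1, 2), ["s1", "s2"])
        combos = [_combo(("A", "A"))]
        report = ac.co_occurrence_report(profile, combos)
        assert report[(1, "A", 2, "A")] == 0

    def test_present_pair_counts_one(self):
        aln = ac.Alignment(ids=["s1"], rows=["AA"])
        profile = ac.extract_profiles(aln, (1, 2), ["s1"])
        assert ac.co_occurrence_report(profile)[(1, "A", 2, "A")] == 1

    def test_counts_equal_brute_scan(self):
        aln, _ = ac.make_extant_fixture(seed=2)
        cols = (348, 495, 496, 576, 603)
        profile = ac.extract_profiles(aln, cols, aln.ids)
        report = ac.co_occurrence_report(profile)
        for (ci, ra, cj, rb), count in report.items():
            i, j = cols.index(ci), cols.index(cj)
            expected = sum(
                1 for t in profile.tuples.values() if t[i] == ra and t[j] == rb
            )
            assert count == expected

    def test_single_column_errors(self):
        aln = ac.Alignment(ids=["s1"], rows=["AA"])
        profile = ac.extract_profiles(aln, (1,), ["s1"])
        with pytest.raises(ValueError):
            ac.co_occurrence_report(profile)
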