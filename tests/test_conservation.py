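"""Residue-to-column mapping, gap trimming and column-level conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from innexscan.conservation import (
    residue_to_column,
    restrict_reports,
    sequon_column_conservation,
    trim_columns,
)
from innexscan.io_formats import Alignment
from innexscan.screening import screen_dataset
from innexscan.sequon import Sequon
from innexscan.synthetic import SimConfig, simulate_clade_alignment


def _sequon(pid, pos, loop="EL1", passes=True):
    return Sequon(protein_id=pid, n_position=pos, triplet="NGT",
                  loop_label=loop, occupancy_score=0.7 if passes else 0.3,
                  passes=passes)


class TestResidueToColumn:
    def test_identity_for_ungapped(self):
        assert residue_to_column("MNAT").tolist() == [1, 2, 3, 4]

    def test_gaps_skipped(self):
        assert residue_to_column("M-NT").tolist() == [1, 3, 4]

    def test_all_gap_row_rejected(self):
        with pytest.raises(ValueError, match="all-gap"):
            residue_to_column("----")

    @given(st.lists(st.sampled_from("A-"), min_size=1, max_size=80)
           .filter(lambda s: "A" in s))
    def test_inverse_consistency(self, chars):
        row = "".join(chars)
        cmap = residue_to_column(row)
        ungapped = row.replace("-", "")
        # reading the row back at mapped columns recovers the sequence
        assert "".join(row[c - 1] for c in cmap) == ungapped
        assert np.all(np.diff(cmap) > 0)
        assert cmap[-1] <= len(row)


class TestTrimColumns:
    def test_gap_free_alignment_unchanged(self):
        aln = Alignment(ids=("a", "b"), rows=("MKVTA" * 3, "MKVCA" * 3))
        trimmed, kept = trim_columns(aln)
        assert trimmed == aln
        assert kept == list(range(1, 16))

    def test_gappy_column_removed(self):
        # column 6 is 60% gaps in a 5-row toy; block rule keeps the rest
        rows = [
            "AAAAA-AAAA",
            "AAAAA-AAAA",
            "AAAAA-AAAA",
            "AAAAAAAAAA",
            "AAAAACAAAA",
        ]
        aln = Alignment(ids=tuple("abcde"), rows=tuple(rows))
        trimmed, kept = trim_columns(aln, max_gap_fraction=0.5, min_block=4)
        assert 6 not in kept
        assert trimmed.n_cols == 9

    def test_short_blocks_removed(self):
        # survivors split into a 2-run and a 6-run: only the 6-run stays
        rows = ["AA--AAAAAA", "AA--AAAAAA", "AA--AAAAAA"]
        aln = Alignment(ids=tuple("abc"), rows=tuple(rows))
        trimmed, kept = trim_columns(aln, max_gap_fraction=0.5, min_block=5)
        assert kept == [5, 6, 7, 8, 9, 10]

    def test_idempotence(self):
        rows = ["AA--AAAAAA", "AAC-AAAAAA", "AAAAAAAAAA"]
        aln = Alignment(ids=tuple("abc"), rows=tuple(rows))
        once, kept1 = trim_columns(aln)
        twice, kept2 = trim_columns(once)
        assert twice == once
        assert kept2 == list(range(1, once.n_cols + 1))

    def test_everything_trimmed_is_an_error(self):
        aln = Alignment(ids=("a", "b"), rows=("A---", "-AAA"))
        with pytest.raises(ValueError, match="every alignment column"):
            trim_columns(aln, max_gap_fraction=0.4, min_block=5)


class TestSequonColumnConservation:
    def _toy(self):
        aln = Alignment(ids=("a", "b", "c"),
                        rows=("MNGT-A", "M-NGTA", "MNGTAA"))
        groups = {"a": "g1", "b": "g1", "c": "g1"}
        return aln, groups

    def test_same_column_required(self):
        aln, groups = self._toy()
        # Asn of a at residue 2 -> column 2; b at residue 2 -> column 3
        sequons = {"a": [_sequon("a", 2)], "b": [_sequon("b", 2)],
                   "c": [_sequon("c", 2)]}
        (rep,) = sequon_column_conservation(aln, sequons, groups)
        assert rep.column_counts == {2: 2, 3: 1}
        assert not rep.group_conserved

    def test_tolerance_mode_accepts_adjacent_column(self):
        aln, groups = self._toy()
        sequons = {"a": [_sequon("a", 2)], "b": [_sequon("b", 2)],
                   "c": [_sequon("c", 2)]}
        (rep,) = sequon_column_conservation(aln, sequons, groups, tolerance=1)
        assert 2 in rep.conserved_columns

    def test_failing_sequons_do_not_count(self):
        aln, groups = self._toy()
        sequons = {"a": [_sequon("a", 2, passes=False)]}
        (rep,) = sequon_column_conservation(aln, sequons, groups)
        assert rep.column_counts == {}

    def test_single_member_group_trivially_conserved(self):
        aln = Alignment(ids=("a",), rows=("MNGTA",))
        (rep,) = sequon_column_conservation(
            aln, {"a": [_sequon("a", 2)]}, {"a": "solo"}
        )
        assert rep.group_conserved
        assert rep.conserved_columns == [2]

    def test_species_counted_once_across_isoforms(self):
        aln = Alignment(ids=("a1", "a2", "b1"),
                        rows=("MNGTA", "MNGTA", "MNGTA"))
        groups = {"a1": "g", "a2": "g", "b1": "g"}
        species = {"a1": "spA", "a2": "spA", "b1": "spB"}
        sequons = {"a1": [_sequon("a1", 2)], "b1": [_sequon("b1", 2)]}
        (rep,) = sequon_column_conservation(aln, sequons, groups, species=species)
        assert rep.n_members == 2  # species, not proteins
        assert rep.group_conserved

    def test_member_missing_from_alignment_named(self):
        aln = Alignment(ids=("a",), rows=("MNGTA",))
        with pytest.raises(KeyError, match="ghost"):
            sequon_column_conservation(aln, {}, {"a": "g", "ghost": "g"})

    def test_count_conservation_across_groups(self):
        aln = Alignment(ids=("a", "b", "c"),
                        rows=("MNGTA", "MNGTA", "MNGTA"))
        groups = {"a": "g1", "b": "g1", "c": "g2"}
        sequons = {k: [_sequon(k, 2)] for k in "abc"}
        reports = sequon_column_conservation(aln, sequons, groups)
        total_at_2 = sum(r.column_counts.get(2, 0) for r in reports)
        assert total_at_2 == 3

    def test_restriction_is_a_subset(self):
        aln, groups = self._toy()
        sequons = {"a": [_sequon("a", 2)], "b": [_sequon("b", 2)]}
        reports = sequon_column_conservation(aln, sequons, groups)
        restricted = restrict_reports(reports, kept_columns=[2])
        assert restricted[0].column_counts == {2: 1}


class TestSimulatedCladeRoundTrip:
    def test_preserved_sequon_is_conserved(self):
        cfg = SimConfig(seed=9)
        aln, recs, truths = simulate_clade_alignment(cfg, 8)
        verdicts = screen_dataset(recs, None)
        (rep,) = sequon_column_conservation(
            aln, {v.protein_id: v.sequons for v in verdicts},
            {r.id: r.taxon_group for r in recs},
            species={r.id: r.species for r in recs},
        )
        truth_col = truths[0].sequons[0][0]  # ungapped alignment: column == position
        assert rep.group_conserved
        assert truth_col in rep.conserved_columns

    def test_single_knockout_breaks_conservation(self):
        cfg = SimConfig(seed=9)
        preserve = [True] * 8
        preserve[2] = False
        aln, recs, truths = simulate_clade_alignment(cfg, 8, preserve)
        verdicts = screen_dataset(recs, None)
        (rep,) = sequon_column_conservation(
            aln, {v.protein_id: v.sequons for v in verdicts},
            {r.id: r.taxon_group for r in recs},
            species={r.id: r.species for r in recs},
        )
        n_pos = truths[0].sequons[0][0] if truths[0].sequons else truths[1].sequons[0][0]
        assert rep.column_counts.get(n_pos, 0) == 7
        assert not rep.group_conserved

    def test_ungapped_identity_map_limit(self):
        """On an ungapped alignment, conservation at column c equals
        conservation at residue position c."""
        cfg = SimConfig(seed=9)
        aln, recs, _ = simulate_clade_alignment(cfg, 5)
        verdicts = screen_dataset(recs, None)
        sequons = {v.protein_id: v.sequons for v in verdicts}
        (rep,) = sequon_column_conservation(
            aln, sequons, {r.id: "g" for r in recs},
            species={r.id: r.species for r in recs},
        )
        by_position: dict[int, int] = {}
        for v in verdicts:
            for s in v.sequons:
                if s.passes:
                    by_position[s.n_position] = by_position.get(s.n_position, 0) + 1
        assert rep.column_counts == by_position
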