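"""The generator's own contracts: determinism, truth completeness, planting."""

import numpy as np
import pytest

from innexscan.screening import screen_dataset, screen_record
from innexscan.sequon import find_sequons
from innexscan.synthetic import (
    LOOP_ALPHABET,
    SimConfig,
    TaxonSpec,
    simulate_clade_alignment,
    simulate_dataset,
    simulate_protein,
)
from innexscan.topology import infer_topology


class TestSimulateProtein:
    def test_no_planting_means_no_sequons_at_all(self, rng):
        cfg = SimConfig(seed=0)
        rec, truth = simulate_protein(cfg, rng, "p", "s", "g", p_el_ngs=0.0)
        assert truth.sequons == ()
        # alphabet exclusion: the scanner finds nothing either
        assert find_sequons(rec.sequence) == []

    def test_planting_probability_one_gives_exactly_one(self, rng):
        cfg = SimConfig(seed=0)
        for i in range(20):
            rec, truth = simulate_protein(cfg, rng, f"p{i}", "s", "g", p_el_ngs=1.0)
            assert len(truth.sequons) == 1
            assert len(find_sequons(rec.sequence)) == 1
            (n_pos, loop) = truth.sequons[0]
            s, e = truth.segments[loop]
            assert s <= n_pos <= e  # planted inside the true EL span

    def test_loop_choice_weights(self, rng):
        cfg = SimConfig(seed=0)
        _, t1 = simulate_protein(cfg, rng, "p1", "s", "g", 1.0, el1_weight=1.0)
        _, t2 = simulate_protein(cfg, rng, "p2", "s", "g", 1.0, el1_weight=0.0)
        assert t1.sequons[0][1] == "EL1"
        assert t2.sequons[0][1] == "EL2"

    def test_loop_alphabet_excludes_sequon_letters(self):
        assert not set("NSTP") & set(LOOP_ALPHABET)

    def test_planted_cysteines_counted(self, rng):
        cfg = SimConfig(seed=0, el_cysteines=3)
        rec, truth = simulate_protein(cfg, rng, "p", "s", "g", p_el_ngs=1.0)
        from innexscan.sequon import count_loop_cysteines

        model = infer_topology(rec.sequence)
        el1, el2 = count_loop_cysteines(rec.sequence, model)
        # called boundaries may be off by <=3 residues, but cysteines are
        # planted interior to the loops at these loop lengths
        assert (el1, el2) == (3, 3)

    def test_same_seed_byte_identical(self):
        cfg = SimConfig(seed=0)
        r1, _ = simulate_protein(cfg, np.random.default_rng(5), "p", "s", "g", 1.0)
        r2, _ = simulate_protein(cfg, np.random.default_rng(5), "p", "s", "g", 1.0)
        assert r1.sequence == r2.sequence

    def test_too_short_loop_rejected(self, rng):
        ranges = dict(SimConfig().segment_ranges)
        ranges["EL1"] = (5, 8)
        with pytest.raises(ValueError, match="EL1"):
            SimConfig(seed=0, segment_ranges=ranges).validate()


class TestSimulateDataset:
    def test_counting_without_planted_rejects(self):
        cfg = SimConfig(
            seed=1,
            taxa=(
                TaxonSpec("t1", n_species=3, isoforms_min=1, isoforms_max=1,
                          p_el_ngs=0.5),
                TaxonSpec("t2", n_species=3, isoforms_min=1, isoforms_max=1,
                          p_el_ngs=0.5),
            ),
            decoy_fraction=0.0, fragment_fraction=0.0, duplicate_fraction=0.0,
        )
        ds = simulate_dataset(cfg)
        assert len(ds.records) == 6
        assert all(t.class_label == "INNEXIN" for t in ds.truth)

    def test_duplicate_bookkeeping(self):
        cfg = SimConfig(
            seed=2,
            taxa=(TaxonSpec("t", n_species=10, isoforms_min=10, isoforms_max=10,
                            p_el_ngs=0.5),),
            decoy_fraction=0.0, fragment_fraction=0.0, duplicate_fraction=0.1,
        )
        ds = simulate_dataset(cfg)
        dups = [t for t in ds.truth if t.class_label == "DUPLICATE"]
        assert len(ds.records) == 100 + len(dups)
        by_id = {r.id: r for r in ds.records}
        for d in dups:
            assert d.source_id and by_id[d.id].sequence == by_id[d.source_id].sequence
            assert by_id[d.id].species == by_id[d.source_id].species
            assert d.source_id < d.id  # source id sorts first, so it is kept

    def test_lancelet_like_taxon_one_sequon_each(self):
        """One isoform per species, planting probability 1: every protein
        carries exactly one extracellular sequon."""
        cfg = SimConfig(
            seed=3,
            taxa=(TaxonSpec("lancelets", n_species=8, isoforms_min=1,
                            isoforms_max=1, p_el_ngs=1.0),),
            decoy_fraction=0.0, fragment_fraction=0.0, duplicate_fraction=0.0,
        )
        ds = simulate_dataset(cfg)
        assert all(len(t.sequons) == 1 for t in ds.truth)

    def test_cross_file_consistency(self, messy_dataset):
        _cfg, ds = messy_dataset
        assert {t.id for t in ds.truth} == {r.id for r in ds.records}
        assert set(ds.taxonomy.ids) == {r.id for r in ds.records}

    def test_dataset_determinism(self, small_config):
        d1 = simulate_dataset(small_config)
        d2 = simulate_dataset(small_config)
        assert d1.records == d2.records
        assert d1.truth == d2.truth

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="decoy_fraction"):
            SimConfig(seed=0, decoy_fraction=1.5).validate()

    def test_truth_completeness_on_realistic_mode(self):
        """With full loop alphabets, the recomputed truth still matches the
        scanner restricted to extracellular loops."""
        cfg = SimConfig(
            seed=4, realistic=True,
            taxa=(TaxonSpec("t", n_species=5, isoforms_min=2, isoforms_max=2,
                            p_el_ngs=0.5),),
            decoy_fraction=0.0, fragment_fraction=0.0, duplicate_fraction=0.0,
        )
        ds = simulate_dataset(cfg)
        for rec, truth in zip(ds.records, ds.truth):
            found = set()
            for n_pos, _trip in find_sequons(rec.sequence):
                for el in ("EL1", "EL2"):
                    s, e = truth.segments[el]
                    if s <= n_pos <= e:
                        found.add((n_pos, el))
            assert found == set(truth.sequons)


class TestSimulateCladeAlignment:
    def test_zero_rate_copies_ancestor(self):
        cfg = SimConfig(seed=5, substitution_rate=0.0)
        aln, recs, _ = simulate_clade_alignment(cfg, 4)
        assert len(set(aln.rows)) == 1

    def test_rate_bounds_enforced(self):
        with pytest.raises(ValueError, match="substitution_rate"):
            SimConfig(seed=5, substitution_rate=1.0).validate()

    def test_members_survive_the_screen(self):
        """Substitutions stay within segment alphabets, so every descendant
        still presents the four-TM architecture."""
        cfg = SimConfig(seed=6, substitution_rate=0.15)
        aln, recs, truths = simulate_clade_alignment(cfg, 6)
        verdicts = screen_dataset(recs, None)
        assert all(v.status == "ACCEPTED" for v in verdicts)

    def test_knockout_removes_the_sequon(self):
        cfg = SimConfig(seed=7)
        preserve = [True, False, True]
        aln, recs, truths = simulate_clade_alignment(cfg, 3, preserve)
        assert truths[1].sequons == ()
        v = screen_record(recs[1])
        assert not v.has_el_ngs

    def test_observed_divergence_tracks_rate(self):
        cfg = SimConfig(seed=8, substitution_rate=0.1)
        aln, recs, truths = simulate_clade_alignment(cfg, 2)
        a, b = aln.rows
        diff = sum(x != y for x, y in zip(a, b)) / len(a)
        # two independent draws at rate 0.1; expect ~0.19 differing sites
        assert 0.10 < diff < 0.30
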