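from collections import defaultdict

import pytest

import cleavemap as cm


def count_occurrences(seq, motif):
    n, i = 0, seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


class TestMakeSubstrate:
    def test_plants_exactly_requested_sites(self):
        sub = cm.make_substrate(1500, 3, "UACAUA", seed=7)
        assert count_occurrences(sub.sequence, "UACAUA") == 3
        assert len(sub.planted_sites) == 3
        for p in sub.planted_sites:
            assert sub.sequence[p - 1 : p + 5] == "UACAUA"

    def test_zero_sites_means_zero_occurrences(self):
        sub = cm.make_substrate(400, 0, "UACAUA", seed=1)
        assert count_occurrences(sub.sequence, "UACAUA") == 0

    def test_same_seed_is_deterministic(self):
        a = cm.make_substrate(800, 2, seed=5)
        b = cm.make_substrate(800, 2, seed=5)
        assert a == b

    def test_impossible_packing_errors(self):
        with pytest.raises(ValueError):
            cm.make_substrate(30, 5, "UACAUA", seed=0)


class TestDigest:
    def test_forced_split_at_planted_site(self):
        sub = cm.make_substrate(600, 1, seed=2)
        (s,) = sub.planted_sites
        model = cm.DigestionModel(
            site_cleavage_prob=1.0, background_break_rate=0.0, n_molecules=1
        )
        frags = cm.digest(sub, model, seed=0)
        assert [(f.start, f.end) for f in frags] == [(1, s), (s + 1, 600)]

    def test_no_cleavage_gives_full_length_fragment(self):
        sub = cm.make_substrate(500, 2, seed=2)
        model = cm.DigestionModel(
            site_cleavage_prob=0.0, background_break_rate=0.0, n_molecules=3
        )
        frags = cm.digest(sub, model, seed=0)
        assert [(f.start, f.end) for f in frags] == [(1, 500)] * 3

    def test_seeded_fragment_multiset_reproducible(self):
        sub = cm.make_substrate(900, 3, seed=4)
        model = cm.DigestionModel(n_molecules=50, background_break_rate=1e-3)
        a = cm.digest(sub, model, seed=9)
        b = cm.digest(sub, model, seed=9)
        assert a == b

    def test_fragments_partition_each_molecule(self):
        sub = cm.make_substrate(700, 2, seed=6)
        model = cm.DigestionModel(n_molecules=40, background_break_rate=2e-3)
        frags = cm.digest(sub, model, seed=1)
        # fragments are emitted molecule by molecule, starting at 1
        total, per_molecule = 0, []
        for f in frags:
            if f.start == 1 and total:
                per_molecule.append(total)
                total = 0
            total += len(f)
        per_molecule.append(total)
        assert per_molecule == [700] * model.n_molecules

    def test_boundaries_fall_inside_planted_motifs(self):
        sub = cm.make_substrate(1000, 3, seed=8)
        model = cm.DigestionModel(
            site_cleavage_prob=1.0, background_break_rate=0.0, n_molecules=10
        )
        expected_starts = {p + model.cut_offset for p in sub.planted_sites}
        for f in cm.digest(sub, model, seed=0):
            if f.start != 1:
                assert f.start in expected_starts


class TestLibraryPrep:
    def test_size_select_threshold(self):
        frags = [
            cm.Fragment("s", 1, 150),
            cm.Fragment("s", 151, 350),
            cm.Fragment("s", 351, 1883),
        ]
        kept = cm.size_select(frags, 200)
        assert [len(f) for f in kept] == [200, 1533]
        assert cm.size_select(frags, 0) == frags

    def test_all_short_gives_empty_list(self):
        assert cm.size_select([cm.Fragment("s", 1, 50)], 200) == []

    @pytest.mark.parametrize("prob,expect", [(1.0, True), (0.0, False)])
    def test_ligation_extremes(self, prob, expect):
        frags = [cm.Fragment("s", 1, 300)] * 20
        out = cm.ligate_barcode(frags, ligation_prob=prob, seed=0)
        assert all(f.barcoded is expect for f in out)

    def test_bad_barcode_rejected(self):
        with pytest.raises(ValueError):
            cm.ligate_barcode([cm.Fragment("s", 1, 10)], barcode="ACGTX")

    def test_barcoded_read_starts_with_barcode_then_substrate(self):
        sub = cm.make_substrate(600, 1, seed=2)
        (s,) = sub.planted_sites
        model = cm.DigestionModel(
            site_cleavage_prob=1.0, background_break_rate=0.0,
            n_molecules=1, read_error_rate=0.0,
        )
        frags = cm.ligate_barcode(cm.digest(sub, model, seed=0), ligation_prob=1.0, seed=0)
        reads = cm.fragments_to_reads([sub], frags, model, seed=0)
        downstream = next(r for r in reads if f"|{s + 1}|" in r.id)
        expect = (cm.DEFAULT_BARCODE + sub.sequence[s:])[: model.read_length]
        assert downstream.sequence == expect

    def test_reads_shorter_than_barcode_cannot_be_assigned(self):
        sub = cm.make_substrate(400, 1, seed=3)
        model = cm.DigestionModel(read_length=30, n_molecules=2, read_error_rate=0.0)
        frags = cm.ligate_barcode(cm.digest(sub, model, seed=0), ligation_prob=1.0, seed=0)
        reads = cm.fragments_to_reads([sub], frags, model, seed=0)
        assert all(len(r) == 30 for r in reads)
        assert cm.extract_barcoded(reads, cm.DEFAULT_BARCODE) == []

    def test_seeded_reads_reproducible(self):
        sub = cm.make_substrate(500, 2, seed=1)
        model = cm.DigestionModel(n_molecules=20)
        frags = cm.ligate_barcode(cm.digest(sub, model, seed=1), seed=1)
        a = cm.fragments_to_reads([sub], frags, model, seed=5, n_reads=200)
        b = cm.fragments_to_reads([sub], frags, model, seed=5, n_reads=200)
        assert a == b
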