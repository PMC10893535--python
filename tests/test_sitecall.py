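import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cleavemap as cm
from cleavemap.sitecall import CoverageProfile, RCIProfile

BC = cm.DEFAULT_BARCODE


def rci_oracle(depth):
    """Brute-force RCI: divide, with the zero-denominator rule."""
    out = []
    prev = 0
    for d in depth:
        out.append(d / prev if prev > 0 else float(d))
        prev = d
    return out


class TestExtractBarcoded:
    def test_exact_prefix_stripped(self):
        r = cm.ReadRecord("r", BC + "ACGUACGU")
        (kept,) = cm.extract_barcoded([r], BC, 0)
        assert kept.sequence == "ACGUACGU"

    def test_one_substitution_respects_max_mm(self):
        mutated = ("A" if BC[0] != "A" else "C") + BC[1:]
        r = cm.ReadRecord("r", mutated + "ACGUACGU")
        assert cm.extract_barcoded([r], BC, 0) == []
        (kept,) = cm.extract_barcoded([r], BC, 1)
        assert kept.sequence == "ACGUACGU"

    def test_short_read_discarded(self):
        assert cm.extract_barcoded([cm.ReadRecord("r", BC[:20])], BC) == []

    def test_full_retention_with_perfect_ligation(self, clean_run):
        substrates, reads, _ = clean_run
        kept = cm.extract_barcoded(reads, BC, 0)
        eligible = [r for r in reads if len(r) > len(BC)]
        assert len(kept) == len(eligible)


class TestMapReads:
    def make_sub(self, seed=0, length=400):
        return cm.make_substrate(length, 0, seed=seed)

    def test_error_free_read_maps_at_origin(self):
        sub = self.make_sub()
        read = cm.ReadRecord("r", sub.sequence[100:180])
        (m,) = cm.map_reads([read], [sub])
        assert (m.start, m.mismatches, m.matched_len) == (101, 0, 80)

    def test_t_and_u_equivalent(self):
        sub = self.make_sub()
        read = cm.ReadRecord("r", sub.sequence[100:180].replace("U", "T"))
        (m,) = cm.map_reads([read], [sub])
        assert (m.start, m.mismatches) == (101, 0)

    def test_ambiguous_read_discarded(self):
        shared = cm.make_substrate(120, 0, seed=4).sequence[:60]
        a = cm.Substrate(id="a", sequence=shared + self.make_sub(1, 200).sequence)
        b = cm.Substrate(id="b", sequence=shared + self.make_sub(2, 200).sequence)
        read = cm.ReadRecord("r", shared[:50])
        assert cm.map_reads([read], [a, b]) == []

    def test_too_many_mismatches_discarded(self):
        sub = self.make_sub()
        frag = list(sub.sequence[100:180])
        for i in (40, 50, 60):  # keep the 20-base seed intact
            frag[i] = "A" if frag[i] != "A" else "C"
        read = cm.ReadRecord("r", "".join(frag))
        assert cm.map_reads([read], [sub], max_mismatches=2) == []
        (m,) = cm.map_reads([read], [sub], max_mismatches=3)
        assert m.mismatches == 3


class TestCoverage:
    def test_overlapping_reads_stack(self, toy_substrate):
        maps = [
            cm.Mapping("r1", "toy", 1, 10, 0),
            cm.Mapping("r2", "toy", 4, 10, 0),
        ]
        prof = cm.coverage(maps, toy_substrate)
        assert prof.depth[4] == 2  # position 5
        assert prof.depth[0] == 1

    def test_no_reads_gives_zero_profile(self, toy_substrate):
        prof = cm.coverage([], toy_substrate)
        assert not prof.depth.any()

    def test_depth_sum_equals_mapped_bases(self, toy_substrate):
        maps = [cm.Mapping(f"r{i}", "toy", 1 + i, 8, 0) for i in range(5)]
        prof = cm.coverage(maps, toy_substrate)
        assert prof.depth.sum() == sum(m.matched_len for m in maps)


class TestRCI:
    def test_direct_division(self):
        prof = CoverageProfile("s", np.array([10, 50]))
        assert cm.rci(prof).rci[1] == 5.0

    def test_zero_denominator_rule(self):
        prof = CoverageProfile("s", np.array([3, 0, 7, 0]))
        out = cm.rci(prof).rci
        assert out[0] == 3.0  # depth[0] taken as 0
        assert out[1] == 0.0
        assert out[2] == 7.0  # previous position has zero coverage
        assert out[3] == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1, max_size=60))
    def test_matches_bruteforce_oracle(self, depth):
        out = cm.rci(CoverageProfile("s", np.array(depth)))
        assert np.allclose(out.rci, rci_oracle(depth))


class TestTopSites:
    def build(self, rci_values, depths, sid="s"):
        return (
            RCIProfile(sid, np.asarray(rci_values, dtype=float)),
            CoverageProfile(sid, np.asarray(depths, dtype=int)),
        )

    def test_distinct_rcis_ranked_descending(self):
        rci_vals = np.zeros(40)
        depths = np.full(40, 50)
        for pos, v in [(10, 9.0), (20, 7.0), (30, 5.0)]:
            rci_vals[pos - 1] = v
        r, c = self.build(rci_vals, depths)
        sites = cm.top_sites([r], [c], K=3)
        assert [(s.rank, s.position) for s in sites] == [(1, 10), (2, 20), (3, 30)]

    def test_tie_break_matches_bruteforce_sort(self):
        rng = np.random.default_rng(0)
        rci_vals = rng.choice([0.5, 2.0, 3.0], size=30)
        depths = rng.choice([5, 9, 13], size=30)
        profiles = [self.build(rci_vals, depths, "s1"), self.build(rci_vals, depths, "s2")]
        sites = cm.top_sites(
            [p[0] for p in profiles], [p[1] for p in profiles], K=10, window_w=5
        )
        candidates = [
            (-rci_vals[n - 1], -depths[n - 1], sid, n)
            for sid in ("s1", "s2")
            for n in range(3, 29)  # window of 5 fits
            if depths[n - 1] >= 5
        ]
        expected = [(sid, n) for _, _, sid, n in sorted(candidates)[:10]]
        assert [(s.substrate_id, s.position) for s in sites] == expected

    def test_k_larger_than_available_returns_all(self):
        r, c = self.build([1, 1, 9, 1, 1], [10, 10, 10, 10, 10])
        sites = cm.top_sites([r], [c], K=10, window_w=3)
        assert len(sites) == 3  # positions 2-4 fit a 3-wide window

    def test_empty_profiles_error(self):
        with pytest.raises(ValueError):
            cm.top_sites([], [], K=5)

    def test_min_depth_floor_excludes_shallow_positions(self):
        r, c = self.build([0, 0, 50.0, 0, 0], [1, 1, 2, 1, 1])
        with_floor = cm.top_sites([r], [c], K=1, window_w=3, min_depth=5)
        assert with_floor == []


class TestPerfectRecovery:
    def test_all_top_sites_are_planted_cut_positions(self, clean_run):
        substrates, _, result = clean_run
        truth = {
            (s.id, p + 1) for s in substrates for p in s.planted_sites
        }  # cut_offset = 1
        assert {(s.substrate_id, s.position) for s in result.sites} <= truth
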