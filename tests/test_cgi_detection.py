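"""Island statistics, the sliding-window scanner vs its brute-force
reference, the acceptance filter, consensus combination, and CpG classes."""

import numpy as np
import pytest

from _oracles import naive_best_window, naive_gc, naive_oe, naive_scan_islands
from cisvelem.cgi_detection import (
    PRESETS,
    AlgorithmPreset,
    CpGIsland,
    apply_island_criteria,
    classify_promoter_cpg_class,
    consensus_call,
    cpg_oe_ratio,
    gc_fraction,
    scan_islands,
)
from cisvelem.sequence_io import PromoterRecord
from cisvelem.synthetic_data import generate_background, plant_island


@pytest.mark.parametrize(
    "seq,expected",
    [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("ACGTN", 0.5)],
)
def test_gc_fraction_values(seq, expected):
    assert gc_fraction(seq) == expected


@pytest.mark.parametrize(
    "seq,expected",
    [("CGCGCG", 2.0), ("ATATAT", 0.0), ("ACGTACGT", 4.0), ("GGGG", 0.0)],
)
def test_cpg_oe_values(seq, expected):
    assert cpg_oe_ratio(seq) == expected


def test_stat_functions_reject_empty():
    with pytest.raises(ValueError):
        gc_fraction("")
    with pytest.raises(ValueError):
        cpg_oe_ratio("")


def test_oe_zero_without_c_or_g():
    rng = np.random.default_rng(3)
    for _ in range(20):
        seq = "".join(rng.choice(list("AGT"), size=50))  # no C
        assert cpg_oe_ratio(seq) == 0.0


def _mixed_test_sequences(n, seed):
    """Backgrounds spanning CpG-depleted, near-threshold and island-bearing
    regimes, to exercise merge and trim paths."""
    rng = np.random.default_rng(seed)
    seqs = []
    for i in range(n):
        kind = i % 4
        s = int(rng.integers(0, 2**31 - 1))
        if kind == 0:
            seqs.append(generate_background(3001, 0.41, 0.25, s))
        elif kind == 1:
            seqs.append(generate_background(3001, 0.50, 0.60, s))
        elif kind == 2:
            seqs.append(generate_background(3001, 0.55, 0.80, s))
        else:
            bg = generate_background(3001, 0.41, 0.25, s)
            length = int(rng.integers(350, 801))
            start = int(rng.integers(0, 3001 - length))
            bg, _ = plant_island(bg, start, length, 0.60, 1.0, seed=s + 1)
            seqs.append(bg)
    return seqs


@pytest.mark.parametrize("preset_name", list(PRESETS))
def test_scanner_matches_bruteforce_reference(preset_name):
    preset = PRESETS[preset_name]
    for seq in _mixed_test_sequences(24, seed=100):
        got = [(i.start, i.end) for i in scan_islands(seq, preset)]
        want = naive_scan_islands(
            seq, preset.window, preset.min_length, preset.min_gc, preset.min_oe
        )
        assert got == want


def test_cg_repeat_single_island():
    seq = "CG" * 300
    (isl,) = scan_islands(seq, PRESETS["GGF"])
    assert (isl.start, isl.end) == (0, 600)
    assert isl.oe == 2.0 and isl.gc == 1.0


def test_at_repeat_empty():
    seq = "AT" * 1500 + "A"
    for preset in PRESETS.values():
        assert scan_islands(seq, preset) == []


def test_short_sequence_warns_not_fatal():
    with pytest.warns(UserWarning):
        assert scan_islands("ACGT" * 10, PRESETS["GGF"]) == []


def test_planted_island_recovered_with_overlap():
    # a merged island may legitimately extend up to a window width beyond
    # the planted span on each side, so coverage of the planted interval
    # is the recovery criterion (the scan itself is oracle-checked above)
    bg = generate_background(3001, 0.41, 0.25, seed=7)
    seq, (a, b) = plant_island(bg, 1000, 400, 0.60, 1.0, seed=7)
    islands = apply_island_criteria(scan_islands(seq, PRESETS["GGF"]), seq)
    assert islands, "planted island not detected"
    best = max(islands, key=lambda i: min(i.end, b) - max(i.start, a))
    coverage = max(0, min(best.end, b) - max(best.start, a)) / (b - a)
    assert coverage >= 0.8
    assert best.start >= a - PRESETS["GGF"].window
    assert best.end <= b + PRESETS["GGF"].window


def test_reported_islands_satisfy_preset_thresholds():
    for seq in _mixed_test_sequences(8, seed=200):
        for preset in PRESETS.values():
            for isl in scan_islands(seq, preset):
                sub = seq[isl.start : isl.end]
                assert gc_fraction(sub) >= preset.min_gc
                assert cpg_oe_ratio(sub) >= preset.min_oe
                assert isl.length >= preset.min_length


def test_threshold_monotonicity_total_length():
    base = PRESETS["GGF"]
    for seq in _mixed_test_sequences(8, seed=300):
        total = sum(i.length for i in scan_islands(seq, base))
        for stricter in (
            AlgorithmPreset("X", base.window, base.min_length, base.min_gc + 0.05, base.min_oe),
            AlgorithmPreset("Y", base.window, base.min_length, base.min_gc, base.min_oe + 0.1),
        ):
            assert sum(i.length for i in scan_islands(seq, stricter)) <= total


class TestIslandCriteria:
    def _island_for(self, seq):
        return CpGIsland("g", 0, len(seq), gc_fraction(seq), cpg_oe_ratio(seq), "GGF")

    def test_length_exactly_300_removed(self):
        seq = "CG" * 83 + "AT" * 67  # 300 nt, gc 0.553, oe >= 0.6
        assert len(seq) == 300 and gc_fraction(seq) > 0.5 and cpg_oe_ratio(seq) >= 0.6
        assert apply_island_criteria([self._island_for(seq)], seq) == []

    def test_length_301_kept(self):
        seq = "CG" * 83 + "AT" * 67 + "G"
        assert len(seq) == 301
        assert len(apply_island_criteria([self._island_for(seq)], seq)) == 1

    def test_low_oe_removed(self):
        seq = "GGGGCCCC" * 62 + "GGGG"  # gc 1.0 but few CpGs
        assert len(seq) == 500 and cpg_oe_ratio(seq) < 0.6
        assert apply_island_criteria([self._island_for(seq)], seq) == []

    def test_gc_exactly_half_removed(self):
        # alternating CGAT: gc exactly 0.50 fails the strict criterion
        seq = "CGAT" * 100
        isl = self._island_for(seq)
        assert gc_fraction(seq) == 0.5 and cpg_oe_ratio(seq) >= 0.6
        assert apply_island_criteria([isl], seq) == []


class TestConsensus:
    def _mk(self, start, end, preset):
        return CpGIsland("g", start, end, 0.6, 1.0, preset)

    def _per_preset(self, **kw):
        d = {"GGF": [], "TJ": [], "PM": []}
        d.update(kw)
        return d

    def test_all_three_agree_merges(self):
        pp = self._per_preset(
            GGF=[self._mk(1000, 1400, "GGF")],
            TJ=[self._mk(980, 1380, "TJ")],
            PM=[self._mk(1020, 1420, "PM")],
        )
        has, islands = consensus_call(pp, k=2)
        assert has is True
        assert [(i.start, i.end) for i in islands] == [(980, 1420)]
        assert islands[0].preset == "CONSENSUS"

    def test_single_preset_insufficient(self):
        pp = self._per_preset(GGF=[self._mk(1000, 1400, "GGF")])
        assert consensus_call(pp, k=2) == (False, [])

    def test_two_presets_fail_k3(self):
        pp = self._per_preset(
            GGF=[self._mk(1000, 1400, "GGF")], PM=[self._mk(1000, 1400, "PM")]
        )
        has, islands = consensus_call(pp, k=3)
        assert has is False and islands == []

    def test_k1_is_or_and_k3_is_and(self):
        pp = self._per_preset(GGF=[self._mk(0, 400, "GGF")])
        assert consensus_call(pp, k=1)[0] is True
        assert consensus_call(pp, k=3)[0] is False
        full = self._per_preset(
            GGF=[self._mk(0, 400, "GGF")],
            TJ=[self._mk(0, 400, "TJ")],
            PM=[self._mk(0, 400, "PM")],
        )
        assert consensus_call(full, k=3)[0] is True

    def test_disjoint_islands_do_not_pair(self):
        # both presets have an island, so has_cgi holds, but no overlap
        # pairing reaches support 2
        pp = self._per_preset(
            GGF=[self._mk(0, 400, "GGF")], PM=[self._mk(2000, 2400, "PM")]
        )
        has, islands = consensus_call(pp, k=2)
        assert has is True and islands == []

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            consensus_call(self._per_preset(), k=0)
        with pytest.raises(ValueError):
            consensus_call(self._per_preset(), k=4)


class TestCpGClass:
    def test_hcp_via_planted_island(self):
        bg = generate_background(3001, 0.41, 0.25, seed=21)
        seq, _ = plant_island(bg, 1200, 600, 0.62, 1.0, seed=3)
        rec = PromoterRecord("g", seq)
        assert classify_promoter_cpg_class(rec) == "HCP"
        assert naive_best_window(seq)[2] is True

    def test_at_promoter_is_lcp(self):
        rec = PromoterRecord("g", "AT" * 1500 + "A")
        assert classify_promoter_cpg_class(rec) == "LCP"

    def test_classes_match_bruteforce_sweep(self):
        rng = np.random.default_rng(5)
        for gc, oe in [(0.41, 0.25), (0.50, 0.55), (0.55, 0.85)]:
            seq = generate_background(1200, gc, oe, int(rng.integers(2**31)))
            rec = PromoterRecord("g", seq, rel_start=-800, rel_end=400)
            best_gc, best_oe, hcp = naive_best_window(seq)
            want = "HCP" if hcp else ("LCP" if best_oe < 0.48 else "ICP")
            assert classify_promoter_cpg_class(rec) == want

    def test_short_promoter_warns(self):
        rec = PromoterRecord("g", "ACGT" * 50, rel_start=-100, rel_end=100)
        with pytest.warns(UserWarning):
            classify_promoter_cpg_class(rec)
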