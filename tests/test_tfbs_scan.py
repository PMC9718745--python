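"""PWM loading, log-odds scanning vs exhaustive enumeration, and the
gene-presence / frequency aggregation."""

import numpy as np
import pandas as pd
import pytest

from _oracles import naive_scan_pwm
from cisvelem.sequence_io import PromoterRecord
from cisvelem.synthetic_data import generate_background, plant_sites
from cisvelem.tfbs_scan import (
    DEFAULT_PANEL_TFS,
    PartnerPanel,
    PositionWeightMatrix,
    default_panel,
    default_pwm_library,
    load_pwms,
    relative_score,
    revcomp,
    scan_pwm,
    tf_gene_frequency,
    tf_presence_matrix,
)


def _count_pwm(word, counts_on=97, counts_off=1, pseudocount=0.0):
    """PWM from a consensus word with the given count split."""
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.full((len(word), 4), float(counts_off))
    for j, ch in enumerate(word):
        counts[j, idx[ch]] = counts_on
    tot = counts.sum(axis=1)
    probs = (counts + pseudocount) / (tot + 4 * pseudocount)[:, None]
    return PositionWeightMatrix("TEST", probs, pseudocount=pseudocount)


def _det_pwm(word):
    """Deterministic (0/1 probability) PWM, pseudocount 0."""
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.zeros((len(word), 4))
    for j, ch in enumerate(word):
        probs[j, idx[ch]] = 1.0
    return PositionWeightMatrix("DET", probs)


class TestLoadPwms:
    def test_pseudocount_arithmetic(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(
            ">M1 T1\n"
            "A [ 10 0 0 0 ]\nC [ 0 10 0 0 ]\nG [ 0 0 10 0 ]\nT [ 0 0 0 10 ]\n"
        )
        (pwm,) = load_pwms(path, pseudocount=1.0)
        assert pwm.probs[0, 0] == pytest.approx((10 + 1) / (10 + 4))
        assert pwm.consensus == "ACGT"
        (pwm0,) = load_pwms(path, pseudocount=0.0)
        assert pwm0.probs[0].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_default_library_covers_panel(self):
        pwms = default_pwm_library()
        panel = default_panel()
        assert len(pwms) == 17
        assert list(panel.tf_names) == list(DEFAULT_PANEL_TFS)

    def test_malformed_record_fatal(self, tmp_path):
        path = tmp_path / "bad.pfm"
        path.write_text(">M1 T1\nA [ 1 1 ]\nC [ 1 1 ]\nG [ 1 1 ]\n")
        with pytest.raises(Exception):
            load_pwms(path)


class TestScan:
    def test_deterministic_acgt_scores_8_bits(self):
        pwm = _det_pwm("ACGT")
        hits = scan_pwm("ACGT", pwm, min_rel_score=1.0)
        plus = [h for h in hits if h.strand == "+"]
        assert plus and plus[0].start == 0
        assert plus[0].score_bits == pytest.approx(4 * np.log2(4))
        assert plus[0].rel_score == 1.0

    def test_reverse_complement_hit(self):
        pwm = _det_pwm("AAAA")
        hits = scan_pwm("TTTT", pwm, min_rel_score=1.0)
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_consensus_and_anticonsensus_rel_scores(self):
        pwm = _count_pwm("ACGTAC", pseudocount=0.01)
        assert relative_score(pwm, "ACGTAC") == pytest.approx(1.0)
        anti = "".join("ACGT"[int(np.argmin(pwm.log_odds[j]))] for j in range(6))
        assert relative_score(pwm, anti) == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            w = int(rng.integers(5, 13))
            word = "".join(rng.choice(list("ACGT"), size=w))
            pwm = _count_pwm(word, counts_on=int(rng.integers(50, 100)), pseudocount=0.01)
            seq = generate_background(800, 0.45, 0.8, int(rng.integers(2**31)))
            got = scan_pwm(seq, pwm, 0.8)
            want = naive_scan_pwm(
                seq, pwm.log_odds.tolist(), pwm.min_score, pwm.max_score, 0.8
            )
            assert [(h.start, h.strand) for h in got] == [(s, st) for s, st, *_ in want]
            for h, (_, _, score, rel) in zip(got, want):
                assert h.score_bits == pytest.approx(score, abs=1e-9)
                assert h.rel_score == pytest.approx(rel, abs=1e-9)

    def test_threshold_monotonicity(self):
        pwm = _count_pwm("GGGGCGGGGC", pseudocount=0.01)
        seq = generate_background(2000, 0.5, 0.8, 99)
        loose = {(h.start, h.strand) for h in scan_pwm(seq, pwm, 0.75)}
        tight = {(h.start, h.strand) for h in scan_pwm(seq, pwm, 0.85)}
        assert tight <= loose

    def test_n_windows_skipped(self):
        pwm = _det_pwm("ACGT")
        assert scan_pwm("ACGNACGT", pwm, 1.0)[0].start == 4

    def test_short_sequence_warns(self):
        pwm = _det_pwm("ACGTACGT")
        with pytest.warns(UserWarning):
            assert scan_pwm("ACG", pwm, 0.8) == []


class TestPresence:
    def _records_with_sp1(self):
        pwms = default_pwm_library()
        sp1 = next(p for p in pwms if p.tf_name == "SP1")
        recs = []
        for i, plant in enumerate([True, True, False]):
            seq = generate_background(3001, 0.41, 0.25, seed=400 + i)
            if plant:
                seq, _ = plant_sites(seq, sp1, [1500])
            recs.append(PromoterRecord(f"G{i + 1}", seq))
        return recs, pwms

    def test_planted_column(self):
        # near-consensus threshold so raw background (unscrubbed here,
        # unlike generate_study_set output) cannot produce chance hits
        recs, pwms = self._records_with_sp1()
        panel = PartnerPanel(["SP1"])
        mat = tf_presence_matrix(recs, pwms, panel, min_rel_score=0.95)
        assert mat["SP1"].tolist() == [True, True, False]

    def test_empty_panel_zero_columns(self):
        recs, pwms = self._records_with_sp1()
        mat = tf_presence_matrix(recs, pwms, PartnerPanel([]))
        assert mat.shape == (3, 0)

    def test_imperfect_sites_fail_maximal_threshold(self):
        pwms = default_pwm_library()
        sp1 = next(p for p in pwms if p.tf_name == "SP1")
        word = sp1.consensus
        degraded = "T" + word[1:-1] + "A"  # two mismatches
        seq = generate_background(3001, 0.41, 0.25, seed=77)
        seq = seq[:1500] + degraded + seq[1500 + len(word):]
        mat = tf_presence_matrix(
            [PromoterRecord("G1", seq)], pwms, PartnerPanel(["SP1"]),
            min_rel_score=1.0,
        )
        assert mat["SP1"].tolist() == [False]

    def test_unresolved_panel_tf_fatal(self):
        recs, pwms = self._records_with_sp1()
        with pytest.raises(ValueError, match="NOSUCHTF"):
            tf_presence_matrix(recs, pwms, PartnerPanel(["NOSUCHTF"]))


def test_frequency_equals_column_popcount():
    rng = np.random.default_rng(8)
    mat = pd.DataFrame(
        rng.random((30, 6)) < 0.4,
        index=[f"G{i}" for i in range(30)],
        columns=list("ABCDEF"),
    )
    freq = tf_gene_frequency(mat)
    for col in mat.columns:
        assert freq[col] == sum(bool(v) for v in mat[col])
    assert tf_gene_frequency(mat.loc[:, []] ).empty
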