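"""Brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: statistics
are recomputed with plain string slicing and Python loops so that the
production scanners can be checked against an independent route.
"""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def naive_gc(seq: str) -> float:
    non_n = len(seq) - seq.count("N")
    if non_n == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / non_n


def naive_oe(seq: str) -> float:
    n_c, n_g = seq.count("C"), seq.count("G")
    if n_c * n_g == 0:
        return 0.0
    return seq.count("CG") * (len(seq) - seq.count("N")) / (n_c * n_g)


def naive_scan_islands(seq, window, min_length, min_gc, min_oe):
    """Enumerate every window, mark qualifying positions, merge the union
    of qualifying windows into regions, trim alternately 3' then 5' until
    the whole span qualifies (strict GC) or falls below min_length.
    Returns [(start, end)]."""
    qualifying = []
    for i in range(len(seq) - window + 1):
        win = seq[i : i + window]
        if win.count("N") > 0.10 * window:
            continue
        if naive_gc(win) >= min_gc and naive_oe(win) >= min_oe:
            qualifying.append(i)
    # union of [i, i+window) intervals, merging overlapping or touching
    regions = []
    for i in qualifying:
        if regions and i <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], i + window)
        else:
            regions.append([i, i + window])
    out = []
    for a, b in regions:
        trim3 = True
        while b - a >= min_length:
            span = seq[a:b]
            if naive_gc(span) > min_gc and naive_oe(span) >= min_oe:
                out.append((a, b))
                break
            if trim3:
                b -= 1
            else:
                a += 1
            trim3 = not trim3
    return out


def naive_scan_pwm(seq, log_odds, min_score_sum, max_score_sum, min_rel):
    """Exhaustive per-position, per-strand PWM scoring.

    ``log_odds`` is a (width, 4) list-of-lists in ACGT order.
    Returns [(start, strand, score, rel)] sorted by (start, strand).
    """
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(log_odds)
    denom = max_score_sum - min_score_sum
    hits = []
    for i in range(len(seq) - w + 1):
        win = seq[i : i + w]
        if "N" in win:
            continue
        for strand, word in (("+", win), ("-", rc(win))):
            score = 0.0
            for j, ch in enumerate(word):
                score += log_odds[j][idx[ch]]
            if not math.isfinite(denom) or denom == 0:
                rel = 1.0 if score == max_score_sum else 0.0
            else:
                rel = (score - min_score_sum) / denom
            if rel >= min_rel:
                hits.append((i, strand, score, rel))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def naive_best_window(seq, w=500):
    """(max GC, max O/E, any-window HCP flag) by direct sweep."""
    best_gc = best_oe = 0.0
    hcp = False
    for i in range(len(seq) - w + 1):
        win = seq[i : i + w]
        g, o = naive_gc(win), naive_oe(win)
        best_gc = max(best_gc, g)
        best_oe = max(best_oe, o)
        if g >= 0.55 and o >= 0.75:
            hcp = True
    return best_gc, best_oe, hcp


def exact_tail_p(a, b, c, d):
    """One-sided hypergeometric tail P(X >= a) for the 2x2 table
    [[a, b], [c, d]] by direct summation of hypergeometric terms."""
    M = a + b + c + d
    K = a + c  # total sequences containing the word
    n = a + b  # positive-set size
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
    return total


def naive_min_peak_dist(peaks, seq_id, pos):
    """All-pairs minimum TSS-to-peak distance; None if no peak on seq_id."""
    best = None
    for p_seq, p_start, p_end in peaks:
        if p_seq != seq_id:
            continue
        d = max(0, p_start - pos, pos - p_end)
        if best is None or d < best:
            best = d
    return best
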