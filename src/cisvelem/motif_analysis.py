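"""Discriminative short-motif elicitation over promoter functional regions.

Instead of an EM-based motif model, enrichment is computed over exact
words (optionally IUPAC-generalized at match time): for each k-mer seen
in at least two positive sequences, a sequence-level 2x2 table is built
against a dinucleotide-preserving shuffled background and scored with a
one-sided hypergeometric tail; a Bonferroni-style E-value multiplies the
p-value by the number of distinct words tested. Both strands are
searched and a word is collapsed with its reverse complement onto the
lexicographically smaller representative. This keeps the statistic
exactly reproducible by direct combinatorial evaluation while matching
the zero-or-one-occurrence-per-sequence semantics of DREME-style tools.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from Bio.Data.IUPACData import ambiguous_dna_values

from .cgi_detection import CpGIsland
from .sequence_io import PromoterRecord, extract_relative_region
from .tfbs_scan import revcomp

__all__ = [
    "FunctionalRegionSet",
    "MotifCandidate",
    "extract_functional_regions",
    "dinucleotide_shuffle",
    "kmer_enrichment",
    "motif_prevalence",
    "write_meme_minimal",
]


@dataclass
class FunctionalRegionSet:
    """The three TSS-relative scan regions of one gene: the full
    regulatory region (RR, -2000..+1000), the concatenated consensus
    CpG-island spans (absent when the gene has none), and the close
    promoter (-400..+100)."""

    gene_id: str
    rr: str
    promoter: str
    cgi: Optional[str] = None


@dataclass
class MotifCandidate:
    """An enriched word with its sequence-level contingency counts.

    ``prevalence`` is the fraction of positive sequences containing the
    word on either strand.
    """

    word: str
    k: int
    n_pos_with: int
    n_pos_without: int
    n_bg_with: int
    n_bg_without: int
    p_value: float
    e_value: float

    @property
    def prevalence(self) -> float:
        return self.n_pos_with / (self.n_pos_with + self.n_pos_without)


def extract_functional_regions(
    record: PromoterRecord,
    consensus_islands: Sequence[CpGIsland] = (),
    rr_bounds: tuple[int, int] = (-2000, 1000),
    promoter_bounds: tuple[int, int] = (-400, 100),
) -> FunctionalRegionSet:
    """Cut the RR and close-promoter windows and concatenate island spans
    (promoter-local half-open coordinates) in coordinate order."""
    rr = extract_relative_region(record, *rr_bounds)
    promoter = extract_relative_region(record, *promoter_bounds)
    cgi = None
    if consensus_islands:
        parts = []
        for isl in sorted(consensus_islands, key=lambda i: i.start):
            if not (0 <= isl.start < isl.end <= len(record.sequence)):
                raise ValueError(
                    f"{record.gene_id}: island [{isl.start},{isl.end}) outside record"
                )
            parts.append(record.sequence[isl.start : isl.end])
        cgi = "".join(parts)
    return FunctionalRegionSet(record.gene_id, rr, promoter, cgi)


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Euler-path shuffle preserving length, the first and last base, and
    the exact dinucleotide multiset (Altschul-Erikson)."""
    n = len(seq)
    if n < 2:
        return seq
    rng = np.random.default_rng(seed)
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    last = seq[-1]
    verts = list(succ)
    # pick one final exit edge per non-terminal vertex such that following
    # the chosen edges always reaches the terminal vertex
    for _ in range(1000):
        last_exit = {
            v: succ[v][int(rng.integers(len(succ[v])))] for v in verts if v != last
        }
        ok = True
        for v in verts:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - dense 4-letter graphs converge immediately
        raise RuntimeError("could not sample a valid Euler shuffle")
    order: dict[str, list[str]] = {}
    for v in verts:
        edges = list(succ[v])
        if v != last:
            edges.remove(last_exit[v])
        rng.shuffle(edges)
        if v != last:
            edges.append(last_exit[v])
        order[v] = edges
    ptr = {v: 0 for v in verts}
    out = [seq[0]]
    cur = seq[0]
    for _ in range(n - 1):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    """Canonical (strand-collapsed) k-mers present in one sequence."""
    rc = revcomp(seq)
    n = len(seq)
    out: set[str] = set()
    for i in range(n - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        wr = rc[n - k - i : n - i]
        out.add(w if w <= wr else wr)
    return out


def kmer_enrichment(
    positives: Sequence[str],
    k_min: int = 6,
    k_max: int = 8,
    n_shuffles_per_seq: int = 1,
    seed: int = 0,
    e_threshold: float = 0.05,
    min_pos_occurrence: int = 2,
) -> list[MotifCandidate]:
    """Rank words discriminatively enriched in ``positives`` over their
    dinucleotide shuffles.

    For each word of each k in [k_min, k_max] occurring in at least
    ``min_pos_occurrence`` positives (either strand), the one-sided
    hypergeometric tail p of its sequence-level 2x2 table is computed;
    E = p x (number of distinct words tested across all k). Candidates
    with E < ``e_threshold`` are returned sorted by p then word.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    if not (4 <= k_min <= k_max <= 12):
        raise ValueError("need 4 <= k_min <= k_max <= 12")
    background: list[str] = []
    for i, s in enumerate(positives):
        for j in range(n_shuffles_per_seq):
            child = (seed * 1000003 + i * n_shuffles_per_seq + j) % (2**31 - 1)
            background.append(dinucleotide_shuffle(s, child))
    n_pos, n_bg = len(positives), len(background)
    shortest = min(len(s) for s in positives)

    tables: list[tuple[str, int, int, int]] = []  # (word, k, a, c)
    n_words_tested = 0
    for k in range(k_min, k_max + 1):
        if k > shortest:
            warnings.warn(f"k={k} exceeds the shortest sequence; skipped")
            continue
        pos_counts: Counter[str] = Counter()
        for s in positives:
            pos_counts.update(_canonical_kmers(s, k))
        bg_counts: Counter[str] = Counter()
        for s in background:
            bg_counts.update(_canonical_kmers(s, k))
        tested = [w for w, c in pos_counts.items() if c >= min_pos_occurrence]
        n_words_tested += len(tested)
        for w in tested:
            tables.append((w, k, pos_counts[w], bg_counts.get(w, 0)))
    if not tables:
        return []
    a = np.array([t[2] for t in tables])
    c = np.array([t[3] for t in tables])
    # population: all sequences; successes: sequences containing the word;
    # draws: the positive set; observed: positives containing the word
    p = hypergeom.sf(a - 1, n_pos + n_bg, a + c, n_pos)
    out = []
    for (w, k, aa, cc), pv in zip(tables, p):
        ev = float(pv) * n_words_tested
        if ev < e_threshold:
            out.append(
                MotifCandidate(
                    word=w, k=k,
                    n_pos_with=int(aa), n_pos_without=n_pos - int(aa),
                    n_bg_with=int(cc), n_bg_without=n_bg - int(cc),
                    p_value=float(pv), e_value=ev,
                )
            )
    out.sort(key=lambda m: (m.p_value, m.word))
    return out


def _iupac_regex(word: str) -> re.Pattern[str]:
    parts = []
    for ch in word.upper():
        vals = ambiguous_dna_values.get(ch)
        if not vals or ch == "X":
            raise ValueError(f"invalid IUPAC letter {ch!r} in {word!r}")
        parts.append(ch if len(vals) == 1 else f"[{vals}]")
    return re.compile("".join(parts))


def motif_prevalence(word: str, sequences: Sequence[str]) -> float:
    """Fraction of sequences containing >= 1 match of ``word`` (IUPAC
    codes allowed) on either strand."""
    if not word:
        raise ValueError("word must be non-empty")
    pat = _iupac_regex(word)
    pat_rc = _iupac_regex(revcomp(word.upper()))
    if not sequences:
        return 0.0
    n = sum(
        1 for s in sequences if pat.search(s) is not None or pat_rc.search(s) is not None
    )
    return n / len(sequences)


def write_meme_minimal(
    candidates: Sequence[MotifCandidate], path, background=(0.25, 0.25, 0.25, 0.25)
) -> None:
    """Write candidates as MEME minimal motif format (one-hot letter
    probabilities from the exact word) for downstream PWM use."""
    idx = {b: i for i, b in enumerate("ACGT")}
    with open(path, "w", newline="\n") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA %.5f C %.5f G %.5f T %.5f\n\n"
            % tuple(background)
        )
        for m in candidates:
            fh.write(f"MOTIF {m.word}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.k} "
                f"nsites= {m.n_pos_with} E= {m.e_value:.3g}\n"
            )
            for ch in m.word:
                row = [0.0] * 4
                row[idx[ch]] = 1.0
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
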