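"""CpG-island detection and promoter CpG-class calling.

A CpG island here is a region whose GC fraction and observed/expected CpG
ratio exceed preset thresholds. The O/E statistic is the classic
``N_CpG * L / (N_C * N_G)`` (CpG dinucleotide count normalized by the count
expected from mononucleotide composition).

Three literature presets are provided (GGF, TJ, PM, after the
Gardiner-Garden & Frommer, Takai-Jones and Ponger-Mouchiroud island
definitions). The scanner is a deterministic sliding-window procedure:
every window of the preset width is scored at step 1; qualifying windows
are merged; merged spans that fail the whole-span criteria are trimmed
1 nt alternately from the 3' then the 5' end until they qualify or fall
below the preset's minimum length. This approximates the Takai-Jones
shrink procedure uniformly across presets and is exactly reproducible by
a brute-force reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import GenomicInterval, PromoterRecord

__all__ = [
    "AlgorithmPreset",
    "CpGIsland",
    "PRESETS",
    "gc_fraction",
    "cpg_oe_ratio",
    "scan_islands",
    "apply_island_criteria",
    "consensus_call",
    "classify_promoter_cpg_class",
    "islands_to_bed",
]

# Windows with more than this fraction of N are never qualifying.
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class AlgorithmPreset:
    """Sliding-window island definition: window width, minimum island
    length and the GC / O/E thresholds (evaluated per window and on the
    whole merged span)."""

    name: str
    window: int
    min_length: int
    min_gc: float
    min_oe: float

    def __post_init__(self) -> None:
        if self.window < 100:
            raise ValueError("window must be >= 100")
        if not (0 < self.min_gc < 1):
            raise ValueError("min_gc must be in (0, 1)")
        if self.min_oe <= 0:
            raise ValueError("min_oe must be positive")


#: Parameter values of the three cited island definitions.
PRESETS: dict[str, AlgorithmPreset] = {
    "GGF": AlgorithmPreset("GGF", window=200, min_length=200, min_gc=0.50, min_oe=0.60),
    "TJ": AlgorithmPreset("TJ", window=200, min_length=500, min_gc=0.55, min_oe=0.65),
    "PM": AlgorithmPreset("PM", window=500, min_length=500, min_gc=0.50, min_oe=0.60),
}


@dataclass
class CpGIsland:
    """A detected island: 0-based half-open promoter coordinates plus the
    GC fraction and O/E ratio of its span and the preset that produced it
    (or "CONSENSUS")."""

    gene_id: str
    start: int
    end: int
    gc: float
    oe: float
    preset: str

    @property
    def length(self) -> int:
        return self.end - self.start


def gc_fraction(seq: str) -> float:
    """(G + C) / non-N length. All-N input returns 0 with a warning."""
    if not seq:
        raise ValueError("empty sequence")
    non_n = len(seq) - seq.count("N")
    if non_n == 0:
        warnings.warn("gc_fraction of all-N sequence; returning 0")
        return 0.0
    return (seq.count("G") + seq.count("C")) / non_n


def cpg_oe_ratio(seq: str) -> float:
    """Observed/expected CpG ratio: N_CpG * L / (N_C * N_G).

    ``L`` is the non-N length; dinucleotides containing N never count.
    Returns 0 when the sequence lacks C or lacks G.
    """
    if not seq:
        raise ValueError("empty sequence")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c * n_g == 0:
        return 0.0
    n_cpg = seq.count("CG")
    length = len(seq) - seq.count("N")
    return n_cpg * length / (n_c * n_g)


class _SeqStats:
    """Prefix-sum counters for O(1) span statistics over one sequence."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_n = arr == ord("N")
        cg = np.zeros(len(arr), dtype=np.int64)
        if len(arr) > 1:
            cg[:-1] = (is_c[:-1] & is_g[1:]).astype(np.int64)
        z = np.zeros(1, dtype=np.int64)
        self.cum_c = np.concatenate([z, np.cumsum(is_c, dtype=np.int64)])
        self.cum_g = np.concatenate([z, np.cumsum(is_g, dtype=np.int64)])
        self.cum_n = np.concatenate([z, np.cumsum(is_n, dtype=np.int64)])
        self.cum_cg = np.concatenate([z, np.cumsum(cg)])
        self.length = len(arr)

    def span(self, a: int, b: int) -> tuple[int, int, int, int]:
        """(n_c, n_g, n_cpg, non_n) over [a, b)."""
        n_c = int(self.cum_c[b] - self.cum_c[a])
        n_g = int(self.cum_g[b] - self.cum_g[a])
        n_cpg = int(self.cum_cg[b - 1] - self.cum_cg[a]) if b - 1 > a else 0
        non_n = (b - a) - int(self.cum_n[b] - self.cum_n[a])
        return n_c, n_g, n_cpg, non_n

    def span_gc_oe(self, a: int, b: int) -> tuple[float, float]:
        n_c, n_g, n_cpg, non_n = self.span(a, b)
        gc = (n_c + n_g) / non_n if non_n else 0.0
        oe = n_cpg * non_n / (n_c * n_g) if n_c * n_g else 0.0
        return gc, oe


def scan_islands(
    seq: str, preset: AlgorithmPreset, gene_id: str = ""
) -> list[CpGIsland]:
    """Deterministic sliding-window island scan under one preset.

    Returns non-overlapping islands sorted by start; every island
    satisfies ``gc >= min_gc``, ``oe >= min_oe`` and
    ``length >= min_length`` evaluated on its whole span.
    """
    w = preset.window
    if len(seq) < w:
        warnings.warn(
            f"sequence shorter than window ({len(seq)} < {w}); no islands"
        )
        return []
    stats = _SeqStats(seq)
    n_win = len(seq) - w + 1
    starts = np.arange(n_win)
    n_c = stats.cum_c[w:] - stats.cum_c[:n_win]
    n_g = stats.cum_g[w:] - stats.cum_g[:n_win]
    n_n = stats.cum_n[w:] - stats.cum_n[:n_win]
    n_cpg = stats.cum_cg[starts + w - 1] - stats.cum_cg[starts]
    non_n = w - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(non_n > 0, (n_c + n_g) / np.maximum(non_n, 1), 0.0)
        denom = n_c * n_g
        oe = np.where(denom > 0, (n_cpg * non_n) / np.maximum(denom, 1), 0.0)
    qual = (n_n <= MAX_N_FRACTION * w) & (gc >= preset.min_gc) & (oe >= preset.min_oe)
    q = starts[qual]
    if q.size == 0:
        return []
    # merge overlapping/adjacent qualifying windows: a gap of more than the
    # window width between qualifying starts separates candidate regions
    breaks = np.nonzero(np.diff(q) > w)[0]
    region_bounds = []
    lo = 0
    for br in breaks:
        region_bounds.append((int(q[lo]), int(q[br]) + w))
        lo = br + 1
    region_bounds.append((int(q[lo]), int(q[-1]) + w))

    islands: list[CpGIsland] = []
    for a, b in region_bounds:
        trim_three_prime = True
        while b - a >= preset.min_length:
            span_gc, span_oe = stats.span_gc_oe(a, b)
            # span GC is strict (>) so the scan composes with the strict
            # downstream island filter: an inclusive bound here makes the
            # trim stop exactly on the 0.50 boundary for diluted spans,
            # which the final GC-above-50% criterion would then discard
            if span_gc > preset.min_gc and span_oe >= preset.min_oe:
                islands.append(
                    CpGIsland(gene_id, a, b, span_gc, span_oe, preset.name)
                )
                break
            if trim_three_prime:
                b -= 1
            else:
                a += 1
            trim_three_prime = not trim_three_prime
    return islands


def apply_island_criteria(
    islands: Sequence[CpGIsland],
    seq: str,
    min_length: int = 300,
    min_gc: float = 0.50,
    min_oe: float = 0.60,
) -> list[CpGIsland]:
    """Final island acceptance filter: length strictly greater than
    ``min_length``, GC strictly greater than ``min_gc``, O/E at least
    ``min_oe``, with statistics recomputed on the island span."""
    kept = []
    for isl in islands:
        sub = seq[isl.start : isl.end]
        gc = gc_fraction(sub)
        oe = cpg_oe_ratio(sub)
        if isl.length > min_length and gc > min_gc and oe >= min_oe:
            kept.append(CpGIsland(isl.gene_id, isl.start, isl.end, gc, oe, isl.preset))
    return kept


def _reciprocal_overlap(x: CpGIsland, y: CpGIsland) -> float:
    ov = min(x.end, y.end) - max(x.start, y.start)
    if ov <= 0:
        return 0.0
    return min(ov / x.length, ov / y.length)


def consensus_call(
    per_preset: Mapping[str, Sequence[CpGIsland]],
    k: int = 2,
    seq: str | None = None,
    gene_id: str = "",
) -> tuple[bool, list[CpGIsland]]:
    """Combine per-preset (already filtered) island calls.

    ``has_cgi`` is true iff at least ``k`` presets each report >= 1 island.
    The consensus island set is the merged union of islands supported by
    >= k presets under >= 50% reciprocal-overlap pairing, with statistics
    recomputed on the merged span when ``seq`` is given.
    """
    if not (1 <= k <= 3):
        raise ValueError(f"consensus support k must be in 1..3, got {k}")
    missing = set(PRESETS) - set(per_preset)
    if missing:
        raise ValueError(f"missing presets in consensus input: {sorted(missing)}")
    has_cgi = sum(1 for islands in per_preset.values() if islands) >= k

    tagged = [(p, isl) for p, islands in per_preset.items() for isl in islands]
    supported = []
    for p, isl in tagged:
        support = {
            p2
            for p2, isl2 in tagged
            if _reciprocal_overlap(isl, isl2) >= 0.5
        }
        if len(support) >= k:
            supported.append(isl)
    supported.sort(key=lambda i: (i.start, i.end))
    merged: list[list[int]] = []
    for isl in supported:
        if merged and isl.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], isl.end)
        else:
            merged.append([isl.start, isl.end])
    out = []
    for a, b in merged:
        if seq is not None:
            sub = seq[a:b]
            gc, oe = gc_fraction(sub), cpg_oe_ratio(sub)
        else:
            gc = oe = float("nan")
        out.append(CpGIsland(gene_id, a, b, gc, oe, "CONSENSUS"))
    return has_cgi, out


def classify_promoter_cpg_class(record: PromoterRecord) -> str:
    """HCP / ICP / LCP promoter CpG class (Weber-style 500-nt windows).

    HCP: some 500-nt window has GC >= 0.55 and O/E >= 0.75.
    LCP: no 500-nt window reaches O/E 0.48. ICP otherwise.
    """
    seq = record.sequence
    w = 500
    if len(seq) < w:
        warnings.warn(
            f"{record.gene_id}: promoter shorter than 500 nt; "
            "classifying on the whole sequence"
        )
        gc = np.array([gc_fraction(seq)])
        oe = np.array([cpg_oe_ratio(seq)])
    else:
        stats = _SeqStats(seq)
        n_win = len(seq) - w + 1
        starts = np.arange(n_win)
        n_c = stats.cum_c[w:] - stats.cum_c[:n_win]
        n_g = stats.cum_g[w:] - stats.cum_g[:n_win]
        n_n = stats.cum_n[w:] - stats.cum_n[:n_win]
        n_cpg = stats.cum_cg[starts + w - 1] - stats.cum_cg[starts]
        non_n = w - n_n
        with np.errstate(divide="ignore", invalid="ignore"):
            gc = np.where(non_n > 0, (n_c + n_g) / np.maximum(non_n, 1), 0.0)
            denom = n_c * n_g
            oe = np.where(denom > 0, (n_cpg * non_n) / np.maximum(denom, 1), 0.0)
    if bool(np.any((gc >= 0.55) & (oe >= 0.75))):
        return "HCP"
    if not bool(np.any(oe >= 0.48)):
        return "LCP"
    return "ICP"


def islands_to_bed(islands: Sequence[CpGIsland]) -> list[GenomicInterval]:
    """Islands as BED6: name = gene_id:preset, score = round(O/E * 1000)."""
    return [
        GenomicInterval(
            isl.gene_id,
            isl.start,
            isl.end,
            name=f"{isl.gene_id}:{isl.preset}",
            score=int(round(isl.oe * 1000)),
            strand=".",
        )
        for isl in islands
    ]
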