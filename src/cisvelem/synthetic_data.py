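"""Seeded synthetic promoter cohorts with planted ground truth.

The generator emulates the statistical structure of a 252-gene
downregulation screen: 3001-nt TSS-anchored promoters drawn from a
CpG-depleted order-1 Markov background (GC ~ 0.41, CpG O/E ~ 0.25,
roughly the bulk-genome values), a controllable fraction of genes
carrying a planted CpG island (order-1 Markov segment targeting
GC 0.60 / O/E 1.0, overlapping the TSS), consensus binding sites of
partner TFs and a common 8-mer motif planted in stated fractions of
the island-bearing genes, and |z| scores drawn uniformly from the
selection range 2.0-6.8.

Ground truth is emitted alongside the FASTA so every downstream stage
can be scored against planted labels. For the *planted* TFs, the
generator additionally scrubs chance background matches (iterative
single-base edits outside planted features, re-verifying island
composition margins), so the per-TF gene frequency of a scan at the
default threshold equals the planted composition exactly.

Backgrounds are order-1 Markov rather than i.i.d. so that the
dinucleotide-preserving shuffles used as the motif-enrichment null are
a fair comparison. Seeds are mandatory; there is no wall-clock entropy.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cgi_detection import cpg_oe_ratio, gc_fraction
from .sequence_io import (
    GeneExpressionRecord,
    GenomicInterval,
    PromoterRecord,
    write_bed,
    write_fasta,
)
from .tfbs_scan import (
    PositionWeightMatrix,
    default_pwm_library,
    relative_score,
    revcomp,
    scan_pwm,
)

__all__ = [
    "CohortSpec",
    "GeneTruth",
    "generate_background",
    "plant_island",
    "plant_sites",
    "generate_study_set",
]

_BASES = "ACGT"

# Island acceptance margins: comfortably above the > 0.50 GC / >= 0.60 O/E
# island filter so detector recovery is not threshold-knife-edge, plus a
# realized-vs-target GC tolerance so the emitted island matches its model.
ISLAND_MIN_GC = 0.50
ISLAND_MIN_OE = 0.75
ISLAND_GC_TOL = 0.03


@dataclass
class CohortSpec:
    """Generator contract for one synthetic cohort.

    Defaults mirror the screen's printed composition: 252 genes, 3001-nt
    promoters, 146/252 with CpG islands, the common motif in 80% of the
    island-bearing genes, |z| in 2.0-6.8.
    """

    seed: int
    n_genes: int = 252
    promoter_length: int = 3001
    frac_cgi: float = 146 / 252
    island_length_range: tuple[int, int] = (350, 800)
    island_gc_target: float = 0.60
    island_oe_target: float = 1.0
    background_gc: float = 0.41
    background_cpg_oe: float = 0.25
    planted_tfs: tuple[tuple[str, float], ...] = (
        ("SP1", 1.0),
        ("EGR-1", 0.8),
        ("MYC", 0.6),
    )
    planted_motif: tuple[str, float] = ("GTTCGGCA", 0.80)
    z_range_down: tuple[float, float] = (2.0, 6.8)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in [self.frac_cgi, self.planted_motif[1]] + [
            f for _, f in self.planted_tfs
        ]:
            if not (0 <= frac <= 1):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.island_length_range[1] >= self.promoter_length:
            raise ValueError("island does not fit inside the promoter")


@dataclass
class GeneTruth:
    """Planted features of one gene, the acceptance oracle."""

    gene_id: str
    has_cgi: bool
    islands: list[tuple[int, int]] = field(default_factory=list)
    island_gc: Optional[float] = None
    island_oe: Optional[float] = None
    tf_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    motif_positions: list[int] = field(default_factory=list)
    z_magnitude: float = 0.0
    pdown3b_expected: bool = False


def _stationary(T: np.ndarray) -> np.ndarray:
    A = np.vstack([T.T - np.eye(4), np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def _transition_matrix(gc: float, oe_factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Order-1 transition matrix with stationary GC ``gc`` and expected
    CpG O/E ``oe_factor``: the C->G transition is pinned to
    oe_factor * pi(G) and the remaining mass adjusted by fixed point."""
    if not (0 < gc < 1) or oe_factor <= 0:
        raise ValueError("need 0 < gc < 1 and oe_factor > 0")
    target = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    t_cg = oe_factor * target[2]
    if t_cg >= 1:
        raise ValueError(
            f"infeasible (gc={gc}, oe_factor={oe_factor}): C->G prob {t_cg:.3f} >= 1"
        )
    q = target.copy()
    T = None
    for _ in range(500):
        row_c = q.copy()
        row_c[2] = 0.0
        row_c *= (1 - t_cg) / row_c.sum()
        row_c[2] = t_cg
        T = np.tile(q, (4, 1))
        T[1] = row_c
        pi = _stationary(T)
        if np.max(np.abs(pi - target)) < 1e-12:
            break
        q = q * (target / np.maximum(pi, 1e-12))
        q = np.clip(q, 1e-9, None)
        q /= q.sum()
    if np.any(T < -1e-12):
        raise ValueError(
            f"infeasible (gc={gc}, oe_factor={oe_factor}): transition row {T[1]}"
        )
    return np.clip(T, 0, None), _stationary(T)


def _sample_markov(
    length: int, T: np.ndarray, pi: np.ndarray, rng: np.random.Generator
) -> str:
    cum_rows = [list(np.cumsum(T[i])) for i in range(4)]
    cum_pi = list(np.cumsum(pi))
    u = rng.random(length)
    s = min(bisect_right(cum_pi, u[0]), 3)
    out = [s]
    for i in range(1, length):
        s = min(bisect_right(cum_rows[s], u[i]), 3)
        out.append(s)
    return "".join(_BASES[i] for i in out)


def generate_background(length: int, gc: float, cpg_oe_factor: float, seed: int) -> str:
    """CpG-depleted (or -neutral) order-1 Markov background sequence."""
    T, pi = _transition_matrix(gc, cpg_oe_factor)
    rng = np.random.default_rng(seed)
    return _sample_markov(length, T, pi, rng)


def plant_island(
    seq: str,
    start: int,
    length: int,
    gc_target: float = 0.60,
    oe_target: float = 1.0,
    seed: int = 0,
    max_tries: int = 100,
) -> tuple[str, tuple[int, int]]:
    """Replace ``seq[start:start+length]`` with an island-like Markov draw.

    The realized span must satisfy GC > 0.50 within 0.03 of target and
    O/E >= 0.75 (margins above the island filter); otherwise the draw is
    retried, up to ``max_tries`` times.
    """
    if not (0 <= start and start + length <= len(seq)):
        raise ValueError(f"island [{start},{start + length}) outside sequence")
    T, pi = _transition_matrix(gc_target, oe_target)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seg = _sample_markov(length, T, pi, rng)
        gc, oe = gc_fraction(seg), cpg_oe_ratio(seg)
        if (
            gc > ISLAND_MIN_GC
            and abs(gc - gc_target) <= ISLAND_GC_TOL
            and oe >= ISLAND_MIN_OE
        ):
            return seq[:start] + seg + seq[start + length :], (start, start + length)
    raise ValueError(
        f"no acceptable island draw in {max_tries} tries "
        f"(targets gc={gc_target}, oe={oe_target}, length={length})"
    )


def plant_sites(
    seq: str,
    pwm: PositionWeightMatrix,
    positions: Sequence[int],
    strands: Optional[Sequence[str]] = None,
    sample: bool = False,
    seed: int = 0,
) -> tuple[str, list[tuple[int, str]]]:
    """Overwrite each position with the PWM consensus word (default) or a
    PWM-sampled word; '-' strand plants the reverse complement."""
    w = pwm.width
    strands = list(strands) if strands is not None else ["+"] * len(positions)
    if len(strands) != len(positions):
        raise ValueError("positions and strands must have equal length")
    ordered = sorted(zip(positions, strands))
    for (p1, _), (p2, _) in zip(ordered, ordered[1:]):
        if p2 < p1 + w:
            raise ValueError(f"overlapping plant positions {p1} and {p2}")
    rng = np.random.default_rng(seed)
    chars = list(seq)
    truth = []
    for pos, strand in ordered:
        if not (0 <= pos and pos + w <= len(seq)):
            raise ValueError(f"plant position {pos} out of bounds")
        if sample:
            word = "".join(
                _BASES[rng.choice(4, p=pwm.probs[j])] for j in range(w)
            )
        else:
            word = pwm.consensus
        if strand == "-":
            word = revcomp(word)
        chars[pos : pos + w] = word
        truth.append((pos, strand))
    return "".join(chars), truth


def _island_margins_ok(chars: list[str], islands: Sequence[tuple[int, int]]) -> bool:
    for a, b in islands:
        sub = "".join(chars[a:b])
        if not (gc_fraction(sub) > ISLAND_MIN_GC and cpg_oe_ratio(sub) >= ISLAND_MIN_OE):
            return False
    return True


def _scrub_spurious_sites(
    chars: list[str],
    pwms: dict[str, PositionWeightMatrix],
    planted_starts: dict[str, set[int]],
    keep: np.ndarray,
    islands: Sequence[tuple[int, int]],
    min_rel_score: float,
    rng: np.random.Generator,
    max_rounds: int = 40,
) -> None:
    """Edit single bases until no non-planted hit of any planted-TF PWM
    remains at ``min_rel_score``, without touching planted features and
    keeping island composition above its margins."""
    for _ in range(max_rounds):
        seq = "".join(chars)
        spurious = []
        for tf, pwm in pwms.items():
            for h in scan_pwm(seq, pwm, min_rel_score):
                if h.start not in planted_starts.get(tf, set()):
                    spurious.append((pwm, h.start))
        if not spurious:
            return
        for pwm, start in spurious:
            w = pwm.width
            lo = pwm.log_odds
            lo_rc = lo[::-1, ::-1]

            def _rels() -> tuple[float, float]:
                window = "".join(chars[start : start + w])
                return (
                    relative_score(pwm, window),
                    relative_score(pwm, revcomp(window)),
                )

            rel_f, rel_r = _rels()
            if rel_f < min_rel_score and rel_r < min_rel_score:
                continue  # already broken by an earlier edit this round
            editable = [p for p in range(start, start + w) if not keep[p]]
            rng.shuffle(editable)
            # a single mismatch only lowers the relative score by ~1/width,
            # so apply greedy anti-consensus edits until both strands drop
            for p in editable:
                j = p - start
                row = lo[j] if rel_f >= rel_r else lo_rc[j]
                old = chars[p]
                chars[p] = _BASES[int(np.argmin(row))]
                if chars[p] == old or not _island_margins_ok(chars, islands):
                    chars[p] = old
                    continue
                rel_f, rel_r = _rels()
                if rel_f < min_rel_score and rel_r < min_rel_score:
                    break
            # an unfixable hit (fully inside kept features) is left for the
            # final verification below; does not occur with the bundled library
    seq = "".join(chars)
    leftover = [
        (tf, h.start)
        for tf, pwm in pwms.items()
        for h in scan_pwm(seq, pwm, min_rel_score)
        if h.start not in planted_starts.get(tf, set())
    ]
    if leftover:
        raise RuntimeError(f"could not scrub spurious TF hits: {leftover[:5]}")


def _free_position(
    rng: np.random.Generator,
    length: int,
    width: int,
    occupied: list[tuple[int, int]],
    gap: int = 20,
    max_tries: int = 200,
) -> int:
    """Uniform position whose window keeps ``gap`` nt clear of every
    occupied feature: adjacent planted words could otherwise juxtapose
    into unintended composite binding sites."""
    for _ in range(max_tries):
        pos = int(rng.integers(0, length - width + 1))
        if all(pos + width + gap <= a or pos >= b + gap for a, b in occupied):
            return pos
    raise RuntimeError("could not place a planted feature without overlap")


def generate_study_set(
    spec: CohortSpec,
    out_dir=None,
    pwm_library: Optional[Sequence[PositionWeightMatrix]] = None,
    scan_min_rel_score: float = 0.8,
    scrub: bool = True,
) -> tuple[list[PromoterRecord], list[GeneExpressionRecord], list[GeneTruth]]:
    """Generate the cohort; optionally write FASTA, gene table, truth
    tables, truth-island BED and a spec echo into ``out_dir``.

    Deterministic: identical spec (seed included) gives byte-identical
    outputs.
    """
    from .tfbs_scan import resolve_panel_pwms, PartnerPanel  # local to avoid cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    L = spec.promoter_length
    tss = (L - 1) * 2 // 3  # index 2000 for the default 3001-nt window
    pwms = list(pwm_library) if pwm_library is not None else default_pwm_library()
    planted_tf_names = [tf for tf, _ in spec.planted_tfs]
    resolved = resolve_panel_pwms(pwms, PartnerPanel(planted_tf_names)) if planted_tf_names else {}
    tf_pwm = {tf: mats[0] for tf, mats in resolved.items()}

    n_cgi = int(round(spec.frac_cgi * n))
    order = rng.permutation(n)
    cgi_idx = set(int(i) for i in order[:n_cgi])
    cgi_sorted = sorted(cgi_idx)

    tf_recipients: dict[str, set[int]] = {}
    for tf, frac in spec.planted_tfs:
        k = int(round(frac * n_cgi))
        perm = rng.permutation(cgi_sorted)
        tf_recipients[tf] = set(int(i) for i in perm[:k])
    motif_word, motif_frac = spec.planted_motif
    perm = rng.permutation(cgi_sorted)
    motif_recipients = set(int(i) for i in perm[: int(round(motif_frac * n_cgi))])

    z = rng.uniform(spec.z_range_down[0], spec.z_range_down[1], size=n)

    width = len(str(n))
    records: list[PromoterRecord] = []
    expr: list[GeneExpressionRecord] = []
    truths: list[GeneTruth] = []
    for i in range(n):
        gene_id = f"G{i + 1:0{width}d}"
        seed_bg = int(rng.integers(0, 2**31 - 1))
        seq = generate_background(L, spec.background_gc, spec.background_cpg_oe, seed_bg)
        truth = GeneTruth(gene_id=gene_id, has_cgi=i in cgi_idx, z_magnitude=float(z[i]))
        occupied: list[tuple[int, int]] = []
        if truth.has_cgi:
            ilen = int(rng.integers(spec.island_length_range[0], spec.island_length_range[1] + 1))
            lo = max(0, tss - ilen + 100)
            hi = min(L - ilen, tss - 100)
            if lo >= hi:  # degenerate geometry (tiny promoters): place anywhere
                lo, hi = 0, L - ilen
            start = int(rng.integers(lo, hi + 1))
            seed_isl = int(rng.integers(0, 2**31 - 1))
            seq, interval = plant_island(
                seq, start, ilen, spec.island_gc_target, spec.island_oe_target, seed_isl
            )
            truth.islands = [interval]
            occupied.append(interval)
        for tf in planted_tf_names:
            if i in tf_recipients.get(tf, set()):
                pwm = tf_pwm[tf]
                pos = _free_position(rng, L, pwm.width, occupied)
                strand = "+" if rng.random() < 0.5 else "-"
                seq, planted = plant_sites(seq, pwm, [pos], [strand])
                truth.tf_sites[tf] = planted
                occupied.append((pos, pos + pwm.width))
        if i in motif_recipients:
            pos = _free_position(rng, L, len(motif_word), occupied)
            seq = seq[:pos] + motif_word + seq[pos + len(motif_word) :]
            truth.motif_positions = [pos]
            occupied.append((pos, pos + len(motif_word)))
        if scrub and tf_pwm:
            chars = list(seq)
            keep = np.zeros(L, dtype=bool)
            for a, b in occupied:
                if (a, b) not in truth.islands:
                    keep[a:b] = True
            planted_starts = {
                tf: {p for p, _ in sites} for tf, sites in truth.tf_sites.items()
            }
            _scrub_spurious_sites(
                chars, tf_pwm, planted_starts, keep, truth.islands,
                scan_min_rel_score, rng,
            )
            seq = "".join(chars)
        if truth.islands:
            a, b = truth.islands[0]
            truth.island_gc = gc_fraction(seq[a:b])
            truth.island_oe = cpg_oe_ratio(seq[a:b])
        z_lo, z_hi = spec.z_range_down
        truth.pdown3b_expected = (
            truth.has_cgi
            and bool(truth.tf_sites)
            and z_lo <= truth.z_magnitude <= z_hi
        )
        records.append(PromoterRecord(gene_id, seq, -tss, L - tss))
        expr.append(GeneExpressionRecord(gene_id, float(z[i])))
        truths.append(truth)

    if out_dir is not None:
        _write_cohort(Path(out_dir), spec, records, truths)
    return records, expr, truths


def _write_cohort(
    out_dir: Path,
    spec: CohortSpec,
    records: Sequence[PromoterRecord],
    truths: Sequence[GeneTruth],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(records, out_dir / "promoters.fasta")
    # microarray convention: downregulation printed with negative sign
    with open(out_dir / "genes.tsv", "w", newline="\n") as fh:
        fh.write("gene_id\tz_score\n")
        for t in truths:
            fh.write(f"{t.gene_id}\t{-t.z_magnitude:.4f}\n")
    with open(out_dir / "truth_genes.tsv", "w", newline="\n") as fh:
        fh.write(
            "gene_id\thas_cgi\tz_magnitude\tn_tf_sites\tmotif_planted\tpdown3b_expected\n"
        )
        for t in truths:
            n_sites = sum(len(v) for v in t.tf_sites.values())
            fh.write(
                f"{t.gene_id}\t{int(t.has_cgi)}\t{t.z_magnitude:.4f}\t"
                f"{n_sites}\t{int(bool(t.motif_positions))}\t{int(t.pdown3b_expected)}\n"
            )
    islands = [
        GenomicInterval(
            t.gene_id, a, b,
            name=f"{t.gene_id}:truth",
            score=int(round((t.island_oe or 0) * 1000)),
            strand=".",
        )
        for t in truths
        for a, b in t.islands
    ]
    write_bed(islands, out_dir / "truth_islands.bed")
    with open(out_dir / "truth_sites.tsv", "w", newline="\n") as fh:
        fh.write("gene_id\tfeature\tstart\tstrand\n")
        for t in truths:
            for tf, sites in sorted(t.tf_sites.items()):
                for pos, strand in sites:
                    fh.write(f"{t.gene_id}\t{tf}\t{pos}\t{strand}\n")
            for pos in t.motif_positions:
                fh.write(f"{t.gene_id}\tMOTIF:{spec.planted_motif[0]}\t{pos}\t+\n")
    with open(out_dir / "cohort_spec.json", "w", newline="\n") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
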