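"""PWM scanning of promoter regions against a DNMT3B-partner TF panel.

Matrices are read from JASPAR PFM text (four count rows per record),
converted to per-position base probabilities with a pseudocount, and
scanned as log2-odds scores against a background base model on both
strands. A hit's relative score rescales the log-odds score onto [0, 1]
between the worst and best word of the matrix, so thresholds are
comparable across TFs of different widths and information content.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .sequence_io import PromoterRecord, extract_relative_region

__all__ = [
    "PositionWeightMatrix",
    "TFBSHit",
    "PartnerPanel",
    "DEFAULT_PANEL_TFS",
    "load_pwms",
    "load_panel",
    "default_pwm_library",
    "default_panel",
    "scan_pwm",
    "relative_score",
    "tf_presence_matrix",
    "tf_gene_frequency",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: The 17 named TFs of the DNMT3B-partner panel (an 18th partner with
#: sites is reported but unnamed in the source screen, so it is not
#: guessed here; the panel file is user-editable).
DEFAULT_PANEL_TFS = (
    "SP1", "EGR-1", "ER", "GATA-1", "GR", "c-JUN", "YY1", "ATF", "CREB",
    "ELK1", "c-FOS", "MYC", "E2F", "HOXA5", "HNF4", "MEF2", "PPAR",
)

# normalized-alias -> normalized-panel-name (JASPAR-style names on the left)
_SYNONYMS = {
    "ESR1": "ER",
    "ESR2": "ER",
    "NR3C1": "GR",
    "GATA1": "GATA1",
    "JUN": "CJUN",
    "FOS": "CFOS",
    "EGR1": "EGR1",
    "ATF1": "ATF",
    "CREB1": "CREB",
    "E2F1": "E2F",
    "HNF4A": "HNF4",
    "MEF2A": "MEF2",
    "MEF2C": "MEF2",
    "PPARG": "PPAR",
    "PPARA": "PPAR",
}


def _norm(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]", "", name).upper()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities (rows = positions, columns = ACGT)
    with a background model. ``probs`` already includes the pseudocount."""

    tf_name: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0
    matrix_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"{self.tf_name}: probs must be (width, 4)")
        if self.width < 4:
            raise ValueError(f"{self.tf_name}: PWM width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.tf_name}: probability rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.tf_name}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @cached_property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    @cached_property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @cached_property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))


@dataclass
class TFBSHit:
    """One PWM match: 0-based start in promoter coordinates, strand,
    raw log2-odds score and its [0, 1] relative score."""

    gene_id: str
    tf_name: str
    start: int
    strand: str
    score_bits: float
    rel_score: float


@dataclass
class PartnerPanel:
    """The TF panel restricting which matrices are scanned."""

    tf_names: list[str]
    source_note: str = ""

    def __post_init__(self) -> None:
        if len(set(self.tf_names)) != len(self.tf_names):
            raise ValueError("panel TF names must be unique")
        if any(not n for n in self.tf_names):
            raise ValueError("panel TF names must be non-empty")


def load_pwms(path, pseudocount: float = 0.01, background=None) -> list[PositionWeightMatrix]:
    """Read a JASPAR PFM file.

    Counts get ``pseudocount`` added per cell and are row-normalized
    (a consensus cell with 10 observations and pseudocount 1 becomes
    (10+1)/(10+4)). Default background is uniform.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        name = m.name or m.matrix_id or "?"
        counts = np.array([m.counts[b] for b in _BASES], dtype=float).T
        if np.any(counts < 0):
            raise ValueError(f"negative count in matrix {name}")
        col_tot = counts.sum(axis=1)
        if np.any(col_tot == 0):
            raise ValueError(f"zero-sum column in matrix {name}")
        probs = (counts + pseudocount) / (col_tot + 4 * pseudocount)[:, None]
        out.append(
            PositionWeightMatrix(
                tf_name=name,
                probs=probs,
                background=bg,
                pseudocount=pseudocount,
                matrix_id=m.matrix_id or "",
            )
        )
    if not out:
        raise ValueError(f"no matrices parsed from {path}")
    return out


def load_panel(path) -> PartnerPanel:
    """Panel file: one TF name per line, '#' comments allowed."""
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                names.append(line)
    return PartnerPanel(names, source_note=str(path))


def default_pwm_library(pseudocount: float = 0.01) -> list[PositionWeightMatrix]:
    """Bundled synthetic consensus-derived matrices for the partner panel."""
    ref = resources.files("cisvelem").joinpath("data/panel_pwms_synthetic.pfm")
    with resources.as_file(ref) as path:
        return load_pwms(path, pseudocount=pseudocount)


def default_panel() -> PartnerPanel:
    ref = resources.files("cisvelem").joinpath("data/partner_panel.txt")
    with resources.as_file(ref) as path:
        return load_panel(path)


_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rel_from_scores(scores: np.ndarray, pwm: PositionWeightMatrix) -> np.ndarray:
    lo, hi = pwm.min_score, pwm.max_score
    if not np.isfinite(lo) or hi == lo:
        # degenerate range (e.g. zero pseudocount): consensus scores 1, rest 0
        return (scores == hi).astype(float)
    return (scores - lo) / (hi - lo)


def relative_score(pwm: PositionWeightMatrix, word: str) -> float:
    """Relative score of a single word of the PWM's width (forward strand)."""
    if len(word) != pwm.width:
        raise ValueError("word length must equal PWM width")
    codes = _encode(word)
    if np.any(codes == 4):
        return 0.0
    score = float(pwm.log_odds[np.arange(pwm.width), codes].sum())
    return float(_rel_from_scores(np.array([score]), pwm)[0])


def scan_pwm(
    seq: str,
    pwm: PositionWeightMatrix,
    min_rel_score: float = 0.8,
    gene_id: str = "",
) -> list[TFBSHit]:
    """Score every start position on both strands; keep hits with
    relative score >= ``min_rel_score``. Windows containing N are skipped.
    Hits are sorted by start, '+' before '-'."""
    if not (0 < min_rel_score <= 1):
        raise ValueError("min_rel_score must be in (0, 1]")
    w = pwm.width
    if len(seq) < w:
        warnings.warn(f"sequence shorter than PWM width ({len(seq)} < {w})")
        return []
    codes = _encode(seq)
    n_win = len(seq) - w + 1
    has_n = np.convolve((codes == 4).astype(np.int64), np.ones(w, dtype=np.int64))[
        w - 1 : w - 1 + n_win
    ]
    valid = has_n == 0
    # padded 5th column so N positions do not poison the sum (they are
    # excluded by `valid` anyway)
    lo = np.hstack([pwm.log_odds, np.zeros((w, 1))])
    lo_rc = lo[::-1, [3, 2, 1, 0, 4]]
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    for j in range(w):
        col = codes[j : j + n_win]
        fwd += lo[j, col]
        rev += lo_rc[j, col]
    hits: list[TFBSHit] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        rel = _rel_from_scores(scores, pwm)
        for i in np.nonzero(valid & (rel >= min_rel_score))[0]:
            hits.append(
                TFBSHit(
                    gene_id, pwm.tf_name, int(i), strand,
                    float(scores[i]), float(rel[i]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def resolve_panel_pwms(
    pwms: Sequence[PositionWeightMatrix], panel: PartnerPanel
) -> dict[str, list[PositionWeightMatrix]]:
    """Map each panel TF to its matrices (case-insensitive, with a small
    synonym map). Raises listing any panel TF with no matrix."""
    by_key: dict[str, list[PositionWeightMatrix]] = {}
    for pwm in pwms:
        key = _norm(pwm.tf_name)
        key = _SYNONYMS.get(key, key)
        by_key.setdefault(key, []).append(pwm)
    resolved = {}
    unresolved = []
    for tf in panel.tf_names:
        key = _norm(tf)
        matches = by_key.get(key) or by_key.get(_SYNONYMS.get(key, key), [])
        if matches:
            resolved[tf] = matches
        else:
            unresolved.append(tf)
    if unresolved:
        raise ValueError(f"panel TFs with no PWM: {unresolved}")
    return resolved


def tf_presence_matrix(
    records: Sequence[PromoterRecord],
    pwms: Sequence[PositionWeightMatrix],
    panel: PartnerPanel,
    region: tuple[int, int] = (-2000, 1000),
    min_rel_score: float = 0.8,
) -> pd.DataFrame:
    """Boolean genes x TFs matrix: cell true iff >= 1 hit for that TF in
    the gene's TSS-relative ``region`` (inclusive bounds)."""
    resolved = resolve_panel_pwms(pwms, panel)
    data = {}
    for rec in records:
        sub = extract_relative_region(rec, region[0], region[1])
        row = {}
        for tf, tf_pwms in resolved.items():
            row[tf] = any(
                scan_pwm(sub, p, min_rel_score, gene_id=rec.gene_id)
                for p in tf_pwms
            )
        data[rec.gene_id] = row
    df = pd.DataFrame.from_dict(data, orient="index")
    if df.empty:
        df = pd.DataFrame(index=[r.gene_id for r in records])
    return df.reindex(columns=list(panel.tf_names)).fillna(False).astype(bool)


def tf_gene_frequency(matrix: pd.DataFrame) -> pd.Series:
    """Per-TF count of genes with >= 1 site (column sums)."""
    return matrix.sum(axis=0).astype(int)


def ranked_tf_table(freq: pd.Series) -> pd.DataFrame:
    """Frequency-distribution table, most frequent TF first."""
    df = freq.sort_values(ascending=False, kind="stable").rename("n_genes").reset_index()
    df.columns = ["tf", "n_genes"]
    return df


def plot_tf_frequencies(freq: pd.Series, path) -> None:
    """Bar chart of the per-TF gene frequency (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = ranked_tf_table(freq)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.bar(ranked["tf"], ranked["n_genes"], color="#4C72B0")
    ax.set_ylabel("genes with ≥ 1 site")
    ax.set_xlabel("partner TF")
    plt.setp(ax.get_xticklabels(), rotation=60, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
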