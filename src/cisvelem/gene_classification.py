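"""Downregulated-gene selection, P-down-3B designation, and peak overlap.

A P-down-3B gene is a gene downregulated under DNMT3B overexpression
whose promoter carries a consensus CpG island and at least one
partner-TF binding site. Common-motif presence is reported alongside
and can optionally be made a gating condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import GeneExpressionRecord, GenomicInterval

__all__ = [
    "GeneAnnotation",
    "select_downregulated",
    "designate_pdown3b",
    "peak_gene_overlap",
]


@dataclass
class GeneAnnotation:
    """Per-gene aggregation of all screening evidence."""

    gene_id: str
    z_magnitude: float
    selected: bool
    has_cgi: dict[str, bool] = field(default_factory=dict)  # per preset
    has_cgi_consensus: Optional[bool] = None
    n_partner_tfs_with_site: Optional[int] = None
    motif_present: Optional[bool] = None
    pdown3b: Optional[bool] = None
    cpg_class: Optional[str] = None


def select_downregulated(
    records: Sequence[GeneExpressionRecord], z_lo: float = 2.0, z_hi: float = 6.8
) -> list[GeneExpressionRecord]:
    """Keep genes whose |z| lies in [z_lo, z_hi], inclusive both ends."""
    if z_lo > z_hi:
        raise ValueError("z_lo must be <= z_hi")
    return [r for r in records if z_lo <= r.z_magnitude <= z_hi]


def designate_pdown3b(
    annotations: Sequence[GeneAnnotation], require_motif: bool = False
) -> list[GeneAnnotation]:
    """Set ``pdown3b = selected AND consensus CGI AND >= 1 partner-TF site``
    (AND motif presence when ``require_motif``). Mutates and returns the
    annotations."""
    for ann in annotations:
        for fld in ("has_cgi_consensus", "n_partner_tfs_with_site", "motif_present"):
            if getattr(ann, fld) is None:
                raise ValueError(f"{ann.gene_id}: missing field {fld!r}")
        ann.pdown3b = (
            ann.selected
            and bool(ann.has_cgi_consensus)
            and ann.n_partner_tfs_with_site >= 1
            and (bool(ann.motif_present) or not require_motif)
        )
    return list(annotations)


def peak_gene_overlap(
    peaks: Sequence[GenomicInterval],
    tss: Mapping[str, tuple[str, int]],
    max_dist: int = 5000,
    has_cgi: Optional[Mapping[str, bool]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Nearest-peak distance per gene TSS plus near-peak summary counts.

    ``tss`` maps gene_id -> (seq_id, position). Distance is 0 when the
    TSS lies inside a peak, otherwise ``start - pos`` or ``pos - end``
    to the nearest peak on the same seq_id; genes with no peak on their
    seq_id get NaN. The summary counts genes with distance <= max_dist,
    stratified by ``has_cgi`` when given.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if not peaks:
        warnings.warn("empty peak set; all distances undefined")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.seq_id, []).append(p)
    rows = []
    for gene_id, (seq_id, pos) in tss.items():
        dist = float("nan")
        for p in by_chrom.get(seq_id, []):
            d = max(0, p.start - pos, pos - p.end)
            if not (dist == dist) or d < dist:  # NaN-safe min
                dist = float(d)
        rows.append({"gene_id": gene_id, "nearest_peak_dist": dist})
    df = pd.DataFrame(rows).set_index("gene_id")
    near = df["nearest_peak_dist"] <= max_dist
    summary: dict = {
        "n_genes": len(df),
        "n_near_peak": int(near.sum()),
        "max_dist": max_dist,
    }
    if has_cgi is not None:
        cgi_mask = pd.Series(
            [bool(has_cgi.get(g, False)) for g in df.index], index=df.index
        )
        summary["n_near_peak_with_cgi"] = int((near & cgi_mask).sum())
        summary["n_near_peak_without_cgi"] = int((near & ~cgi_mask).sum())
        summary["n_with_cgi"] = int(cgi_mask.sum())
        summary["n_without_cgi"] = int((~cgi_mask).sum())
    return df, summary
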