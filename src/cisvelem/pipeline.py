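"""End-to-end screening pipeline and its machine-readable run report.

Stage order: select downregulated genes -> CpG-island scan under three
presets + acceptance filter + consensus -> partner-TF PWM scan ->
functional regions -> discriminative motif enrichment and prevalence ->
P-down-3B designation -> optional peak overlap. Every stage writes a
plain-text artifact into the output directory, and the report can be
rebuilt bit-exactly from those artifacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import cgi_detection as cgi
from . import gene_classification as gcls
from . import motif_analysis as motifs
from . import sequence_io as sio
from . import tfbs_scan as tfbs

__all__ = ["PipelineConfig", "run_pipeline", "rebuild_report"]

log = logging.getLogger("cisvelem")


@dataclass
class PipelineConfig:
    """All pipeline inputs and tunables; YAML-loadable with CLI overrides."""

    fasta: str
    gene_table: str
    out_dir: str
    pwm_library: Optional[str] = None  # None -> bundled synthetic library
    panel: Optional[str] = None  # None -> bundled 17-TF partner panel
    peaks: Optional[str] = None
    rel_start: int = -2000
    rel_end: int = 1001
    permissive_fasta: bool = False
    z_lo: float = 2.0
    z_hi: float = 6.8
    consensus_k: int = 2
    min_rel_score: float = 0.8
    scan_region: tuple[int, int] = (-2000, 1000)
    k_min: int = 6
    k_max: int = 8
    n_shuffles: int = 1
    require_motif: bool = False
    max_peak_dist: int = 5000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "scan_region" in raw:
            raw["scan_region"] = tuple(raw["scan_region"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("fasta", "gene_table"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} not found: {p}")
        for name in ("pwm_library", "panel", "peaks"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} not found: {p}")
        if not (1 <= self.consensus_k <= 3):
            raise ValueError("consensus_k must be in 1..3")
        if not (0 < self.min_rel_score <= 1):
            raise ValueError("min_rel_score must be in (0, 1]")
        if not (4 <= self.k_min <= self.k_max <= 12):
            raise ValueError("need 4 <= k_min <= k_max <= 12")
        if self.z_lo > self.z_hi:
            raise ValueError("z_lo must be <= z_hi")


def _dump_json(obj, path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("reading inputs: %s, %s", config.fasta, config.gene_table)
    records = sio.read_fasta(
        config.fasta, config.rel_start, config.rel_end, permissive=config.permissive_fasta
    )
    expr = sio.read_gene_table(config.gene_table)
    by_id = {r.gene_id: r for r in records}

    selected = gcls.select_downregulated(expr, config.z_lo, config.z_hi)
    selected_ids = [r.gene_id for r in selected if r.gene_id in by_id]
    log.info("selected %d/%d genes with |z| in [%s, %s]",
             len(selected_ids), len(expr), config.z_lo, config.z_hi)
    sel_records = [by_id[g] for g in selected_ids]

    # --- CpG islands, three presets + filter + consensus -------------------
    per_gene_islands: dict[str, dict[str, list[cgi.CpGIsland]]] = {}
    consensus: dict[str, tuple[bool, list[cgi.CpGIsland]]] = {}
    bed_by_preset: dict[str, list] = {p: [] for p in cgi.PRESETS}
    consensus_bed = []
    for rec in sel_records:
        per_preset = {}
        for name, preset in cgi.PRESETS.items():
            islands = cgi.scan_islands(rec.sequence, preset, gene_id=rec.gene_id)
            islands = cgi.apply_island_criteria(islands, rec.sequence)
            per_preset[name] = islands
            bed_by_preset[name].extend(cgi.islands_to_bed(islands))
        has, cons = cgi.consensus_call(
            per_preset, k=config.consensus_k, seq=rec.sequence, gene_id=rec.gene_id
        )
        per_gene_islands[rec.gene_id] = per_preset
        consensus[rec.gene_id] = (has, cons)
        consensus_bed.extend(cgi.islands_to_bed(cons))
    for name, ivs in bed_by_preset.items():
        sio.write_bed(ivs, out / f"islands_{name}.bed")
    sio.write_bed(consensus_bed, out / "islands_consensus.bed")

    cgi_rows = []
    for g in selected_ids:
        per_preset = per_gene_islands[g]
        for name, islands in per_preset.items():
            cgi_rows.append({
                "gene_id": g,
                "preset": name,
                "n_islands": len(islands),
                "best_oe": max((i.oe for i in islands), default=float("nan")),
                "best_gc": max((i.gc for i in islands), default=float("nan")),
                "has_cgi_consensus": consensus[g][0],
            })
    pd.DataFrame(cgi_rows).to_csv(out / "cgi_summary.tsv", sep="\t", index=False)
    n_with_cgi = {
        name: sum(1 for g in selected_ids if per_gene_islands[g][name])
        for name in cgi.PRESETS
    }
    n_consensus = sum(1 for g in selected_ids if consensus[g][0])
    log.info("CGI genes per preset %s; consensus (k=%d): %d",
             n_with_cgi, config.consensus_k, n_consensus)

    # --- partner-TF scanning ----------------------------------------------
    pwms = (
        tfbs.load_pwms(config.pwm_library)
        if config.pwm_library
        else tfbs.default_pwm_library()
    )
    panel = tfbs.load_panel(config.panel) if config.panel else tfbs.default_panel()
    presence = tfbs.tf_presence_matrix(
        sel_records, pwms, panel,
        region=config.scan_region, min_rel_score=config.min_rel_score,
    )
    freq = tfbs.tf_gene_frequency(presence)
    tfbs.ranked_tf_table(freq).to_csv(out / "tf_frequency.tsv", sep="\t", index=False)
    hit_rows = []
    resolved = tfbs.resolve_panel_pwms(pwms, panel)
    for rec in sel_records:
        sub = sio.extract_relative_region(rec, *config.scan_region)
        for tf, tf_pwms in resolved.items():
            for pwm in tf_pwms:
                for h in tfbs.scan_pwm(sub, pwm, config.min_rel_score, rec.gene_id):
                    hit_rows.append({
                        "gene_id": h.gene_id, "tf": tf, "start": h.start,
                        "strand": h.strand,
                        "score_bits": round(h.score_bits, 6),
                        "rel_score": round(h.rel_score, 6),
                    })
    pd.DataFrame(
        hit_rows, columns=["gene_id", "tf", "start", "strand", "score_bits", "rel_score"]
    ).to_csv(out / "tfbs_hits.tsv", sep="\t", index=False)
    log.info("TFBS scan: %d hits, %d/%d panel TFs with >= 1 gene",
             len(hit_rows), int((freq > 0).sum()), len(freq))

    # --- motif enrichment over the CGI-positive regulatory regions ---------
    cgi_gene_ids = [g for g in selected_ids if consensus[g][0]]
    positives = [
        motifs.extract_functional_regions(by_id[g], consensus[g][1]).rr
        for g in cgi_gene_ids
    ]
    candidates = (
        motifs.kmer_enrichment(
            positives, config.k_min, config.k_max,
            n_shuffles_per_seq=config.n_shuffles, seed=config.seed,
        )
        if positives
        else []
    )
    cand_df = pd.DataFrame(
        [
            {
                "word": m.word, "k": m.k,
                "n_pos_with": m.n_pos_with, "n_pos_without": m.n_pos_without,
                "n_bg_with": m.n_bg_with, "n_bg_without": m.n_bg_without,
                "p_value": m.p_value, "e_value": m.e_value,
                "prevalence": m.prevalence,
            }
            for m in candidates
        ],
        columns=["word", "k", "n_pos_with", "n_pos_without", "n_bg_with",
                 "n_bg_without", "p_value", "e_value", "prevalence"],
    )
    # %.17g keeps the float columns round-trip exact for report rebuilding
    cand_df.to_csv(out / "motifs.tsv", sep="\t", index=False, float_format="%.17g")
    motifs.write_meme_minimal(candidates[:10], out / "motifs.meme")
    top_word = candidates[0].word if candidates else None
    log.info("motif enrichment: %d candidates; top %s", len(candidates), top_word)

    motif_present = {g: False for g in selected_ids}
    if top_word:
        for g in selected_ids:
            rr = motifs.extract_functional_regions(by_id[g], consensus[g][1]).rr
            motif_present[g] = motifs.motif_prevalence(top_word, [rr]) > 0

    # --- annotation + designation ------------------------------------------
    z_by_id = {r.gene_id: r.z_magnitude for r in expr}
    sel_set = set(selected_ids)
    annotations = []
    for r in expr:
        g = r.gene_id
        if g not in by_id:
            continue
        ann = gcls.GeneAnnotation(
            gene_id=g,
            z_magnitude=z_by_id[g],
            selected=g in sel_set,
            has_cgi={
                name: bool(per_gene_islands[g][name]) if g in per_gene_islands else False
                for name in cgi.PRESETS
            },
            has_cgi_consensus=consensus[g][0] if g in consensus else False,
            n_partner_tfs_with_site=(
                int(presence.loc[g].sum()) if g in presence.index else 0
            ),
            motif_present=motif_present.get(g, False),
            cpg_class=cgi.classify_promoter_cpg_class(by_id[g]),
        )
        annotations.append(ann)
    gcls.designate_pdown3b(annotations, require_motif=config.require_motif)
    ann_df = pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "z_magnitude": round(a.z_magnitude, 4),
                "selected": a.selected,
                **{f"has_cgi_{p}": a.has_cgi[p] for p in cgi.PRESETS},
                "has_cgi_consensus": a.has_cgi_consensus,
                "n_partner_tfs_with_site": a.n_partner_tfs_with_site,
                "motif_present": a.motif_present,
                "pdown3b": a.pdown3b,
                "cpg_class": a.cpg_class,
            }
            for a in annotations
        ]
    )
    ann_df.to_csv(out / "annotations.tsv", sep="\t", index=False)
    n_pdown3b = int(ann_df["pdown3b"].sum())
    log.info("designated %d P-down-3B genes", n_pdown3b)

    # --- optional peak overlap ----------------------------------------------
    peak_summary = None
    if config.peaks:
        peaks = sio.read_bed(config.peaks)
        tss = {
            r.gene_id: (r.gene_id, r.tss_index) for r in sel_records
        }
        has_cgi_map = {g: consensus[g][0] for g in selected_ids}
        dist_df, peak_summary = gcls.peak_gene_overlap(
            peaks, tss, max_dist=config.max_peak_dist, has_cgi=has_cgi_map
        )
        dist_df.to_csv(out / "peak_distances.tsv", sep="\t")
        _dump_json(peak_summary, out / "peak_summary.json")
        log.info("peak overlap: %s", peak_summary)

    report = {
        "config": dataclasses.asdict(config),
        "n_input": len(annotations),
        "n_selected": len(selected_ids),
        "n_with_cgi": n_with_cgi,
        "n_with_cgi_consensus": n_consensus,
        "tf_gene_frequency": {tf: int(v) for tf, v in freq.items()},
        "n_panel_tfs_with_sites": int((freq > 0).sum()),
        "top_motifs": [
            {
                "word": m.word, "p_value": m.p_value, "e_value": m.e_value,
                "prevalence": m.prevalence,
            }
            for m in candidates[:10]
        ],
        "n_pdown3b": n_pdown3b,
        "peak_overlap": peak_summary,
    }
    _dump_json(dataclasses.asdict(config), out / "config.json")
    _dump_json(report, out / "report.json")
    return report


def rebuild_report(out_dir) -> dict:
    """Re-derive report.json from the stage artifacts alone (bit-exact)."""
    out = Path(out_dir)
    with open(out / "config.json") as fh:
        config = json.load(fh)
    ann = pd.read_csv(out / "annotations.tsv", sep="\t")
    freq_df = pd.read_csv(out / "tf_frequency.tsv", sep="\t")
    cand = pd.read_csv(out / "motifs.tsv", sep="\t", float_precision="round_trip")
    preset_names = [c[len("has_cgi_"):] for c in ann.columns
                    if c.startswith("has_cgi_") and c != "has_cgi_consensus"]
    peak_summary = None
    if (out / "peak_summary.json").exists():
        with open(out / "peak_summary.json") as fh:
            peak_summary = json.load(fh)
    # panel order is preserved by re-reading the panel file
    panel = (
        tfbs.load_panel(config["panel"]) if config.get("panel") else tfbs.default_panel()
    )
    freq = {tf: 0 for tf in panel.tf_names}
    freq.update({row["tf"]: int(row["n_genes"]) for _, row in freq_df.iterrows()})
    report = {
        "config": config,
        "n_input": int(len(ann)),
        "n_selected": int(ann["selected"].sum()),
        "n_with_cgi": {p: int(ann[ann["selected"]][f"has_cgi_{p}"].sum())
                       for p in preset_names},
        "n_with_cgi_consensus": int(ann[ann["selected"]]["has_cgi_consensus"].sum()),
        "tf_gene_frequency": freq,
        "n_panel_tfs_with_sites": int(sum(1 for v in freq.values() if v > 0)),
        "top_motifs": [
            {
                "word": row["word"], "p_value": float(row["p_value"]),
                "e_value": float(row["e_value"]),
                "prevalence": float(row["prevalence"]),
            }
            for _, row in cand.head(10).iterrows()
        ],
        "n_pdown3b": int(ann["pdown3b"].sum()),
        "peak_overlap": peak_summary,
    }
    _dump_json(report, out / "report.json")
    return report
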