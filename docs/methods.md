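# Methods

`cisvelem` reimplements, as a tested library, a promoter *cis*-element
screen for genes downregulated under DNMT3B overexpression: CpG-island
(CGI) detection under three literature presets, position-weight-matrix
(PWM) scanning against a panel of transcription factors reported to
interact physically with DNMT3B, discriminative short-motif elicitation
over TSS-relative functional regions, and the final "P-down-3B"
designation (downregulated ∧ consensus CGI ∧ ≥ 1 partner-TF site).
Because the original inputs (EPD promoter exports, the microarray gene
list, proprietary TRANSFAC-derived matrices, ChIP-seq peak calls) are
not redistributable, every stage is exercised end-to-end on a seeded
synthetic cohort with planted ground truth.

## Coordinates and inputs

Promoters are TSS-anchored sense-strand windows, by default −2000..+1000
(3001 nt, TSS at internal index 2000). Internally all coordinates are
0-based half-open; TSS-relative position *p* maps to index
*p* − `rel_start`. Expression input is a TSV of per-gene microarray z
statistics; because published tables report downregulation with either
sign convention, z is normalized to absolute magnitude at parse time and
selection keeps 2.0 ≤ |z| ≤ 6.8 (inclusive). BED I/O is 0-based
half-open and round-trips coordinates bit-exactly.

## CpG-island detection

Island statistics are the classic GC fraction and observed/expected CpG
ratio O/E = N<sub>CpG</sub> · L / (N<sub>C</sub> · N<sub>G</sub>), with
N treated as missing (excluded from L and from dinucleotide counts).

The scanner slides a window of the preset width at step 1; a position
qualifies when its window meets the preset GC and O/E thresholds
(windows with > 10 % N never qualify). The union of qualifying windows
is merged into candidate regions; a region whose whole span fails the
criteria is trimmed 1 nt alternately from the 3′ then 5′ end,
re-evaluating after each trim, until it qualifies or falls below the
preset's minimum length. This is a deterministic, brute-force-checkable
uniform approximation of the Takai–Jones shrink procedure. Presets:

| preset | window | min length | min GC | min O/E |
|--------|--------|-----------|--------|---------|
| GGF    | 200    | 200       | 0.50   | 0.60    |
| TJ     | 200    | 500       | 0.55   | 0.65    |
| PM     | 500    | 500       | 0.50   | 0.60    |

Numerical choice: the whole-span GC test during trim is strict (>)
rather than inclusive. The downstream island acceptance filter — length
strictly > 300 nt, GC strictly > 50 %, O/E ≥ 0.6, recomputed on the
span — is strict on GC, and an inclusive trim bound makes the trim stop
exactly on the 0.50 boundary for background-diluted spans, which the
filter would then discard systematically. With the strict span bound
the scanner and filter compose coherently. Window qualification remains
inclusive (≥).

The consensus call requires at least *k* presets (default 2, i.e.
majority) to each report ≥ 1 filtered island; consensus island
intervals are the merged union of islands supported by ≥ *k* presets
under ≥ 50 % reciprocal overlap. Promoter CpG class uses Weber-style
500-nt windows: HCP if any window has GC ≥ 0.55 and O/E ≥ 0.75, LCP if
no window reaches O/E 0.48, ICP otherwise.

## TFBS scanning

Matrices are JASPAR PFM counts converted to probabilities with a
0.01-per-cell pseudocount, scanned as log2-odds against a uniform
background on both strands. A hit's relative score rescales the raw
score to [0, 1] between the matrix's worst and best word; the default
threshold is 0.80, making thresholds comparable across widths. Windows
containing N are skipped. The shipped partner panel lists the 17 named
DNMT3B-interacting TFs (an 18th partner with sites is reported but
unnamed in the source screen, so it is deliberately not guessed); the
panel file is user-editable and names are matched case-insensitively
with a small synonym map. The bundled matrix library
(`data/panel_pwms_synthetic.pfm`) is **synthetic** — consensus-derived
count matrices built for these 17 TFs from field-standard core motifs —
because the matrices used by the original TRANSFAC-based tool are
proprietary; users with a JASPAR export should point the pipeline at it.

## Motif elicitation

Rather than an EM motif model, enrichment is computed over exact words:
for each k-mer (k = 6..8 by default, both strands collapsed onto the
lexicographically smaller of word/reverse-complement) present in ≥ 2
positive sequences, a sequence-level (zero-or-one occurrence) 2×2 table
is built against a background of dinucleotide-preserving Euler-path
shuffles of the positives (Altschul–Erikson; one shuffle per sequence
by default), scored with the one-sided hypergeometric tail, and
corrected with a Bonferroni-style E-value (p × number of distinct words
tested across all k; threshold 0.05). Sequence-level counting matches
the "present in ≥ 80 % of genes" prevalence semantics, and exact-word
statistics make every p-value reproducible by direct combinatorial
evaluation. Prevalence of any word (IUPAC codes allowed) is the
fraction of sequences containing at least one match on either strand.
The three scanned functional regions are the full regulatory region
(−2000..+1000), the concatenated consensus-island spans, and the close
promoter (−400..+100).

## Designation and peak overlap

P-down-3B = selected ∧ consensus CGI ∧ ≥ 1 partner-TF site. Motif
presence is reported alongside but is not a gating condition (a flag
can require it), matching the definition's wording. Peak overlap
reports each gene's minimum TSS-to-peak distance (0 inside a peak) and
counts genes within a configurable distance (default 5000 nt, the
"near" radius being unstated in the source), stratified by CGI status.

## Synthetic cohort generator

The generator emulates the screen's composition: 252 genes, 3001-nt
promoters, 146/252 (≈ 0.579) with islands, z drawn uniformly from
2.0–6.8 for every gene (the cohort is by construction the selected
set). Backgrounds are order-1 Markov chains — not i.i.d., so the
dinucleotide-preserving shuffle null in motif analysis is fair — with
stationary GC 0.41 and expected CpG O/E 0.25 (bulk-genome-like
depletion); the C→G transition is pinned to `oe_factor · π(G)` and the
remaining transition mass adjusted by fixed point so both moments hold.

Islands are order-1 Markov segments targeting GC 0.60 / O/E 1.0,
350–800 nt, placed to overlap the TSS. A draw is accepted only if the
realized span has GC > 0.50 *and within 0.03 of target* and O/E ≥ 0.75;
otherwise it is redrawn. The margins keep detector acceptance away from
the 0.50/0.60 thresholds, and the target tolerance makes the emitted
island match its model — without it, occasional low-GC realizations of
short islands sit exactly on the knife edge of the 500-nt-window preset.

Partner-TF sites are planted as PWM consensus words (SP1 in 100 %,
EGR-1 in 80 %, MYC in 60 % of island genes by default; either strand),
and a common 8-mer (default `GTTCGGCA`, carrying the TpCpGpG core
reported as a de novo methylation preference) in 80 % of island genes.
Planted features keep a 20-nt spacing buffer from each other — adjacent
planted words can otherwise juxtapose into unintended composite sites —
and are placed outside the island span so island composition stays
exactly as drawn. After planting, the generator *scrubs* chance matches
of the planted TFs' matrices from every gene (greedy anti-consensus
single-base edits outside planted features, re-verifying island margins
after each edit): at relative score 0.80 an 8-mer matrix produces ~1–2
chance hits per 3-kb promoter, which would otherwise contaminate the
planted frequency table. Ground-truth site guarantees therefore apply
to the planted TFs; non-planted panel TFs show natural chance-hit
frequencies. All randomness flows from the single mandatory seed; equal
spec + seed gives byte-identical outputs.

What the generator does **not** emulate: real promoter sequence
(repeats, TATA/Inr elements, isochore structure), correlated TF-site
co-occurrence, degenerate (non-consensus) binding sites, methylation
levels, or expression noise. Passing recovery tests therefore shows the
detectors are correct and calibrated on signals at the stated margins —
not that they would achieve the same operating point on genomic data.

## Problem sizes and determinism

Default analyses run at the study scale the cohort defines: 252
promoters × 3001 nt, three island presets, 17 PWMs on both strands,
k = 6–8 enrichment over ~146 positives with one shuffle each — a few
seconds on one core. Test-suite oracle comparisons use 200 sequences
per island preset and 100 random sequence/PWM pairs. The pipeline is
deterministic given its config seed; reports contain no timestamps and
can be rebuilt bit-exactly from the on-disk stage artifacts.

## Known limitations

- The scanner is a uniform sliding-window approximation; it does not
  reproduce the cited tools' exact outputs (notably the probabilistic
  Ponger–Mouchiroud model, represented here by its island definition).
- The published screen's headline counts depend on inputs that are not
  redistributable; this package reproduces the *procedure* and verifies
  it on planted truth, not the published gene list.
- Exact-word enrichment finds ungapped, fixed-length motifs only; no EM
  refinement, gaps, or variable-width models.
- With consensus-planted sites the TFBS sensitivity criterion is
  insensitive to the scoring threshold; degenerate-site recovery can be
  probed with `plant_sites(..., sample=True)` but has no calibrated
  guarantee.
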