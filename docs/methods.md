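# Methods

## The gene activity model

The package scores gene activity from single-cell chromatin accessibility
under one central assumption: *promoter accessibility is a necessary
condition for transcription*. Accessibility of a gene's promoter gates its
entry into the matrix (the golden rule), while accessibility of connected
distal enhancers and of exonic sequence refine the score. Accessibility is
treated as binary per peak and cell; all quantitative structure comes from
the genomic model and the co-accessibility scores, not from read counts.

### Genomic model

Genes are reduced to: a body interval, a strand, a merged exon set, a
2-base TSS region at the transcription start, and a promoter window (the
body enlarged by `upstream_bp` bases upstream of the TSS). Only
protein-coding genes are kept, because the matrix is meant to be comparable
with transcript-level expression; pseudogenes, miRNA and lncRNA records are
dropped at load time. One promoter per gene: all transcripts are collapsed
to a single merged exon list, and alternative promoters/isoforms are out of
scope. Regulatory tracks contribute intervals labeled `promoter` or
`enhancer_distal`; anything else (CTCF-only, proximal-enhancer signatures,
unknown labels) maps to `other` and is ignored by labeling — proximal
enhancers can be opted in through the track `label_map`.

All internal coordinates are 0-based half-open (BED convention); GTF input
is converted on read.

### Peak labeling

Each peak takes exactly one label, in strict precedence:

1. `prom` — a promoter region lies inside the peak, **or** the peak covers
   some gene's 2-base TSS;
2. `enhD` — a distal-enhancer region lies inside the peak;
3. `exon` — the peak lies inside an exon;
4. `empty` — otherwise.

The default overlap semantics are containment as written above (signature
region inside peak; peak inside exon), with `any_overlap` available as a
relaxed mode. The TSS clause is necessarily "peak covers TSS": a peak can
never fit inside a 2-base interval. The precedence makes `prom` absorb
peaks that also carry enhancer signatures, and `enhD` absorb
enhancer-in-intron/exon cases, so regulatory information is never shadowed
by positional overlap with the gene body.

The TSS rule serves two purposes beyond the track signatures: it rescues
genes that have no predicted promoter signature near their TSS, and it
disambiguates shared promoter signatures between divergent gene pairs —
a promoter peak covering one gene's TSS is associated to that gene alone,
regardless of how much of the neighboring gene's window it overlaps.

### Association maps and components

- `GP` (genes × promoter peaks, binary): a prom peak covering one or more
  TSSs associates to exactly those genes; a prom peak covering none
  associates to every gene whose promoter window it intersects (multi-gene
  association is allowed and logged). Genes with an empty `GP` row are
  removed everywhere.
- `PE` (promoter peaks × enhancer peaks): co-accessibility scores of
  connections that survive filtering — endpoints labeled {prom, enhD},
  score ≥ `cam`, center distance ≤ `d_th`.
- `GI` (genes × exon peaks): `exp(−d/decay_scale)` where `d` is the
  distance of the peak center to the gene's transcription-start
  coordinate. The TSS point is the body start (plus strand) or body end
  (minus strand); the decay prevents long, exon-rich genes from dominating.

Components: `P = binarize(GP × D_prom)`, `C = GP × PE × D_enh`,
`E = GI × D_exon`; `GAGAM = wp·P + wc·C + we·E` with binary weights. `P`
is clipped to {0,1} because a gene with several accessible promoter peaks
is still simply "active"; `binarize_promoter=False` keeps raw counts. The
two standard presets are `(1,1,1)` and `(1,1,0)`.

### Co-accessibility

Co-accessibility is normally computed by an external pipeline; the CSV
reader (`Peak1,Peak2,coaccess`, both `chr1_100_600` and `chr1:100-600`
id dialects) is the faithful interoperability path. The built-in
estimator is a deliberately simple surrogate — Pearson correlation of
binary accessibility vectors for same-chromosome peak pairs within
`coaccess_window_bp` — suitable for desk-scale data and testing; it is
*not* a graphical-lasso co-accessibility model and makes no distance
penalty or network inference claims.

`cam` is derived from the data as the mean of the strictly positive
scores. Scores ≤ 0 are treated as non-connections; setting
`cam_include_negatives=True` restores the literal "mean of non-zero
scores" reading. `cam` is computed on the full connection list before the
promoter–enhancer restriction.

### Normalization

Per-cell size-factor normalization (`cell_total`): each column is divided
by its total and rescaled by the median of the nonzero column totals, so
all nonzero cells carry equal total activity; all-zero cells stay zero.
`log_cell_total` additionally applies `log1p`; `none` disables. The median
is taken over nonzero totals so empty cells cannot drag the scale factor.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `upstream_bp` | 500 | bp | promoter-window extension upstream of the TSS (≈ mean peak length) |
| `tss_width` | 2 | bp | width of the TSS region |
| `decay_scale` | 5000 | bp | exon-weight decay scale; weight = e^(−d/scale) |
| `d_th` | 30000 | bp | maximum promoter–enhancer connection distance |
| `weights` | (1,1,1) | — | binary selection of P/C/E contributions |
| `overlap_mode` | literal_containment | — | labeling overlap semantics |
| `strand_aware` | true | — | transcription-directional TSS and upstream extension |
| `coaccess_window_bp` | 500000 | bp | pair window of the surrogate estimator |

`strand_aware=False` reproduces the strand-blind formulas (TSS at
`[start, start+tss_width)`, upstream always before `start`) for
comparability with annotation-agnostic conventions.

## Synthetic data

`make_toy_genome` lays out alternating-strand genes with disjoint 10 kb
bodies every 40 kb on one synthetic chromosome, two exons per gene, a
promoter signature 100–300 bp upstream of each TSS, and enhancers 5–25 kb
from the TSS (inside the 30 kb connection window). `simulate_peak_matrix`
places one 400 bp peak centered on every promoter/enhancer/exon region —
regions narrower than peaks and exon peaks narrower than exons, so the
literal containment mode is satisfiable by construction. Each cell type
opens its marker genes' peaks with probability `p_open_active` (default
0.8) against a background of `p_noise` (default 0.05); housekeeping genes
open in all cells; marker prom–enhancer pairs become truth connections
with scores uniform in [0.3, 0.9]. Default study conditions: 60 genes,
3 cell types × 200 cells, 10 markers per type.

What the simulation does **not** emulate: fragment-level counts, read
depth variation, doublets, batch effects, peak-calling noise, overlapping
genes, or realistic co-accessibility structure (scores are planted, not
estimated from a latent network). Passing recovery tests therefore shows
the pipeline is correct and sensitive under clean planted structure, not
that it is robust to every artifact of real scATAC-seq data.

Note one interaction of defaults: because truth-connection scores are
uniform and `cam` is their mean, a marker gene whose connections all fall
below the mean receives no co-accessibility contribution — by design of
the threshold, not a defect; such genes are still scored through P and E.

## Numerical and design choices

- Degenerate inputs: peaks open in zero or all cells have undefined
  correlation and are skipped by the surrogate estimator (counted);
  all-zero cells stay zero through normalization; an all-zero matrix is
  rejected by the LSI embedding; a dataset in which no gene has a promoter
  peak fails loudly (golden rule).
- Ties in differential-activity ranking break on the Wilcoxon rank-sum
  p-value, then gene id, for determinism. Constant genes keep p = 1 and
  effect 0. Wilcoxon one-vs-rest is a pragmatic field-standard choice, as
  is the Mann–Whitney U test between marker and housekeeping Gini samples
  for the RAGI p-value (`test="welch"` switches to a Welch t-test).
- RAGI uses *mean* activity per cluster per gene, then the Gini index over
  cluster means; Gini of an all-zero vector is 0 by convention.
- TF-IDF: term frequency per cell × `log(1 + n_cells/df)`; first SVD
  component dropped by default (depth-correlated). The embedding is
  transductive — components are fit on the matrix being embedded.
- k-means (`n_init=10`) and Leiden are seeded; all simulation randomness
  flows from one `numpy` generator seeded in the config.
- Test/acceptance problem sizes: micro-fixtures are ≤10 genes × ≤30 peaks
  × ≤10 cells so a per-base brute-force oracle stays exact and cheap; the
  recovery experiment uses the default 60-gene/600-cell simulation.

## Known limitations

- The built-in co-accessibility estimator is a correlation surrogate;
  quantitative agreement with graphical-lasso pipelines is not expected.
- Assembly conversion (liftover) is out of scope: peaks and annotations
  must share one assembly.
- One promoter per gene; no isoform- or alternative-promoter-level
  activity.
- The `prom`-by-TSS clause requires full coverage of the 2-base TSS; a
  peak ending inside the TSS (1 bp difference) is not rescued.
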