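# gagam

Genomic-annotated gene activity matrices from scATAC-seq peak accessibility.

scATAC-seq summarizes single-cell chromatin accessibility as a binary
peak-by-cell matrix `D`, but peaks are experiment-specific intervals that
cannot be compared across datasets or against gene expression. This package
converts `D` into a **gene activity matrix** — genes × cells, like an
expression matrix — by first *functionally labeling* every peak against a
genomic model (gene bodies, exons, TSS, and ENCODE cCRE-style
promoter/distal-enhancer tracks) and then combining three interpretable
contributions per gene:

```
GAGAM = wp·P + wc·C + we·E        (wp, wc, we ∈ {0, 1})
```

- **P = GP × D_prom** (binarized) — promoter accessibility. `GP` associates
  each gene with its promoter peaks: peaks carrying a promoter signature or
  covering a gene's TSS. The *golden rule*: a gene enters the matrix only
  if it has at least one promoter peak.
- **C = GP × PE × D_enh** — promoter–enhancer co-accessibility. `PE` holds
  co-accessibility scores `ca` of promoter–enhancer peak pairs that survive
  two filters: `ca ≥ cam` (the mean of the dataset's positive scores) and
  center distance `d ≤ 30 kb`.
- **E = GI × D_exon** — exon accessibility, weighted by `exp(−d/5000)` of
  the peak-center-to-TSS distance so long genes are not over-represented.

Each peak gets exactly one label with strict precedence
`prom > enhD > exon > empty`; the default weight presets are `(1,1,1)` and
`(1,1,0)` (with/without the exon term). Columns are finally size-factor
normalized to the median per-cell total. A validation toolkit (TF-IDF/LSI
embedding, k-means/Leiden clustering, ARI/AMI, RAGI, differential-activity
ranking) and a planted-structure synthetic data generator make the whole
pipeline testable without downloads.

Intended users: bioinformaticians analyzing scATAC-seq or multiome data who
want gene-level, regulation-aware activity scores instead of raw peaks.

## Worked example

Simulate a small dataset with 3 planted cell types, build the matrix, and
evaluate the clustering:

```sh
gagam simulate --outdir ds --n-genes 12 --cells-per-type 30 \
    --marker-genes-per-type 3 --seed 1
gagam label --peaks ds/peaks.bed --genes ds/genes.gtf \
    --ccres ds/regions.bed --out labeled.bed
gagam build --matrix ds/matrix.mtx --peaks ds/peaks.bed \
    --barcodes ds/barcodes.tsv --genes ds/genes.gtf --ccres ds/regions.bed \
    --connections ds/connections.csv --out gam
gagam eval --gam gam --k 3 --truth ds/truth_labels.tsv \
    --markers ds/markers.txt --housekeeping ds/housekeeping.txt \
    --seed 1 --out metrics.json
```

which prints:

```
prom	12
enhD	24
exon	24
empty	0
total	60
wrote 12 genes x 90 cells to gam
{"ami": 1.0, "ari": 1.0, "n_clusters": 3, "ragi": 0.5459449875175746, "ragi_p": 0.00909090909090909}
```

The label summary shows one promoter, two enhancer and two exon peaks per
gene, as planted. ARI/AMI of 1.0 mean the LSI + k-means clustering of the
activity matrix recovers the planted cell types exactly; the positive RAGI
(mean Gini of marker-gene cluster profiles minus mean Gini of housekeeping
genes, here 0.55 with p < 0.05) means marker activity concentrates in
specific clusters while housekeeping activity is flat — the clustering is
biologically informative.

The same pipeline is available as a library, including scikit-learn style
estimators:

```python
import gagam

ds = gagam.simulate()  # default: 3 types x 200 cells, 60 genes
scorer = gagam.GeneActivityScorer(
    annotation=ds.annotation, peak_ids=ds.D.peak_ids,
    connections=ds.truth_connections,
)
activity = scorer.fit_transform(ds.D.matrix.T.toarray())  # cells x genes
emb = gagam.LSIEmbedder(n_components=30, random_state=1).fit_transform(activity)
```

## Layout

- `src/gagam/genome.py` — genomic model, GTF/BED12/BED track loaders
- `src/gagam/labeling.py` — four-way peak labeling with precedence
- `src/gagam/coaccess.py` — connections reader, windowed-correlation
  surrogate estimator, `cam`/distance filtering
- `src/gagam/gam.py` — GP/PE/GI association maps, P/C/E components,
  combination, normalization
- `src/gagam/pipeline.py`, `src/gagam/estimators.py` — end-to-end builder
  and sklearn-style transformers
- `src/gagam/evaluation.py` — LSI, clustering, ARI/AMI/RAGI, differential
  activity
- `src/gagam/synthetic.py` — toy genomes, planted simulations, the worked
  example
- `docs/methods.md` — model assumptions, parameter meanings, numerical
  choices and limitations
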