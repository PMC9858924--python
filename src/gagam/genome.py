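"""Genomic model: genes, exons, TSS, promoter windows and regulatory tracks.

The gene activity model works on a small set of genomic features per gene:
the gene body, the merged exon set, a short transcription start site (TSS)
region, and a promoter window extending a fixed number of bases upstream of
the TSS.  Regulatory regions (ENCODE cCRE-style promoter / distal-enhancer
tracks) are loaded as labeled intervals.  All coordinates are internally
0-based half-open (BED convention); GTF input (1-based inclusive) is
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)

#: track labels recognised by default; ENCODE ships both UCSC display labels
#: (prom, enhD) and registry labels (PLS, dELS).
DEFAULT_LABEL_MAP = {
    "prom": "promoter",
    "PLS": "promoter",
    "enhD": "enhancer_distal",
    "dELS": "enhancer_distal",
}

REGION_LABELS = ("promoter", "enhancer_distal", "other")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and other.start >= self.start
            and other.end <= self.end
        )

    def intersects(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and other.start < self.end
            and self.start < other.end
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    name: str
    body: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for e in self.exons:
            if not self.body.contains(e):
                raise ValueError(
                    f"exon {e} of gene {self.gene_id} outside body {self.body}"
                )


@dataclass(frozen=True)
class RegulatoryRegion:
    region: GenomicInterval
    label: str

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")


@dataclass
class GenomeAnnotation:
    """Container for the gene set G and regulatory region set R."""

    genes: list[Gene]
    regions: list[RegulatoryRegion] = field(default_factory=list)
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_ids in annotation")
        if not self.chrom_order:
            seen: list[str] = []
            for g in self.genes:
                if g.body.chrom not in seen:
                    seen.append(g.body.chrom)
            for r in self.regions:
                if r.region.chrom not in seen:
                    seen.append(r.region.chrom)
            self.chrom_order = seen

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# TSS / promoter-window derivation


def derive_tss(gene: Gene, tss_width: int = 2, strand_aware: bool = True) -> GenomicInterval:
    """The short TSS region at the transcription start of the gene body.

    By default this is the first two bases of the gene in transcription
    order: ``[start, start+2)`` on the plus strand, ``[end-2, end)`` on the
    minus strand.  With ``strand_aware=False`` the literal strand-blind
    definition ``[start, start+tss_width)`` is used for both strands.
    """
    b = gene.body
    w = min(tss_width, b.length)
    if strand_aware and gene.strand == "-":
        return GenomicInterval(b.chrom, b.end - w, b.end)
    return GenomicInterval(b.chrom, b.start, b.start + w)


def tss_position(gene: Gene, strand_aware: bool = True) -> int:
    """The single transcription-start coordinate used for distance weighting."""
    if strand_aware and gene.strand == "-":
        return gene.body.end
    return gene.body.start


def derive_promoter_window(
    gene: Gene, upstream_bp: int = 500, strand_aware: bool = True
) -> GenomicInterval:
    """Gene body enlarged by ``upstream_bp`` bases upstream of the TSS.

    Upstream is transcription-directional: before ``start`` on the plus
    strand, after ``end`` on the minus strand (clipped at zero).  With
    ``strand_aware=False`` the extension is always before ``start``.
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    b = gene.body
    if strand_aware and gene.strand == "-":
        return GenomicInterval(b.chrom, b.start, b.end + upstream_bp)
    return GenomicInterval(b.chrom, max(0, b.start - upstream_bp), b.end)


# ---------------------------------------------------------------------------
# Interval utilities


def merge_intervals(intervals) -> tuple[GenomicInterval, ...]:
    """Union of possibly-overlapping intervals, sorted, per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return tuple(merged)


# ---------------------------------------------------------------------------
# Loaders


def load_gene_annotation(
    path,
    format: str = "gtf",
    biotype_whitelist: set[str] | None = None,
) -> list[Gene]:
    """Load genes from a GTF or BED12 file, keeping whitelisted biotypes only.

    All transcripts of a gene are collapsed to a single merged, non-overlapping
    exon list (one promoter per gene; isoform structure is not modelled).
    Genes without exons are skipped with a warning.
    """
    if biotype_whitelist is None:
        biotype_whitelist = {"protein_coding"}
    if format == "gtf":
        genes = _load_gtf(path)
    elif format == "bed12":
        genes = _load_bed12(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    kept = [g for g in genes if g.biotype in biotype_whitelist]
    dropped = len(genes) - len(kept)
    if dropped:
        log.info("dropped %d genes outside biotype whitelist", dropped)
    return kept


def _load_gtf(path) -> list[Gene]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # malformed record
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc

    def attr(feat, *names, default=""):
        for n in names:
            if n in feat.attributes:
                return feat.attributes[n][0]
        return default

    genes: list[Gene] = []
    skipped_no_exons = 0
    gene_feats = list(db.features_of_type("gene"))
    if gene_feats:
        for gf in gene_feats:
            gid = attr(gf, "gene_id", default=gf.id)
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end)
                for e in db.children(gf, featuretype="exon")
            ]
            if not exons:
                skipped_no_exons += 1
                continue
            genes.append(
                Gene(
                    gene_id=gid,
                    name=attr(gf, "gene_name", default=gid),
                    body=GenomicInterval(gf.seqid, gf.start - 1, gf.end),
                    strand=gf.strand if gf.strand in "+-" else "+",
                    exons=merge_intervals(exons),
                    biotype=attr(gf, "gene_biotype", "gene_type", default=""),
                )
            )
    else:
        # no explicit gene features: group exons by gene_id
        by_gene: dict[str, list] = {}
        for e in db.features_of_type("exon"):
            by_gene.setdefault(attr(e, "gene_id", default=e.id), []).append(e)
        for gid, exon_feats in by_gene.items():
            exons = [GenomicInterval(e.seqid, e.start - 1, e.end) for e in exon_feats]
            e0 = exon_feats[0]
            body = GenomicInterval(
                e0.seqid, min(i.start for i in exons), max(i.end for i in exons)
            )
            genes.append(
                Gene(
                    gene_id=gid,
                    name=attr(e0, "gene_name", default=gid),
                    body=body,
                    strand=e0.strand if e0.strand in "+-" else "+",
                    exons=merge_intervals(exons),
                    biotype=attr(e0, "gene_biotype", "gene_type", default=""),
                )
            )
    if skipped_no_exons:
        log.warning("skipped %d genes with zero exons", skipped_no_exons)
    return genes


def _load_bed12(path) -> list[Gene]:
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12 record: {exc}") from exc
            if not (len(sizes) == len(starts) == n_blocks):
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            body = GenomicInterval(chrom, start, end)
            exons = tuple(
                GenomicInterval(chrom, start + bs, start + bs + sz)
                for bs, sz in zip(starts, sizes)
            )
            genes.append(
                Gene(
                    gene_id=name,
                    name=name,
                    body=body,
                    strand=strand if strand in "+-" else "+",
                    exons=merge_intervals(exons),
                    biotype="protein_coding",
                )
            )
    return genes


def write_bed12(genes, path) -> None:
    """Write the collapsed gene model as BED12 for inspection / round-trips."""
    with open(path, "w") as fh:
        for g in genes:
            b = g.body
            sizes = ",".join(str(e.length) for e in g.exons)
            starts = ",".join(str(e.start - b.start) for e in g.exons)
            fh.write(
                "\t".join(
                    [
                        b.chrom,
                        str(b.start),
                        str(b.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(b.start),
                        str(b.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def load_regulatory_track(
    path,
    label_column: int = 9,
    label_map: dict[str, str] | None = None,
) -> list[RegulatoryRegion]:
    """Load a BED regulatory track whose ``label_column`` (0-based) carries a
    functional label; labels outside ``label_map`` become ``other``."""
    if label_map is None:
        label_map = dict(DEFAULT_LABEL_MAP)
    regions: list[RegulatoryRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if label_column >= len(f):
                raise ValueError(
                    f"{path}:{lineno}: label column {label_column} out of range"
                )
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates: {exc}") from exc
            raw = f[label_column]
            label = label_map.get(raw, "other")
            regions.append(RegulatoryRegion(iv, label))
    return regions


def write_regulatory_track(regions, path) -> None:
    with open(path, "w") as fh:
        inverse = {"promoter": "prom", "enhancer_distal": "enhD", "other": "other"}
        for i, r in enumerate(regions):
            iv = r.region
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        f"R{i}",
                        "0",
                        ".",
                        str(iv.start),
                        str(iv.end),
                        "0,0,0",
                        inverse[r.label],
                    ]
                )
                + "\n"
            )


def write_gtf(genes, path, source: str = "gagam") -> None:
    """Write genes as Ensembl-dialect GTF (gene / transcript / exon rows)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            b = g.body
            fh.write(
                f"{b.chrom}\t{source}\tgene\t{b.start + 1}\t{b.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            tattrs = attrs + f' transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{b.chrom}\t{source}\ttranscript\t{b.start + 1}\t{b.end}\t.\t{g.strand}\t.\t{tattrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
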