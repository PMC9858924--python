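"""Functional labeling of scATAC-seq peaks against the genomic model.

Each peak receives exactly one of four labels, in strict precedence:

``prom``
    a promoter-labeled regulatory region lies inside the peak, or the peak
    covers some gene's TSS region;
``enhD``
    a distal-enhancer region lies inside the peak (and no promoter does);
``exon``
    the peak lies inside an exon of some gene;
``empty``
    none of the above.

The default overlap semantics are literal containment (annotation region
inside peak; peak inside exon); ``any_overlap`` is a relaxed alternative.
The TSS clause always requires the peak to cover the full TSS region, since
a peak can never fit inside a 2-base interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .genome import Gene, GenomeAnnotation, GenomicInterval, derive_tss

log = logging.getLogger(__name__)

PEAK_LABELS = ("prom", "enhD", "exon", "empty")
OVERLAP_MODES = ("literal_containment", "any_overlap")


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    index: int

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


def parse_peak_id(peak_id: str) -> GenomicInterval:
    """Parse ``chr1:100-600`` or ``chr1_100_600`` into an interval."""
    s = peak_id.strip()
    try:
        if ":" in s:
            chrom, rest = s.rsplit(":", 1)
            start, end = rest.split("-")
        else:
            chrom, start, end = s.rsplit("_", 2)
        return GenomicInterval(chrom, int(start), int(end))
    except ValueError as exc:
        raise ValueError(f"unparseable peak id {peak_id!r}") from exc


def peaks_from_ids(peak_ids) -> list[Peak]:
    return [Peak(parse_peak_id(pid), i) for i, pid in enumerate(peak_ids)]


def peaks_from_bed(path) -> list[Peak]:
    """Read peaks from a BED3(+) file, preserving file order as matrix order."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates: {exc}") from exc
            peaks.append(Peak(iv, len(peaks)))
    return peaks


def overlaps(a: GenomicInterval, b: GenomicInterval, mode: str = "literal_containment") -> bool:
    """Whether *a* overlaps *b*: containment of a in b, or any shared base."""
    if mode == "literal_containment":
        return b.contains(a)
    if mode == "any_overlap":
        return a.intersects(b)
    raise ValueError(f"unknown overlap mode {mode!r}")


@dataclass
class LabeledPeakSet:
    """Peaks with their labels and, per peak, the set of covered TSS genes."""

    peaks: list[Peak]
    labels: list[str]
    tss_hits: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.peaks):
            raise ValueError("one label per peak required")
        for lab in self.labels:
            if lab not in PEAK_LABELS:
                raise ValueError(f"unknown peak label {lab!r}")
        if not self.tss_hits:
            self.tss_hits = [set() for _ in self.peaks]

    def peaks_with_label(self, label: str) -> list[Peak]:
        return [p for p, l in zip(self.peaks, self.labels) if l == label]

    def label_of(self, peak_id: str) -> str | None:
        if not hasattr(self, "_by_id"):
            self._by_id = {p.id: l for p, l in zip(self.peaks, self.labels)}
        return self._by_id.get(peak_id)

    def summary(self) -> dict[str, int]:
        counts = {lab: 0 for lab in PEAK_LABELS}
        for lab in self.labels:
            counts[lab] += 1
        counts["total"] = len(self.labels)
        return counts

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for p, lab, hits in zip(self.peaks, self.labels, self.tss_hits):
                iv = p.interval
                genes = ",".join(sorted(hits)) if hits else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\t{genes}\n")


def _region_tree(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def _hits(trees, peak: GenomicInterval, mode: str):
    """Payloads of tree intervals overlapping the peak under *mode*
    (region-inside-peak containment, or any overlap)."""
    tree = trees.get(peak.chrom)
    if tree is None:
        return []
    found = tree.overlap(peak.start, peak.end)
    if mode == "any_overlap":
        return [h.data for h in found]
    return [h.data for h in found if h.begin >= peak.start and h.end <= peak.end]


def label_peaks(
    peaks: list[Peak],
    annotation: GenomeAnnotation,
    mode: str = "literal_containment",
    tss_width: int = 2,
    strand_aware: bool = True,
) -> LabeledPeakSet:
    """Assign each peak its functional label with strict prom > enhD > exon
    precedence; records per peak which genes' TSS it covers."""
    if mode not in OVERLAP_MODES:
        raise ValueError(f"unknown overlap mode {mode!r}")
    if not annotation.genes and not annotation.regions:
        log.warning("empty annotation: labeling all %d peaks empty", len(peaks))

    prom_trees = _region_tree(
        (r.region, r.region) for r in annotation.regions if r.label == "promoter"
    )
    enh_trees = _region_tree(
        (r.region, r.region) for r in annotation.regions if r.label == "enhancer_distal"
    )
    tss_trees = _region_tree(
        (derive_tss(g, tss_width, strand_aware), g.gene_id) for g in annotation.genes
    )
    exon_trees = _region_tree(
        (e, g.gene_id) for g in annotation.genes for e in g.exons
    )

    labels: list[str] = []
    tss_hits: list[set[str]] = []
    for p in peaks:
        iv = p.interval
        # TSS clause: the peak must cover the full TSS region regardless of mode
        hits = set(_hits(tss_trees, iv, "literal_containment"))
        tss_hits.append(hits)
        if _hits(prom_trees, iv, mode) or hits:
            labels.append("prom")
        elif _hits(enh_trees, iv, mode):
            labels.append("enhD")
        elif _peak_in_exon(exon_trees, iv, mode):
            labels.append("exon")
        else:
            labels.append("empty")
    return LabeledPeakSet(peaks, labels, tss_hits)


def _peak_in_exon(exon_trees, peak: GenomicInterval, mode: str) -> bool:
    tree = exon_trees.get(peak.chrom)
    if tree is None:
        return False
    found = tree.overlap(peak.start, peak.end)
    if mode == "any_overlap":
        return bool(found)
    # literal: the peak must be contained in an exon
    return any(h.begin <= peak.start and h.end >= peak.end for h in found)


def exon_genes_of_peak(
    peak: Peak, genes: list[Gene], mode: str = "literal_containment"
) -> list[str]:
    """gene_ids whose exons the peak lies in (literal) / touches (relaxed)."""
    out = []
    for g in genes:
        for e in g.exons:
            ok = e.contains(peak.interval) if mode == "literal_containment" else e.intersects(peak.interval)
            if ok:
                out.append(g.gene_id)
                break
    return out


def label_summary(lps: LabeledPeakSet) -> dict[str, int]:
    """Counts per label plus total; counts always sum to the peak count."""
    return lps.summary()
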