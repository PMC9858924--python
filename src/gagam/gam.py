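"""Construction of the gene activity matrix from labeled peaks.

The activity of a gene is a weighted sum of three contributions computed
from the binary peak-by-cell matrix ``D``:

* ``P`` — promoter accessibility.  A binary gene-to-promoter-peak map ``GP``
  (the *golden rule*: a gene enters the matrix only if it has at least one
  promoter peak) is multiplied with the promoter rows of ``D`` and
  binarized.
* ``C`` — promoter–enhancer co-accessibility.  ``GP`` is chained through the
  score-valued promoter-to-enhancer map ``PE`` (filtered connections) and
  the enhancer rows of ``D``.
* ``E`` — exon accessibility, weighted by an exponential decay
  ``exp(-d/scale)`` of the peak-center-to-TSS distance so long genes are not
  over-represented.

``GAGAM = wp*P + wc*C + we*E`` with binary weights, then a per-cell
size-factor normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .coaccess import ConnectionSet
from .genome import Gene, derive_promoter_window, derive_tss, tss_position
from .labeling import LabeledPeakSet, Peak, peaks_from_bed

log = logging.getLogger(__name__)

DEFAULT_DECAY_SCALE = 5000.0
GAGAM1_WEIGHTS = (1, 1, 1)
GAGAM2_WEIGHTS = (1, 1, 0)


@dataclass
class PeakCellMatrix:
    """Binary sparse peaks-by-cells accessibility matrix with row/col names."""

    matrix: sp.csr_matrix
    peak_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.peak_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.peak_ids)} peaks x {len(self.cell_ids)} cells"
            )
        data = self.matrix.data
        if data.size and not np.isin(data, (0, 1)).all():
            raise ValueError("accessibility matrix must be binary")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def rows(self, peak_ids) -> sp.csr_matrix:
        idx = {pid: i for i, pid in enumerate(self.peak_ids)}
        return self.matrix[[idx[p] for p in peak_ids], :]

    @classmethod
    def read(cls, mtx_path, peaks_bed_path, barcodes_path) -> "PeakCellMatrix":
        """Read the 10X-style triplet: MatrixMarket matrix + peaks BED3 +
        one-barcode-per-line text file."""
        from scipy.io import mmread

        m = sp.csr_matrix(mmread(str(mtx_path)))
        peaks = peaks_from_bed(peaks_bed_path)
        with open(barcodes_path) as fh:
            cells = [line.strip() for line in fh if line.strip()]
        return cls(m, [p.id for p in peaks], cells)

    def write(self, mtx_path, peaks_bed_path, barcodes_path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(mtx_path), sp.coo_matrix(self.matrix))
        from .labeling import parse_peak_id

        with open(peaks_bed_path, "w") as fh:
            for pid in self.peak_ids:
                iv = parse_peak_id(pid)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        with open(barcodes_path, "w") as fh:
            fh.write("\n".join(self.cell_ids) + "\n")

    def peaks(self) -> list[Peak]:
        from .labeling import peaks_from_ids

        return peaks_from_ids(self.peak_ids)


@dataclass
class GenePeakAssociation:
    """Sparse genes-by-peak-subset association matrix.

    ``kind`` is one of ``promoter`` (binary GP), ``exon`` (decay-weighted
    GI) or ``connection`` (score-valued PE, whose rows are promoter peaks
    rather than genes).
    """

    matrix: sp.csr_matrix
    gene_ids: list[str]
    peak_ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.gene_ids), len(self.peak_ids)):
            raise ValueError("association shape does not match id lists")
        if self.kind not in ("promoter", "exon", "connection"):
            raise ValueError(f"unknown association kind {self.kind!r}")


@dataclass
class GeneActivityMatrix:
    """The combined genes-by-cells activity matrix plus its components."""

    gagam: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    components: dict[str, np.ndarray] = field(default_factory=dict)
    weights: tuple[int, int, int] = GAGAM1_WEIGHTS
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gagam = np.asarray(self.gagam, dtype=float)
        if self.gagam.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("activity matrix shape does not match id lists")

    def write(self, outdir) -> None:
        from pathlib import Path

        from scipy.io import mmwrite

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "gagam.mtx"), sp.coo_matrix(self.gagam))
        (outdir / "genes.tsv").write_text("\n".join(self.gene_ids) + "\n")
        (outdir / "barcodes.tsv").write_text("\n".join(self.cell_ids) + "\n")


# ---------------------------------------------------------------------------
# Gene–peak association maps


def build_gene_promoter_map(
    lps: LabeledPeakSet,
    genes: list[Gene],
    upstream_bp: int = 500,
    strand_aware: bool = True,
) -> GenePeakAssociation:
    """Binary gene-to-promoter-peak association ``GP``.

    A prom peak that covers one or more genes' TSS regions is associated to
    exactly those genes (the TSS disambiguates shared promoter signatures
    between divergent genes).  A prom peak covering no TSS is associated to
    every gene whose promoter window (gene body plus ``upstream_bp`` bases
    upstream) it intersects.  Genes left without any promoter peak are
    excluded from the matrix entirely (the golden rule).
    """
    prom_peaks = lps.peaks_with_label("prom")
    hits_by_peak = {p.id: h for p, h, l in zip(lps.peaks, lps.tss_hits, lps.labels)}
    known = {g.gene_id for g in genes}

    assoc: dict[str, set[int]] = {g.gene_id: set() for g in genes}
    for col, p in enumerate(prom_peaks):
        hits = hits_by_peak[p.id] & known
        if hits:
            for gid in hits:
                assoc[gid].add(col)
        else:
            windows = (
                (g, derive_promoter_window(g, upstream_bp, strand_aware)) for g in genes
            )
            for g, w in windows:
                if w.intersects(p.interval):
                    assoc[g.gene_id].add(col)

    gp_genes = [g for g in genes if assoc[g.gene_id]]
    if not gp_genes:
        log.warning("no gene has an associated promoter peak")
    rows, cols = [], []
    for r, g in enumerate(gp_genes):
        for c in sorted(assoc[g.gene_id]):
            rows.append(r)
            cols.append(c)
    m = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(gp_genes), len(prom_peaks)),
    )
    multi = sum(1 for col in range(len(prom_peaks)) if m[:, col].nnz > 1)
    if multi:
        log.info("%d promoter peaks associated to multiple genes", multi)
    return GenePeakAssociation(
        m, [g.gene_id for g in gp_genes], [p.id for p in prom_peaks], "promoter"
    )


def build_pe_map(
    filtered: ConnectionSet, prom_peak_ids: list[str], enh_peak_ids: list[str]
) -> GenePeakAssociation:
    """Promoter-peak by enhancer-peak score matrix ``PE`` from filtered
    connections (entries are co-accessibility scores, 0 elsewhere)."""
    if not filtered.filtered:
        raise ValueError("PE map requires a filtered ConnectionSet")
    prom_idx = {pid: i for i, pid in enumerate(prom_peak_ids)}
    enh_idx = {pid: i for i, pid in enumerate(enh_peak_ids)}
    rows, cols, vals = [], [], []
    for c in filtered.connections:
        if c.p1 in prom_idx and c.p2 in enh_idx:
            rows.append(prom_idx[c.p1])
            cols.append(enh_idx[c.p2])
            vals.append(c.ca)
    m = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(prom_peak_ids), len(enh_peak_ids))
    )
    return GenePeakAssociation(m, list(prom_peak_ids), list(enh_peak_ids), "connection")


def exon_weight(d: float, scale: float = DEFAULT_DECAY_SCALE) -> float:
    """Exponentially decaying weight ``exp(-d/scale)`` of a peak-center-to-TSS
    distance ``d`` in bp."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return math.exp(-d / scale)


def build_exon_map(
    lps: LabeledPeakSet,
    gp_genes: list[Gene],
    decay_scale: float = DEFAULT_DECAY_SCALE,
    mode: str = "literal_containment",
    strand_aware: bool = True,
) -> GenePeakAssociation:
    """Decay-weighted gene-to-exon-peak association ``GI``.

    Only genes that passed the golden rule contribute rows; an exon peak is
    associated to a gene when it lies within (literal mode) or touches
    (relaxed mode) one of the gene's exons, with weight
    ``exp(-|center(peak) - TSS(gene)| / decay_scale)``.
    """
    exon_peaks = lps.peaks_with_label("exon")
    rows, cols, vals = [], [], []
    for r, g in enumerate(gp_genes):
        tss = tss_position(g, strand_aware)
        for c, p in enumerate(exon_peaks):
            in_exon = any(
                e.contains(p.interval)
                if mode == "literal_containment"
                else e.intersects(p.interval)
                for e in g.exons
            )
            if in_exon:
                rows.append(r)
                cols.append(c)
                vals.append(exon_weight(abs(p.interval.center - tss), decay_scale))
    m = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(gp_genes), len(exon_peaks))
    )
    return GenePeakAssociation(
        m, [g.gene_id for g in gp_genes], [p.id for p in exon_peaks], "exon"
    )


# ---------------------------------------------------------------------------
# Component matrices


def build_promoter_matrix(
    GP: GenePeakAssociation, D: PeakCellMatrix, binarize: bool = True
) -> np.ndarray:
    """Promoter component ``P = GP x D_prom``, binarized by default so a gene
    with several accessible promoter peaks still scores 1."""
    if GP.kind != "promoter":
        raise ValueError("expected a promoter association")
    P = (GP.matrix @ D.rows(GP.peak_ids)).toarray()
    if binarize:
        P = (P > 0).astype(float)
    return P


def build_coaccessibility_matrix(
    GP: GenePeakAssociation, PE: GenePeakAssociation, D: PeakCellMatrix
) -> np.ndarray:
    """Co-accessibility component ``C = GP x PE x D_enh``: summed scores of a
    gene's connected, accessible distal enhancers."""
    if PE.kind != "connection":
        raise ValueError("expected a connection association")
    if GP.peak_ids != PE.gene_ids:
        raise ValueError("GP promoter-peak columns must match PE rows")
    return (GP.matrix @ PE.matrix @ D.rows(PE.peak_ids)).toarray()


def build_exon_matrix(GI: GenePeakAssociation, D: PeakCellMatrix) -> np.ndarray:
    """Exon component ``E = GI x D_exon`` (decay-weighted, real-valued)."""
    if GI.kind != "exon":
        raise ValueError("expected an exon association")
    return (GI.matrix @ D.rows(GI.peak_ids)).toarray()


def combine(
    P: np.ndarray,
    C: np.ndarray,
    E: np.ndarray,
    gene_ids,
    cell_ids,
    weights: tuple[int, int, int] = GAGAM1_WEIGHTS,
) -> GeneActivityMatrix:
    """Weighted sum ``wp*P + wc*C + we*E`` with binary weights."""
    wp, wc, we = weights
    for w in (wp, wc, we):
        if w not in (0, 1):
            raise ValueError("weights must be binary")
    P, C, E = (np.asarray(M, dtype=float) for M in (P, C, E))
    if not (P.shape == C.shape == E.shape):
        raise ValueError(f"component shapes differ: {P.shape}, {C.shape}, {E.shape}")
    gagam = wp * P + wc * C + we * E
    return GeneActivityMatrix(
        gagam,
        list(gene_ids),
        list(cell_ids),
        components={"P": P, "C": C, "E": E},
        weights=(wp, wc, we),
    )


def normalize_gam(gam: GeneActivityMatrix, method: str = "cell_total") -> GeneActivityMatrix:
    """Per-cell size-factor normalization.

    ``cell_total`` divides each cell's column by its total and rescales by
    the median of the nonzero column totals, so every nonzero cell carries
    equal total activity; ``log_cell_total`` additionally applies
    ``log(1+x)``; ``none`` leaves the matrix unchanged.  All-zero cells stay
    zero.
    """
    if method not in ("cell_total", "log_cell_total", "none"):
        raise ValueError(f"unknown normalization method {method!r}")
    if method == "none":
        gam.normalized = True
        return gam
    X = gam.gagam
    sums = X.sum(axis=0)
    nonzero = sums > 0
    if nonzero.any():
        median = float(np.median(sums[nonzero]))
        scale = np.ones_like(sums)
        scale[nonzero] = median / sums[nonzero]
        X = X * scale[np.newaxis, :]
    if method == "log_cell_total":
        X = np.log1p(X)
    gam.gagam = X
    gam.normalized = True
    gam.provenance["normalization"] = method
    return gam
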