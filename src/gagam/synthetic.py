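"""Synthetic toy genomes and peak matrices with planted cell-type structure.

The generator lays out non-overlapping genes on one synthetic chromosome,
each with a promoter region just upstream of its TSS, two exons, and a few
distal enhancers within the promoter–enhancer connection window.  Each cell
type activates its own marker genes: their promoter / enhancer / exon peaks
open with high probability in cells of that type and with a low background
probability elsewhere; housekeeping genes are open in every cell type.
Region and peak geometry is chosen so that literal-containment labeling is
satisfiable (regions narrower than peaks, exon peaks narrower than exons).

Also ships a fully hand-derived worked example (2 genes, 7 peaks, 3 cells)
whose labels, association maps and matrices are frozen in an
expected-values table, covering the two tricky promoter cases: a gene with
no promoter-track signature rescued by the TSS rule, and divergent genes
sharing a promoter signature disambiguated by TSS association.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .coaccess import Connection, ConnectionSet, write_connections
from .evaluation import ClusterAssignment, GeneSetPair
from .gam import PeakCellMatrix
from .genome import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    RegulatoryRegion,
    tss_position,
    write_gtf,
    write_regulatory_track,
)

log = logging.getLogger(__name__)

CHROM = "chrS"
GENE_LENGTH = 10_000
GENE_SPACING = 40_000
GENE_OFFSET = 30_000
PEAK_WIDTH = 400
ENH_MIN_D, ENH_MAX_D = 5_000, 25_000


@dataclass
class SimulationConfig:
    """Study conditions for the planted-structure simulation."""

    n_genes: int = 60
    n_celltypes: int = 3
    cells_per_type: int = 200
    marker_genes_per_type: int = 10
    p_open_active: float = 0.8
    p_noise: float = 0.05
    enhancers_per_gene: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("p_open_active", "p_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "n_genes",
            "n_celltypes",
            "cells_per_type",
            "marker_genes_per_type",
            "enhancers_per_gene",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.marker_genes_per_type * self.n_celltypes > self.n_genes:
            raise ValueError("more marker genes requested than genes available")


@dataclass
class SyntheticDataset:
    annotation: GenomeAnnotation
    D: PeakCellMatrix
    truth_labels: ClusterAssignment
    truth_gene_sets: GeneSetPair
    truth_connections: ConnectionSet
    peak_gene: dict[str, str] = field(default_factory=dict)
    peak_role: dict[str, str] = field(default_factory=dict)


def make_toy_genome(
    n_genes: int, enhancers_per_gene: int = 2, seed: int = 0
) -> GenomeAnnotation:
    """Deterministic toy genome: alternating-strand genes with disjoint
    10 kb bodies, two exons each, one promoter region 100-300 bp upstream of
    the TSS and enhancers 5-25 kb from the TSS."""
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    regions: list[RegulatoryRegion] = []
    for i in range(n_genes):
        s = GENE_OFFSET + i * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        body = GenomicInterval(CHROM, s, s + GENE_LENGTH)
        exons = (
            GenomicInterval(CHROM, s, s + 1500),
            GenomicInterval(CHROM, s + 8000, s + GENE_LENGTH),
        )
        genes.append(Gene(f"G{i:03d}", f"G{i:03d}", body, strand, exons))
        tss = s if strand == "+" else s + GENE_LENGTH
        sign = -1 if strand == "+" else 1
        # promoter signature 100-300 bp upstream of the TSS
        lo, hi = sorted((tss + sign * 300, tss + sign * 100))
        regions.append(RegulatoryRegion(GenomicInterval(CHROM, lo, hi), "promoter"))
        for _ in range(enhancers_per_gene):
            d = int(rng.integers(ENH_MIN_D, ENH_MAX_D + 1))
            center = tss + sign * d
            regions.append(
                RegulatoryRegion(
                    GenomicInterval(CHROM, center - 100, center + 100),
                    "enhancer_distal",
                )
            )
    return GenomeAnnotation(genes, regions, [CHROM])


def _centered_peak(region: GenomicInterval, width: int = PEAK_WIDTH) -> GenomicInterval:
    c = int(region.center)
    return GenomicInterval(region.chrom, c - width // 2, c + width // 2)


def simulate_peak_matrix(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> SyntheticDataset:
    """Plant cell-type-specific accessibility on a toy genome.

    One peak per promoter / enhancer / exon region (width 400 bp, centered).
    Marker-gene peaks open with ``p_open_active`` in cells of their own
    type and ``p_noise`` elsewhere; housekeeping-gene peaks open with
    ``p_open_active`` everywhere.  Marker prom-enh pairs become truth
    connections with scores uniform in [0.3, 0.9].
    """
    if config.p_open_active <= config.p_noise:
        log.warning(
            "p_open_active <= p_noise: planted structure is unrecoverable"
        )
    rng = np.random.default_rng(config.seed)
    genes = annotation.genes
    per_gene = 1 + config.enhancers_per_gene
    if len(annotation.regions) != per_gene * len(genes):
        raise ValueError("annotation does not look like a make_toy_genome output")

    peak_ivs: list[GenomicInterval] = []
    peak_gene: list[str] = []
    peak_role: list[str] = []
    prom_peak_of: dict[str, int] = {}
    enh_peaks_of: dict[str, list[int]] = {}
    for gi, g in enumerate(genes):
        block = annotation.regions[gi * per_gene : (gi + 1) * per_gene]
        prom, enhs = block[0], block[1:]
        assert prom.label == "promoter"
        prom_peak_of[g.gene_id] = len(peak_ivs)
        peak_ivs.append(_centered_peak(prom.region))
        peak_gene.append(g.gene_id)
        peak_role.append("prom")
        enh_peaks_of[g.gene_id] = []
        for e in enhs:
            enh_peaks_of[g.gene_id].append(len(peak_ivs))
            peak_ivs.append(_centered_peak(e.region))
            peak_gene.append(g.gene_id)
            peak_role.append("enh")
        for e in g.exons:
            peak_ivs.append(_centered_peak(e))
            peak_gene.append(g.gene_id)
            peak_role.append("exon")

    n_peaks = len(peak_ivs)
    n_cells = config.n_celltypes * config.cells_per_type
    cell_types = np.repeat(np.arange(config.n_celltypes), config.cells_per_type)

    mpt = config.marker_genes_per_type
    marker_type: dict[str, int] = {}
    for t in range(config.n_celltypes):
        for g in genes[t * mpt : (t + 1) * mpt]:
            marker_type[g.gene_id] = t
    markers = set(marker_type)
    housekeeping = {g.gene_id for g in genes} - markers

    prob = np.full((n_peaks, n_cells), config.p_noise)
    for pi in range(n_peaks):
        gid = peak_gene[pi]
        if gid in housekeeping:
            prob[pi, :] = config.p_open_active
        else:
            prob[pi, cell_types == marker_type[gid]] = config.p_open_active
    D = (rng.random((n_peaks, n_cells)) < prob).astype(np.int8)

    peak_ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in peak_ivs]
    pcm = PeakCellMatrix(
        sp.csr_matrix(D), peak_ids, [f"cell{j:04d}" for j in range(n_cells)]
    )

    conns: list[Connection] = []
    for gid in sorted(markers):
        p_id = peak_ids[prom_peak_of[gid]]
        p_center = peak_ivs[prom_peak_of[gid]].center
        for ei in enh_peaks_of[gid]:
            ca = float(rng.uniform(0.3, 0.9))
            d = abs(peak_ivs[ei].center - p_center)
            conns.append(Connection(p_id, peak_ids[ei], ca, d))

    return SyntheticDataset(
        annotation=annotation,
        D=pcm,
        truth_labels=ClusterAssignment(list(pcm.cell_ids), cell_types),
        truth_gene_sets=GeneSetPair(markers=markers, housekeeping=housekeeping),
        truth_connections=ConnectionSet(conns),
        peak_gene=dict(zip(peak_ids, peak_gene)),
        peak_role=dict(zip(peak_ids, peak_role)),
    )


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Toy genome + planted peak matrix under the default study conditions."""
    cfg = config or SimulationConfig()
    annotation = make_toy_genome(cfg.n_genes, cfg.enhancers_per_gene, cfg.seed)
    return simulate_peak_matrix(annotation, cfg)


def write_dataset(ds: SyntheticDataset, outdir, force: bool = False) -> None:
    """Write the dataset in the on-disk formats the pipeline reads."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(ds.annotation.genes, outdir / "genes.gtf")
    write_regulatory_track(ds.annotation.regions, outdir / "regions.bed")
    ds.D.write(outdir / "matrix.mtx", outdir / "peaks.bed", outdir / "barcodes.tsv")
    write_connections(ds.truth_connections, outdir / "connections.csv")
    ds.truth_labels.write_tsv(outdir / "truth_labels.tsv")
    (outdir / "markers.txt").write_text(
        "\n".join(sorted(ds.truth_gene_sets.markers)) + "\n"
    )
    (outdir / "housekeeping.txt").write_text(
        "\n".join(sorted(ds.truth_gene_sets.housekeeping)) + "\n"
    )


# ---------------------------------------------------------------------------
# Hand-derived worked example


def worked_example() -> tuple[SyntheticDataset, dict]:
    """The 2-gene / 7-peak / 3-cell fixture with its expected-values table.

    GENEA (+ strand) and GENEB (- strand) are divergent.  The shared
    promoter signature between them is contained in a peak that covers only
    GENEA's TSS, so TSS association assigns it to GENEA alone; GENEB has no
    promoter signature in any of its peaks and is rescued by a peak covering
    its TSS.  Expected labels, association maps, component matrices and the
    combined activity matrices are hand-derived and frozen in the shipped
    table.
    """
    gene_a = Gene(
        "GENEA",
        "GENEA",
        GenomicInterval(CHROM, 1000, 6000),
        "+",
        (GenomicInterval(CHROM, 1000, 1200), GenomicInterval(CHROM, 5500, 6000)),
    )
    gene_b = Gene(
        "GENEB",
        "GENEB",
        GenomicInterval(CHROM, 100, 900),
        "-",
        (GenomicInterval(CHROM, 100, 250), GenomicInterval(CHROM, 750, 900)),
    )
    regions = [
        RegulatoryRegion(GenomicInterval(CHROM, 920, 980), "promoter"),
        RegulatoryRegion(GenomicInterval(CHROM, 7000, 7150), "enhancer_distal"),
        RegulatoryRegion(GenomicInterval(CHROM, 50000, 50150), "enhancer_distal"),
    ]
    annotation = GenomeAnnotation([gene_a, gene_b], regions, [CHROM])

    peak_coords = [
        (910, 1050),   # shared prom signature, covers GENEA's TSS only
        (856, 906),    # covers GENEB's TSS, no prom signature
        (6950, 7200),  # distal enhancer near GENEA
        (1050, 1150),  # inside GENEA exon 1
        (780, 880),    # inside GENEB exon 2
        (16000, 16400),  # intergenic
        (49950, 50200),  # distal enhancer beyond the distance threshold
    ]
    peak_ids = [f"{CHROM}:{s}-{e}" for s, e in peak_coords]

    D = np.array(
        [
            [1, 1, 0],
            [0, 1, 1],
            [1, 0, 1],
            [1, 0, 0],
            [0, 1, 1],
            [1, 1, 1],
            [0, 0, 1],
        ],
        dtype=np.int8,
    )
    pcm = PeakCellMatrix(sp.csr_matrix(D), peak_ids, ["c0", "c1", "c2"])

    conns = ConnectionSet(
        [
            Connection(peak_ids[0], peak_ids[2], 0.6, 6095.0),
            Connection(peak_ids[0], peak_ids[6], 0.9, 49095.0),
            Connection(peak_ids[1], peak_ids[2], 0.1, 6194.0),
        ]
    )

    ds = SyntheticDataset(
        annotation=annotation,
        D=pcm,
        truth_labels=ClusterAssignment(list(pcm.cell_ids), np.zeros(3, dtype=int)),
        truth_gene_sets=GeneSetPair(markers={"GENEA"}, housekeeping={"GENEB"}),
        truth_connections=conns,
        peak_gene={
            peak_ids[0]: "GENEA",
            peak_ids[1]: "GENEB",
            peak_ids[2]: "GENEA",
            peak_ids[3]: "GENEA",
            peak_ids[4]: "GENEB",
        },
        peak_role={
            peak_ids[0]: "prom",
            peak_ids[1]: "prom",
            peak_ids[2]: "enh",
            peak_ids[3]: "exon",
            peak_ids[4]: "exon",
            peak_ids[6]: "enh",
        },
    )
    expected = json.loads(
        resources.files("gagam.data").joinpath("worked_example_expected.json").read_text()
    )
    return ds, expected
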