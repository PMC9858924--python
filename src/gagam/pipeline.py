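"""End-to-end construction of the gene activity matrix.

Ties the stages together: label peaks against the genomic model, obtain and
filter promoter–enhancer co-accessibility, build the three component
matrices, combine them with binary weights, and normalize.
"""

from __future__ import annotations

import logging

from .coaccess import (
    ConnectionSet,
    compute_ca_threshold,
    estimate_coaccessibility,
    filter_connections,
)
from .config import PipelineConfig
from .gam import (
    GeneActivityMatrix,
    PeakCellMatrix,
    build_coaccessibility_matrix,
    build_exon_map,
    build_exon_matrix,
    build_gene_promoter_map,
    build_pe_map,
    build_promoter_matrix,
    combine,
    normalize_gam,
)
from .genome import GenomeAnnotation
from .labeling import LabeledPeakSet, label_peaks

log = logging.getLogger(__name__)


def build_gagam(
    D: PeakCellMatrix,
    annotation: GenomeAnnotation,
    connections: ConnectionSet | None = None,
    config: PipelineConfig | None = None,
) -> tuple[GeneActivityMatrix, LabeledPeakSet]:
    """Run the full pipeline on a peak-by-cell matrix.

    When no connections are supplied the built-in windowed-correlation
    surrogate estimates them from ``D``.  Raises if no gene survives the
    golden rule.
    """
    cfg = config or PipelineConfig()
    peaks = D.peaks()
    lps = label_peaks(
        peaks,
        annotation,
        mode=cfg.overlap_mode,
        tss_width=cfg.tss_width,
        strand_aware=cfg.strand_aware,
    )

    GP = build_gene_promoter_map(
        lps, annotation.genes, upstream_bp=cfg.upstream_bp, strand_aware=cfg.strand_aware
    )
    if not GP.gene_ids:
        raise ValueError("no gene has an accessible promoter peak (golden rule)")
    gp_genes = [annotation.gene(gid) for gid in GP.gene_ids]

    if connections is None:
        connections = estimate_coaccessibility(
            D.matrix, peaks, window_bp=cfg.coaccess_window_bp
        )
    enh_ids = [p.id for p in lps.peaks_with_label("enhD")]
    try:
        cam = compute_ca_threshold(connections, include_negatives=cfg.cam_include_negatives)
        filtered = filter_connections(connections, lps, cam=cam, d_th=cfg.d_th)
    except ValueError:
        log.warning("no usable co-accessibility scores; C component is zero")
        filtered = ConnectionSet([], cam=0.0, d_th=cfg.d_th, filtered=True)
    PE = build_pe_map(filtered, GP.peak_ids, enh_ids)

    GI = build_exon_map(
        lps,
        gp_genes,
        decay_scale=cfg.decay_scale,
        mode=cfg.overlap_mode,
        strand_aware=cfg.strand_aware,
    )

    P = build_promoter_matrix(GP, D, binarize=cfg.binarize_promoter)
    C = build_coaccessibility_matrix(GP, PE, D)
    E = build_exon_matrix(GI, D)

    gam = combine(P, C, E, GP.gene_ids, D.cell_ids, weights=cfg.weights)
    gam.provenance.update(
        {
            "config": cfg.to_dict(),
            "cam": filtered.cam,
            "n_connections_kept": len(filtered),
            "label_counts": lps.summary(),
        }
    )
    return normalize_gam(gam, method=cfg.normalization), lps
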