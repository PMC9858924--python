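import numpy as np
import pytest
import scipy.sparse as sp

from gagam import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    PeakCellMatrix,
    RegulatoryRegion,
    peaks_from_ids,
)


@pytest.fixture
def toy_annotation():
    """One + strand gene with two exons, a promoter region upstream of it and
    a distal enhancer region further away."""
    g1 = Gene(
        "G1",
        "G1",
        GenomicInterval("chr1", 999, 5000),
        "+",
        (GenomicInterval("chr1", 999, 1199), GenomicInterval("chr1", 4700, 5000)),
    )
    regions = [
        RegulatoryRegion(GenomicInterval("chr1", 700, 900), "promoter"),
        RegulatoryRegion(GenomicInterval("chr1", 8000, 8300), "enhancer_distal"),
    ]
    return GenomeAnnotation([g1], regions, ["chr1"])


@pytest.fixture
def toy_peaks():
    return peaks_from_ids(
        [
            "chr1:650-950",    # contains the promoter region
            "chr1:990-1400",   # covers the TSS [999, 1001)
            "chr1:7900-8400",  # contains the enhancer region
            "chr1:1050-1150",  # inside exon 1
            "chr1:3000-3500",  # intronic
        ]
    )


@pytest.fixture
def worked():
    from gagam import worked_example

    return worked_example()


def make_pcm(rows, peak_ids=None, cell_ids=None):
    rows = np.asarray(rows, dtype=np.int8)
    n_peaks, n_cells = rows.shape
    if peak_ids is None:
        peak_ids = [f"chr1:{1000 * i}-{1000 * i + 400}" for i in range(n_peaks)]
    if cell_ids is None:
        cell_ids = [f"c{j}" for j in range(n_cells)]
    return PeakCellMatrix(sp.csr_matrix(rows), peak_ids, cell_ids)
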