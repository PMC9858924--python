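"""Peak–peak co-accessibility: file reader, windowed-correlation estimator,
threshold derivation, and promoter–enhancer filtering.

Co-accessibility scores are normally produced by an external pipeline and
supplied as a CSV of ``Peak1, Peak2, coaccess`` rows; :func:`read_connections`
is the faithful interoperability path.  :func:`estimate_coaccessibility` is a
deliberately simple built-in surrogate — the Pearson correlation of binary
accessibility vectors for peak pairs within a genomic window — adequate for
desk-scale data and testing, and documented as such.

Filtering keeps only strong promoter–enhancer pairs: score at least ``cam``
(the mean of the positive scores of the dataset) and center-to-center
distance at most ``d_th`` (30 kb by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .labeling import LabeledPeakSet, Peak, parse_peak_id

log = logging.getLogger(__name__)

DEFAULT_DISTANCE_THRESHOLD = 30_000


@dataclass(frozen=True)
class Connection:
    """An unordered peak pair with its co-accessibility score and distance."""

    p1: str
    p2: str
    ca: float
    d: float

    def __post_init__(self) -> None:
        if self.p1 == self.p2:
            raise ValueError(f"self-connection {self.p1}")
        if self.d < 0:
            raise ValueError("negative distance")


@dataclass
class ConnectionSet:
    connections: list[Connection]
    cam: float | None = None
    d_th: int = DEFAULT_DISTANCE_THRESHOLD
    filtered: bool = False
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.connections)

    def scores(self) -> np.ndarray:
        return np.array([c.ca for c in self.connections], dtype=float)


def peak_center(peak_id: str) -> float:
    iv = parse_peak_id(peak_id)
    return iv.center


def _canonical_pair(p1: str, p2: str) -> tuple[str, str]:
    return (p1, p2) if p1 <= p2 else (p2, p1)


def read_connections(path) -> ConnectionSet:
    """Read a connections CSV/TSV with columns Peak1, Peak2, coaccess.

    Peak ids in either ``chr1_100_600`` or ``chr1:100-600`` dialect.  The
    center-to-center distance is computed from the ids.  Duplicate unordered
    pairs collapse to the maximum score; rows with missing scores are dropped
    (counted in ``dropped['na_score']``).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"peak1", "peak2", "coaccess"}
    if not required.issubset(df.columns):
        raise ValueError(f"connections file must have columns {sorted(required)}")

    n_na = int(df["coaccess"].isna().sum())
    df = df.dropna(subset=["coaccess"])

    best: dict[tuple[str, str], float] = {}
    for row_no, (pid1, pid2, ca) in enumerate(
        zip(df["peak1"], df["peak2"], df["coaccess"])
    ):
        try:
            parse_peak_id(str(pid1)), parse_peak_id(str(pid2))
        except ValueError as exc:
            raise ValueError(f"row {row_no}: {exc}") from exc
        key = _canonical_pair(str(pid1), str(pid2))
        ca = float(ca)
        if key not in best or ca > best[key]:
            best[key] = ca

    conns = [
        Connection(p1, p2, ca, abs(peak_center(p1) - peak_center(p2)))
        for (p1, p2), ca in best.items()
    ]
    if n_na:
        log.info("dropped %d connection rows with missing scores", n_na)
    return ConnectionSet(conns, dropped={"na_score": n_na})


def write_connections(cs: ConnectionSet, path) -> None:
    """Write connections in the underscore peak-id dialect."""
    with open(path, "w") as fh:
        fh.write("Peak1,Peak2,coaccess\n")
        for c in cs.connections:
            p1 = c.p1.replace(":", "_").replace("-", "_")
            p2 = c.p2.replace(":", "_").replace("-", "_")
            fh.write(f"{p1},{p2},{c.ca}\n")


def estimate_coaccessibility(
    D, peaks: list[Peak], window_bp: int = 500_000
) -> ConnectionSet:
    """Windowed-Pearson surrogate co-accessibility estimator.

    For every same-chromosome peak pair whose centers lie within
    ``window_bp``, the score is the Pearson correlation of the two binary
    accessibility vectors across cells.  Non-positive scores are dropped.
    Peaks accessible in no cell or in every cell have undefined correlation;
    their pairs are skipped (counted in ``dropped['degenerate']``).
    Deterministic given the matrix.
    """
    X = np.asarray(D.todense() if hasattr(D, "todense") else D, dtype=float)
    n_peaks, n_cells = X.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells to estimate co-accessibility")
    if len(peaks) != n_peaks:
        raise ValueError("peak list does not match matrix rows")

    mean = X.mean(axis=1)
    std = X.std(axis=1)
    degenerate = std == 0.0

    order = sorted(
        range(n_peaks), key=lambda i: (peaks[i].interval.chrom, peaks[i].interval.center)
    )
    centers = [peaks[i].interval.center for i in order]
    chroms = [peaks[i].interval.chrom for i in order]

    conns: list[Connection] = []
    n_skipped = 0
    for a in range(n_peaks):
        i = order[a]
        for b in range(a + 1, n_peaks):
            j = order[b]
            if chroms[b] != chroms[a]:
                break
            d = centers[b] - centers[a]
            if d > window_bp:
                break
            if degenerate[i] or degenerate[j]:
                n_skipped += 1
                continue
            ca = float(
                ((X[i] - mean[i]) @ (X[j] - mean[j])) / (n_cells * std[i] * std[j])
            )
            if ca > 0:
                conns.append(Connection(peaks[i].id, peaks[j].id, ca, float(d)))
    if n_skipped:
        log.info("skipped %d pairs with degenerate accessibility vectors", n_skipped)
    return ConnectionSet(conns, dropped={"degenerate": n_skipped})


def compute_ca_threshold(cs: ConnectionSet, include_negatives: bool = False) -> float:
    """The adaptive score threshold ``cam``: mean of the dataset's positive
    co-accessibility scores (optionally of all non-zero scores)."""
    s = cs.scores()
    usable = s[s != 0] if include_negatives else s[s > 0]
    if usable.size == 0:
        raise ValueError("no usable connections: no positive co-accessibility scores")
    cam = float(usable.mean())
    cs.cam = cam
    return cam


def filter_connections(
    cs: ConnectionSet,
    lps: LabeledPeakSet,
    cam: float | None = None,
    d_th: int = DEFAULT_DISTANCE_THRESHOLD,
) -> ConnectionSet:
    """Keep strong promoter–enhancer connections only.

    Retains connections whose endpoints are one ``prom`` and one ``enhD``
    peak, with score >= ``cam`` and distance <= ``d_th``; orientation is
    normalized to (prom, enhD).  Connections naming unknown peaks are
    dropped with a count.  Idempotent.
    """
    if cam is None:
        cam = cs.cam
    if cam is None:
        raise ValueError("cam not computed; call compute_ca_threshold first")

    kept: list[Connection] = []
    n_unknown = 0
    for c in cs.connections:
        l1, l2 = lps.label_of(c.p1), lps.label_of(c.p2)
        if l1 is None or l2 is None:
            n_unknown += 1
            continue
        if {l1, l2} != {"prom", "enhD"}:
            continue
        if c.ca < cam or c.d > d_th:
            continue
        if l1 == "enhD":  # normalize orientation to (prom, enhD)
            c = replace(c, p1=c.p2, p2=c.p1)
        kept.append(c)
    if n_unknown:
        log.info("dropped %d connections referencing unknown peaks", n_unknown)
    return ConnectionSet(
        kept, cam=cam, d_th=d_th, filtered=True, dropped={"unknown_peak": n_unknown}
    )
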