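"""Scikit-learn style estimators wrapping the pipeline.

``GeneActivityScorer`` is a transformer from cell-by-peak accessibility
profiles to cell-by-gene activity profiles (the sklearn samples-by-features
orientation; the library-level functions use the genomics peaks-by-cells
orientation).  ``LSIEmbedder`` is the TF-IDF + truncated-SVD reduction used
before clustering.  Both compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .coaccess import ConnectionSet
from .config import PipelineConfig
from .gam import PeakCellMatrix
from .genome import GenomeAnnotation
from .pipeline import build_gagam


class GeneActivityScorer(BaseEstimator, TransformerMixin):
    """Transform binary peak accessibility into per-gene activity scores.

    Parameters
    ----------
    annotation : GenomeAnnotation
        Gene model plus labeled regulatory regions.
    peak_ids : sequence of str
        Peak identifiers ("chrom:start-end"), one per input feature column.
    connections : ConnectionSet, optional
        Pre-computed co-accessibility records; when omitted, the built-in
        windowed-correlation surrogate is estimated from the data at fit.
    upstream_bp, decay_scale, d_th, tss_width, weights, overlap_mode,
    normalization, strand_aware, cam_include_negatives, binarize_promoter,
    coaccess_window_bp
        See :class:`gagam.config.PipelineConfig`.

    Attributes
    ----------
    gene_ids_ : list of str
        Genes surviving the golden rule, in output column order.
    labels_ : list of str
        Functional label per peak.
    cam_ : float
        Derived co-accessibility threshold.
    label_counts_ : dict
        Per-label peak counts.
    """

    def __init__(
        self,
        annotation: GenomeAnnotation | None = None,
        peak_ids=None,
        connections: ConnectionSet | None = None,
        upstream_bp: int = 500,
        decay_scale: float = 5000.0,
        d_th: int = 30_000,
        tss_width: int = 2,
        weights: tuple[int, int, int] = (1, 1, 1),
        overlap_mode: str = "literal_containment",
        normalization: str = "cell_total",
        strand_aware: bool = True,
        cam_include_negatives: bool = False,
        binarize_promoter: bool = True,
        coaccess_window_bp: int = 500_000,
    ):
        self.annotation = annotation
        self.peak_ids = peak_ids
        self.connections = connections
        self.upstream_bp = upstream_bp
        self.decay_scale = decay_scale
        self.d_th = d_th
        self.tss_width = tss_width
        self.weights = weights
        self.overlap_mode = overlap_mode
        self.normalization = normalization
        self.strand_aware = strand_aware
        self.cam_include_negatives = cam_include_negatives
        self.binarize_promoter = binarize_promoter
        self.coaccess_window_bp = coaccess_window_bp

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            upstream_bp=self.upstream_bp,
            decay_scale=self.decay_scale,
            d_th=self.d_th,
            tss_width=self.tss_width,
            weights=tuple(self.weights),
            overlap_mode=self.overlap_mode,
            normalization=self.normalization,
            strand_aware=self.strand_aware,
            cam_include_negatives=self.cam_include_negatives,
            binarize_promoter=self.binarize_promoter,
            coaccess_window_bp=self.coaccess_window_bp,
        )

    def _as_pcm(self, X) -> PeakCellMatrix:
        if self.annotation is None or self.peak_ids is None:
            raise ValueError("annotation and peak_ids are required")
        Xs = sp.csr_matrix(X)
        if Xs.shape[1] != len(self.peak_ids):
            raise ValueError(
                f"X has {Xs.shape[1]} features but {len(self.peak_ids)} peak_ids given"
            )
        cells = [f"cell{i}" for i in range(Xs.shape[0])]
        return PeakCellMatrix(Xs.T.tocsr(), list(self.peak_ids), cells)

    def fit(self, X, y=None):
        """Label peaks and derive the gene-peak association maps from X
        (cells x peaks, binary)."""
        D = self._as_pcm(X)
        gam, lps = build_gagam(D, self.annotation, self.connections, self._config())
        self.gene_ids_ = gam.gene_ids
        self.labels_ = list(lps.labels)
        self.label_counts_ = lps.summary()
        self.cam_ = gam.provenance.get("cam")
        self._lps = lps
        self.n_features_in_ = len(self.peak_ids)
        return self

    def transform(self, X) -> np.ndarray:
        """Return the cells-by-genes activity matrix for X."""
        check_is_fitted(self, "gene_ids_")
        D = self._as_pcm(X)
        gam, _ = build_gagam(D, self.annotation, self.connections, self._config())
        if gam.gene_ids != self.gene_ids_:
            # align to the fitted gene set; genes absent in this batch score 0
            idx = {g: i for i, g in enumerate(gam.gene_ids)}
            out = np.zeros((len(self.gene_ids_), gam.gagam.shape[1]))
            for r, g in enumerate(self.gene_ids_):
                if g in idx:
                    out[r] = gam.gagam[idx[g]]
            return out.T
        return gam.gagam.T

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "gene_ids_")
        return np.asarray(self.gene_ids_, dtype=object)


class LSIEmbedder(BaseEstimator, TransformerMixin):
    """TF-IDF weighting followed by truncated SVD (latent semantic indexing).

    Operates on cells-by-features matrices; the first, depth-correlated
    singular component is dropped by default.
    """

    def __init__(self, n_components: int = 30, drop_first: bool = True, random_state: int = 0):
        self.n_components = n_components
        self.drop_first = drop_first
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        from .evaluation import lsi_embed

        X = np.asarray(X, dtype=float)
        emb = lsi_embed(
            X.T,
            n_components=self.n_components,
            drop_first=self.drop_first,
            random_state=self.random_state,
        )
        self.n_features_in_ = X.shape[1]
        self.embedding_ = emb
        return emb

    def transform(self, X):
        # SVD components are fit per call on the full matrix (transductive,
        # as in scATAC practice); transform re-runs fit_transform.
        return self.fit_transform(X)
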