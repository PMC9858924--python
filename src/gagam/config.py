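"""Pipeline configuration: validated flat key-value schema, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with their defaults.

    ``upstream_bp``     bases upstream of the TSS included in the promoter
                        window (an estimate of mean peak length).
    ``decay_scale``     exponential decay scale (bp) for exon-peak weights.
    ``d_th``            maximum promoter–enhancer connection distance (bp).
    ``tss_width``       width (bp) of the TSS region at the gene start.
    ``weights``         binary (wp, wc, we) selecting the contributions.
    ``overlap_mode``    'literal_containment' or 'any_overlap'.
    ``normalization``   'cell_total', 'log_cell_total' or 'none'.
    ``strand_aware``    transcription-directional TSS / upstream extension.
    ``cam_include_negatives``  average all non-zero scores when deriving cam
                        instead of the positive scores only.
    ``binarize_promoter``  clip the promoter component to {0,1}.
    ``coaccess_window_bp`` window of the built-in co-accessibility surrogate.
    ``seed``            seed for every stochastic step.
    """

    upstream_bp: int = 500
    decay_scale: float = 5000.0
    d_th: int = 30_000
    tss_width: int = 2
    weights: tuple[int, int, int] = (1, 1, 1)
    overlap_mode: str = "literal_containment"
    normalization: str = "cell_total"
    strand_aware: bool = True
    cam_include_negatives: bool = False
    binarize_promoter: bool = True
    coaccess_window_bp: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = tuple(int(w) for w in self.weights)
        if len(self.weights) != 3 or any(w not in (0, 1) for w in self.weights):
            raise ValueError("weights must be three binary values")
        if self.overlap_mode not in ("literal_containment", "any_overlap"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")
        if self.normalization not in ("cell_total", "log_cell_total", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for name in ("upstream_bp", "d_th", "tss_width", "coaccess_window_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = list(self.weights)
        return d

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a flat mapping")
        return cls.from_dict(data)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
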