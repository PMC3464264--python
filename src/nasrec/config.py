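"""Pipeline configuration and named parameter profiles.

The two dataset-scale profiles record the reference parameterizations of
the method on the standard action benchmarks (IC counts, cluster counts,
selection thresholds Mc/Nc, pooling grid, SVM C and LDA topic count).
The "synthetic-small" profile scales every count down for the synthetic
benchmark so the full pipeline runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

from nasrec.detector import DetectorParams
from nasrec.patches import ScaleConfig

__all__ = ["PipelineConfig", "PROFILES", "get_profile"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of the NAS pipeline."""

    detector: DetectorParams = field(default_factory=DetectorParams)
    scales: ScaleConfig = field(default_factory=ScaleConfig)
    n_ic: int = 64
    n_ic_clusters: int = 32
    n_structural: int = 64
    Mc: int = 1                      # SVM-route selection threshold
    Nc: int = 50
    Mc_lda: int = 1
    Nc_lda: int = 50
    grid: tuple[int, int, int] = (3, 1, 1)
    svm_C: float = 0.125
    lda_topics: int = 8
    train_fraction: float = 1.0      # patch subsample for ICA / clustering
    gabor_restarts: int = 2
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detector"]["nms_radius"] = list(self.detector.nms_radius)
        return d

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)


PROFILES: dict[str, PipelineConfig] = {
    # Reference parameterization for the 6-action benchmark setting.
    "kth-reference": PipelineConfig(
        n_ic=1200, n_ic_clusters=480, n_structural=1000,
        Mc=2, Nc=400, Mc_lda=3, Nc_lda=300,
        grid=(3, 1, 1), svm_C=0.125, lda_topics=50,
        train_fraction=0.119, gabor_restarts=4,
    ),
    # Reference parameterization for the 10-action benchmark setting.
    "weizmann-reference": PipelineConfig(
        n_ic=1200, n_ic_clusters=440, n_structural=700,
        Mc=1, Nc=500, Mc_lda=0, Nc_lda=100,
        grid=(1, 1, 1), svm_C=0.125, lda_topics=30,
        train_fraction=0.175, gabor_restarts=4,
    ),
    # Scaled-down profile for the synthetic benchmark.
    "synthetic-small": PipelineConfig(
        detector=DetectorParams(max_points=120, min_response_frac=0.02,
                                nms_radius=(3, 3, 2)),
        n_ic=64, n_ic_clusters=32, n_structural=64,
        Mc=1, Nc=50, Mc_lda=1, Nc_lda=50,
        grid=(3, 1, 1), svm_C=0.125, lda_topics=8,
        train_fraction=1.0, gabor_restarts=2,
    ),
}


def get_profile(name: str, seed: int | None = None) -> PipelineConfig:
    """Look up an immutable named profile, optionally overriding the seed."""
    try:
        cfg = PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; available: {sorted(PROFILES)}") from None
    return cfg if seed is None else cfg.with_seed(seed)
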