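"""Coupled-scale circular patch sequences around interest points.

At each interest point three blocks are cropped -- 13x13x11, 25x25x21 and
49x49x31 (diameter x diameter x frames) -- aligned so that the centers of
their middle frames coincide with the point.  Larger blocks are reduced to
the common 13x13x11 grid by centered strided sampling (for the middle
scale this picks exactly the even-indexed pixels and frames), then a
circular disc mask is applied to every frame and the surviving pixels are
flattened in a frozen frame-major, row-major order.  Each flattened
sequence is mean-subtracted, giving three equal-length vectors per point
(l = 129 * 11 = 1419) so one ICA routine serves all scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nasrec.detector import InterestPoint
from nasrec.synthvid import VideoVolume

__all__ = [
    "ScaleConfig",
    "PatchSequenceTriple",
    "circular_mask",
    "centered_downsample",
    "sample_patch_triple",
    "extract_patches",
]


@dataclass(frozen=True)
class ScaleConfig:
    """The coupled spatial-temporal scale triple and the common target grid."""

    diameters: tuple[int, ...] = (13, 25, 49)
    durations: tuple[int, ...] = (11, 21, 31)
    target: tuple[int, int] = (13, 11)  # (diameter, duration)

    def __post_init__(self) -> None:
        if len(self.diameters) != len(self.durations):
            raise ValueError("diameters and durations must pair up")
        td, tt = self.target
        for d, T in zip(self.diameters, self.durations):
            if (d - 1) % (td - 1) or (d - 1) // (td - 1) < 1:
                raise ValueError(f"spatial stride for diameter {d} is not a positive integer")
            if (T - 1) % (tt - 1) or (T - 1) // (tt - 1) < 1:
                raise ValueError(f"temporal stride for duration {T} is not a positive integer")

    @property
    def n_scales(self) -> int:
        return len(self.diameters)

    def strides(self, scale: int) -> tuple[int, int]:
        """(spatial, temporal) stride for one scale index."""
        return (
            (self.diameters[scale] - 1) // (self.target[0] - 1),
            (self.durations[scale] - 1) // (self.target[1] - 1),
        )


def circular_mask(diameter: int = 13) -> tuple[np.ndarray, np.ndarray]:
    """Disc mask over a diameter x diameter grid plus its pixel ordering.

    Pixel (r, c) is in-mask iff (r-m)^2 + (c-m)^2 <= (m + 0.4)^2 with m
    the center index.  The 0.4 margin fixes the canonical pixel count of
    the diameter-13 disc at 129 (so every flattened sequence has
    l = 129 * 11 = 1419 entries); a half-pixel margin would admit 137.
    The ordering (row-major over in-mask pixels) is the canonical
    flattening order and is serialized with every codebook.
    """
    if diameter % 2 == 0:
        raise ValueError("diameter must be odd")
    m = diameter // 2
    r, c = np.mgrid[0:diameter, 0:diameter]
    mask = (r - m) ** 2 + (c - m) ** 2 <= (m + 0.4) ** 2
    order = np.flatnonzero(mask.ravel())
    return mask, order


@dataclass
class PatchSequenceTriple:
    """Flattened masked patch sequences at all scales for one point."""

    center: InterestPoint
    vectors: np.ndarray  # (n_scales, l)
    mask_size: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be (n_scales, l)")


def centered_downsample(block: np.ndarray, cfg: ScaleConfig | None = None) -> np.ndarray:
    """Reduce a d x d x T block to the target grid by centered strides.

    Indices are center + k*stride for k = -(td-1)/2 .. (td-1)/2 spatially
    and similarly in time; with stride 2 on a 25x25x21 block this picks
    exactly the even-indexed pixels and frames.  Identity when the block
    is already at target size.  Block axes are (T, rows, cols).
    """
    cfg = cfg or ScaleConfig()
    T, d1, d2 = block.shape
    if d1 != d2:
        raise ValueError("block must be spatially square")
    td, tt = cfg.target
    if (d1 - 1) % (td - 1) or (T - 1) % (tt - 1):
        raise ValueError(f"block {block.shape} has non-integral stride to target {cfg.target}")
    ss = (d1 - 1) // (td - 1)
    st = (T - 1) // (tt - 1)
    sp_idx = (d1 - 1) // 2 + ss * (np.arange(td) - (td - 1) // 2)
    t_idx = (T - 1) // 2 + st * (np.arange(tt) - (tt - 1) // 2)
    return block[np.ix_(t_idx, sp_idx, sp_idx)]


def _crop_replicate(frames: np.ndarray, t0: int, y0: int, x0: int, dur: int, diam: int) -> np.ndarray:
    """Crop a dur x diam x diam block centered at (t0, y0, x0), replicate-padded."""
    T, H, W = frames.shape
    ht, hs = dur // 2, diam // 2
    ti = np.clip(np.arange(t0 - ht, t0 + ht + 1), 0, T - 1)
    yi = np.clip(np.arange(y0 - hs, y0 + hs + 1), 0, H - 1)
    xi = np.clip(np.arange(x0 - hs, x0 + hs + 1), 0, W - 1)
    return frames[np.ix_(ti, yi, xi)]


def sample_patch_triple(
    v: VideoVolume, pt: InterestPoint, cfg: ScaleConfig | None = None
) -> PatchSequenceTriple:
    """Extract, normalize and flatten the coupled-scale sequences at a point."""
    cfg = cfg or ScaleConfig()
    if np.isnan(v.frames).any():
        raise ValueError("NaN in source volume")
    mask, order = circular_mask(cfg.target[0])
    vectors = []
    for s in range(cfg.n_scales):
        block = _crop_replicate(
            v.frames, pt.t, pt.y, pt.x, cfg.durations[s], cfg.diameters[s]
        )
        block = centered_downsample(block, cfg)
        flat = block.reshape(cfg.target[1], -1)[:, order].ravel()  # frame-major
        vectors.append(flat - flat.mean())
    return PatchSequenceTriple(center=pt, vectors=np.stack(vectors), mask_size=int(mask.sum()))


def extract_patches(
    v: VideoVolume, points: list[InterestPoint], cfg: ScaleConfig | None = None
) -> np.ndarray:
    """Batch patch extraction: (n_points, n_scales, l) array."""
    cfg = cfg or ScaleConfig()
    if not points:
        mask, _ = circular_mask(cfg.target[0])
        return np.empty((0, cfg.n_scales, int(mask.sum()) * cfg.target[1]))
    return np.stack([sample_patch_triple(v, pt, cfg).vectors for pt in points])
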