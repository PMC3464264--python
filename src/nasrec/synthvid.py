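"""Video I/O and a deterministic synthetic action-video generator.

The generator emulates the structure of benchmark action datasets: short
grayscale clips, each containing repeated executions of a single action by
one "subject".  Subjects differ by geometric jitter (position, size, speed)
so that grouped cross-validation (leave-one-subject-out) is nontrivial,
and clips of the same subject differ by the pixel-noise draw.  Additive
white Gaussian noise is calibrated to a target signal-to-noise ratio in
dB, defined as 20*log10(Std_signal / Std_noise); 20 dB therefore means
Std_noise/Std_signal = 0.1.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "VideoVolume",
    "SynthSpec",
    "ACTION_REGISTRY",
    "load_video",
    "save_video",
    "rescale_video",
    "generate_clip",
    "generate_dataset",
]

#: BT.601 luma weights used when collapsing color frames to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class VideoVolume:
    """A grayscale video as a T x H x W intensity stack in [0, 1]."""

    frames: np.ndarray
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if 0 in self.frames.shape:
            raise ValueError("empty video volume")
        if not np.isfinite(self.frames).all():
            raise ValueError("video volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic clip.

    ``subject_seed`` controls geometry jitter (position offset, size +-15%,
    speed +-20%); ``clip_seed`` controls the noise draw.  ``snr_db`` may be
    ``math.inf`` for a noise-free render.
    """

    action_label: str
    subject_seed: int = 0
    clip_seed: int = 0
    n_frames: int = 60
    height: int = 60
    width: int = 60
    snr_db: float = 20.0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.action_label not in ACTION_REGISTRY:
            raise KeyError(
                f"unknown action {self.action_label!r}; "
                f"registry: {sorted(ACTION_REGISTRY)}"
            )
        if self.n_frames < 31:
            raise ValueError("n_frames must be >= 31 (largest temporal scale)")
        if math.isnan(self.snr_db):
            raise ValueError("snr_db must be finite or +inf")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _frame_to_float(img: np.ndarray, to_gray: bool) -> np.ndarray:
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / np.iinfo(img.dtype).max
    else:
        img = np.clip(img.astype(np.float64), 0.0, 1.0)
    if img.ndim == 3:
        if to_gray:
            img = img[..., :3] @ _LUMA
        else:
            img = img[..., 0]
    return img


def load_video(path: str, to_gray: bool = True, frame_rate: float = 25.0) -> VideoVolume:
    """Load a video container or a directory of numbered image frames.

    Intensities are linearly mapped to [0, 1]; color frames are converted
    to BT.601 luma when ``to_gray``.
    """
    if os.path.isdir(path):
        names = sorted(
            f for f in os.listdir(path)
            if f.lower().endswith((".png", ".pgm", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"))
        )
        if not names:
            raise ValueError(f"no image frames found in directory {path!r}")
        frames = [_frame_to_float(iio.imread(os.path.join(path, n)), to_gray) for n in names]
    else:
        if not os.path.exists(path):
            raise FileNotFoundError(f"cannot read video {path!r}")
        stack = iio.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_frame_to_float(f, to_gray) for f in stack]
    if len(frames) == 0:
        raise ValueError(f"zero frames in {path!r}")
    return VideoVolume(np.stack(frames), frame_rate=frame_rate)


def save_video(video: VideoVolume, path: str) -> None:
    """Write a video losslessly as a directory of 8-bit PNG frames."""
    os.makedirs(path, exist_ok=True)
    for t, frame in enumerate(video.frames):
        img = np.round(np.clip(frame, 0.0, 1.0) * 255).astype(np.uint8)
        iio.imwrite(os.path.join(path, f"frame_{t:05d}.png"), img)


def rescale_video(video: VideoVolume, factor: float) -> VideoVolume:
    """Spatially rescale every frame by ``factor`` (bilinear), e.g. 1.1 or 0.9."""
    if factor == 1.0:
        return video
    out = ndimage.zoom(video.frames, (1.0, factor, factor), order=1)
    return VideoVolume(np.clip(out, 0.0, 1.0), frame_rate=video.frame_rate)


# ---------------------------------------------------------------------------
# Renderers
# ---------------------------------------------------------------------------

_BG = 0.35
_FG = 0.55  # foreground amplitude above background
_EDGE = 1.0  # softness (pixels) of shape boundaries, for subpixel motion


def _soft(dist: np.ndarray) -> np.ndarray:
    """Smooth indicator of dist<=0 with a ~1-pixel transition band."""
    return 0.5 * (1.0 - np.tanh(dist / _EDGE))


@dataclass
class _Jitter:
    dx: float
    dy: float
    size: float
    speed: float
    phase: float


def _jitter(rng: np.random.Generator) -> _Jitter:
    return _Jitter(
        dx=rng.uniform(-5, 5),
        dy=rng.uniform(-5, 5),
        size=rng.uniform(0.85, 1.15),
        speed=rng.uniform(0.8, 1.2),
        phase=rng.uniform(0, 2 * np.pi),
    )


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:h, 0:w]
    return y.astype(np.float64), x.astype(np.float64)


def _bounce(pos: float, lo: float, hi: float) -> float:
    """Reflect a 1-D coordinate into [lo, hi] (triangular-wave folding)."""
    span = hi - lo
    if span <= 0:
        return lo
    p = (pos - lo) % (2 * span)
    return lo + (p if p <= span else 2 * span - p)


def _render_translating_bar(spec: SynthSpec, j: _Jitter) -> np.ndarray:
    h, w, T = spec.height, spec.width, spec.n_frames
    y, x = _grid(h, w)
    half_w = 3.0 * j.size * (w / 60.0)
    half_h = 0.30 * h * j.size
    cy = h / 2 + j.dy
    v = 1.2 * j.speed * (w / 60.0)
    frames = np.empty((T, h, w))
    for t in range(T):
        cx = _bounce(w * 0.2 + j.dx + v * t, half_w + 1, w - half_w - 1)
        d = np.maximum(np.abs(x - cx) - half_w, np.abs(y - cy) - half_h)
        frames[t] = _BG + _FG * _soft(d)
    return frames


def _render_oscillating_pair(spec: SynthSpec, j: _Jitter) -> np.ndarray:
    h, w, T = spec.height, spec.width, spec.n_frames
    y, x = _grid(h, w)
    half_h = 2.5 * j.size * (h / 60.0)
    half_w = 0.30 * w * j.size
    cx = w / 2 + j.dx
    gap = 0.18 * h * j.size
    amp = 0.10 * h * j.size
    omega = 2 * np.pi * 0.08 * j.speed
    frames = np.empty((T, h, w))
    for t in range(T):
        off = amp * np.sin(omega * t + j.phase)
        c1 = h / 2 + j.dy - gap + off
        c2 = h / 2 + j.dy + gap - off
        d1 = np.maximum(np.abs(y - c1) - half_h, np.abs(x - cx) - half_w)
        d2 = np.maximum(np.abs(y - c2) - half_h, np.abs(x - cx) - half_w)
        frames[t] = _BG + _FG * np.maximum(_soft(d1), _soft(d2))
    return frames


def _render_expanding_blob(spec: SynthSpec, j: _Jitter) -> np.ndarray:
    h, w, T = spec.height, spec.width, spec.n_frames
    y, x = _grid(h, w)
    cy, cx = h / 2 + j.dy, w / 2 + j.dx
    r0 = 0.14 * min(h, w) * j.size
    omega = 2 * np.pi * 0.07 * j.speed
    rr = np.hypot(y - cy, x - cx)
    frames = np.empty((T, h, w))
    for t in range(T):
        r = r0 * (1.0 + 0.55 * np.sin(omega * t + j.phase))
        frames[t] = _BG + _FG * _soft(rr - r)
    return frames


def _render_bouncing_dot(spec: SynthSpec, j: _Jitter) -> np.ndarray:
    h, w, T = spec.height, spec.width, spec.n_frames
    y, x = _grid(h, w)
    r = 3.2 * j.size * (min(h, w) / 60.0)
    vx = 1.4 * j.speed * (w / 60.0)
    vy = 0.9 * j.speed * (h / 60.0)
    frames = np.empty((T, h, w))
    for t in range(T):
        cx = _bounce(w * 0.3 + j.dx + vx * t, r + 1, w - r - 1)
        cy = _bounce(h * 0.4 + j.dy + vy * t, r + 1, h - r - 1)
        frames[t] = _BG + _FG * _soft(np.hypot(y - cy, x - cx) - r)
    return frames


ACTION_REGISTRY = {
    "translating_bar": _render_translating_bar,
    "oscillating_pair": _render_oscillating_pair,
    "expanding_blob": _render_expanding_blob,
    "bouncing_dot": _render_bouncing_dot,
}

_ACTION_IDS = {name: i for i, name in enumerate(sorted(ACTION_REGISTRY))}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def render_clean(spec: SynthSpec) -> VideoVolume:
    """Noise-free render of a clip (geometry fully set by subject_seed)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([_ACTION_IDS[spec.action_label], spec.subject_seed & 0x7FFFFFFF])
    )
    frames = ACTION_REGISTRY[spec.action_label](spec, _jitter(rng))
    if spec.scale_factor != 1.0:
        frames = ndimage.zoom(frames, (1.0, spec.scale_factor, spec.scale_factor), order=1)
    return VideoVolume(np.clip(frames, 0.0, 1.0))


def generate_clip(spec: SynthSpec) -> tuple[VideoVolume, str]:
    """Render one clip with calibrated Gaussian pixel noise.

    The noise standard deviation is Std_signal * 10**(-snr_db/20), with
    Std_signal the standard deviation of the clean render about its mean.
    Returns the volume and the action label.
    """
    clean = render_clean(spec)
    if math.isinf(spec.snr_db):
        return clean, spec.action_label
    sig_std = float(clean.frames.std())
    noise_std = sig_std * 10.0 ** (-spec.snr_db / 20.0)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [
                _ACTION_IDS[spec.action_label],
                spec.subject_seed & 0x7FFFFFFF,
                spec.clip_seed & 0x7FFFFFFF,
                0x5EED,
            ]
        )
    )
    noisy = clean.frames + rng.normal(0.0, noise_std, size=clean.frames.shape)
    return VideoVolume(np.clip(noisy, 0.0, 1.0)), spec.action_label


@dataclass
class DatasetItem:
    video: VideoVolume
    label: str
    subject_id: int
    spec: SynthSpec = field(repr=False, default=None)  # type: ignore[assignment]


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(
    n_subjects: int,
    clips_per_subject: int,
    labels: list[str],
    seed: int = 0,
    n_frames: int = 60,
    height: int = 60,
    width: int = 60,
    snr_db: float = 20.0,
    scale_factor: float = 1.0,
) -> list[DatasetItem]:
    """Balanced synthetic dataset: every subject performs every label.

    Returns ``n_subjects * clips_per_subject * len(labels)`` items with
    subject ids recorded for grouped (leave-one-subject-out) splits.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 for grouped cross-validation")
    if clips_per_subject < 1:
        raise ValueError("clips_per_subject must be >= 1")
    items: list[DatasetItem] = []
    for subj in range(n_subjects):
        for label in labels:
            for clip in range(clips_per_subject):
                spec = SynthSpec(
                    action_label=label,
                    subject_seed=_derived_seed(seed, 1, subj),
                    clip_seed=_derived_seed(seed, 2, subj, _ACTION_IDS[label], clip),
                    n_frames=n_frames,
                    height=height,
                    width=width,
                    snr_db=snr_db,
                    scale_factor=scale_factor,
                )
                video, lab = generate_clip(spec)
                items.append(DatasetItem(video=video, label=lab, subject_id=subj, spec=spec))
    return items
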