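"""Spatiotemporal interest-point detection with the cuboid response.

The response is R = (V*g*h_ev)^2 + (V*g*h_od)^2 where g is a 2-D spatial
Gaussian and (h_ev, h_od) a temporal quadrature pair of 1-D Gabor filters

    h_ev(t) = -cos(2 pi omega t) exp(-t^2 / tau^2)
    h_od(t) = -sin(2 pi omega t) exp(-t^2 / tau^2)

Both temporal filters are mean-subtracted so that a temporally constant
video yields exactly zero response (h_od is already odd; the correction
removes the DC leakage of h_ev).  Interest points are strict local maxima
of R above a fraction of the per-clip maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from nasrec.synthvid import VideoVolume

__all__ = [
    "DetectorParams",
    "InterestPoint",
    "cuboid_response",
    "detect_interest_points",
    "points_to_tsv",
]


@dataclass(frozen=True)
class DetectorParams:
    """Detector configuration.

    omega defaults to 4/tau (the original cuboid-detector convention).
    min_response_frac discards maxima below that fraction of the clip's
    maximum response; nms_radius is the (dx, dy, dt) half-size of the
    local-maximum neighborhood.
    """

    sigma_spatial: float = 2.0
    tau_temporal: float = 3.0
    omega: float | None = None
    max_points: int = 200
    min_response_frac: float = 0.05
    nms_radius: tuple[int, int, int] = (4, 4, 3)

    def __post_init__(self) -> None:
        if self.sigma_spatial <= 0 or self.tau_temporal <= 0:
            raise ValueError("sigma_spatial and tau_temporal must be positive")
        if not 0 <= self.min_response_frac < 1:
            raise ValueError("min_response_frac must lie in [0, 1)")

    @property
    def omega_eff(self) -> float:
        return 4.0 / self.tau_temporal if self.omega is None else self.omega


@dataclass(frozen=True)
class InterestPoint:
    x: int  # column
    y: int  # row
    t: int  # frame
    response: float


def temporal_filters(p: DetectorParams) -> tuple[np.ndarray, np.ndarray]:
    """Mean-subtracted quadrature pair, truncated at +-3*tau frames."""
    half = int(np.ceil(3.0 * p.tau_temporal))
    t = np.arange(-half, half + 1, dtype=np.float64)
    env = np.exp(-(t**2) / p.tau_temporal**2)
    h_ev = -np.cos(2 * np.pi * p.omega_eff * t) * env
    h_od = -np.sin(2 * np.pi * p.omega_eff * t) * env
    h_ev -= h_ev.mean()
    h_od -= h_od.mean()
    return h_ev, h_od


def spatial_kernel(p: DetectorParams) -> np.ndarray:
    """1-D Gaussian section of the (separable) 2-D spatial kernel, +-3*sigma."""
    half = int(np.ceil(3.0 * p.sigma_spatial))
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2 * p.sigma_spatial**2))
    return g / g.sum()


def cuboid_response(v: VideoVolume, p: DetectorParams | None = None) -> np.ndarray:
    """Cuboid detector response volume, same T x H x W shape as the input.

    Convolutions use reflection padding at all borders; raises ValueError
    if the clip is shorter than the temporal filter support.
    """
    p = p or DetectorParams()
    h_ev, h_od = temporal_filters(p)
    if v.n_frames < len(h_ev):
        raise ValueError(
            f"video has {v.n_frames} frames; temporal filter support is {len(h_ev)}"
        )
    g = spatial_kernel(p)
    smoothed = ndimage.correlate1d(v.frames, g, axis=1, mode="reflect")
    smoothed = ndimage.correlate1d(smoothed, g, axis=2, mode="reflect")
    # correlate with reversed kernel == convolve; both filters are symmetric
    # or antisymmetric, but use explicit convolution semantics for clarity.
    even = ndimage.convolve1d(smoothed, h_ev, axis=0, mode="reflect")
    odd = ndimage.convolve1d(smoothed, h_od, axis=0, mode="reflect")
    return even**2 + odd**2


def detect_interest_points(
    v: VideoVolume, p: DetectorParams | None = None, response: np.ndarray | None = None
) -> list[InterestPoint]:
    """Strict local maxima of the cuboid response, sorted by response desc.

    Maxima below min_response_frac * max(R) are discarded; greedy
    non-maximum suppression enforces one point per nms_radius
    neighborhood; at most max_points are returned.  An all-zero response
    yields an empty list.
    """
    p = p or DetectorParams()
    r = cuboid_response(v, p) if response is None else response
    rmax = float(r.max())
    # roundoff floor: mean-subtracted filters leave ~1e-30 residue on
    # temporally constant input, far below any genuine motion response
    if rmax <= 1e-18:
        return []
    dt, dy, dx = p.nms_radius[2], p.nms_radius[1], p.nms_radius[0]
    footprint = np.ones((2 * dt + 1, 2 * dy + 1, 2 * dx + 1), dtype=bool)
    local_max = r >= ndimage.maximum_filter(r, footprint=footprint, mode="reflect")
    thresh = max(p.min_response_frac * rmax, 0.0)
    cand = np.argwhere(local_max & (r > thresh) & (r > 0))
    if cand.size == 0:
        return []
    scores = r[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -scores))
    kept: list[InterestPoint] = []
    kept_coords: list[np.ndarray] = []
    for idx in order:
        c = cand[idx]
        ok = True
        for kc in kept_coords:
            if (
                abs(int(c[0]) - int(kc[0])) <= dt
                and abs(int(c[1]) - int(kc[1])) <= dy
                and abs(int(c[2]) - int(kc[2])) <= dx
            ):
                ok = False
                break
        if ok:
            kept.append(
                InterestPoint(x=int(c[2]), y=int(c[1]), t=int(c[0]), response=float(scores[idx]))
            )
            kept_coords.append(c)
            if len(kept) >= p.max_points:
                break
    return kept


def points_to_tsv(points: list[InterestPoint]) -> str:
    """Serialize points as TSV with a header line (0-based coordinates)."""
    lines = ["x\ty\tt\tresponse"]
    for pt in points:
        lines.append(f"{pt.x}\t{pt.y}\t{pt.t}\t{pt.response:.10g}")
    return "\n".join(lines) + "\n"
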