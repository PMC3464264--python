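"""Per-scale independent-component filter banks and their Gabor summaries.

Patch-sequence vectors are whitened by PCA and unmixed by symmetric
fixed-point ICA; each resulting filter, viewed as a short sequence of
13x13 frames, is summarized by a fitted 2-D Gabor function

    G(x, y) = A exp(-(x'^2/(2 sx^2) + y'^2/(2 sy^2))) cos(2 pi f x' + phi)

with (x', y') the point (x - x0, y - y0) rotated by theta.  Six of the
fitted parameters -- envelope location (x0, y0), envelope scales
(sx, sy), carrier orientation theta and phase phi -- form the canonical
descriptor on which ICs are clustered by K-means with plain Euclidean
distance.  The carrier frequency f is fitted (the function is ill-defined
without it) but excluded from the clustering descriptor.

Parameter canonicalization exploits the Gabor symmetries: theta is
reduced to [0, pi) (each pi-flip negates the phase), phi to [0, 2 pi),
scales are positive with sx >= sy (axis swap rotates theta by pi/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, FastICA

from nasrec.patches import circular_mask

__all__ = [
    "ICBasis",
    "GaborFit",
    "GaborSequenceFit",
    "ICClusterModel",
    "fit_ica",
    "component_to_volume",
    "fit_gabor",
    "gabor_frame",
    "canonicalize",
    "cluster_ics",
]


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class ICBasis:
    """Unit-norm IC filters for one scale plus whitening provenance."""

    scale_id: int
    components: np.ndarray       # (n_ic, l), unit-norm rows
    mean: np.ndarray             # (l,) training mean subtracted before projection
    variance_retained: float     # fraction of variance kept by the PCA step
    n_ic: int

    def project(self, patches: np.ndarray) -> np.ndarray:
        """Filter responses P.A for a (n, l) batch (or (l,) vector)."""
        return (np.atleast_2d(patches) - self.mean) @ self.components.T


def fit_ica(patches: np.ndarray, n_ic: int, seed: int = 0, scale_id: int = 0,
            max_iter: int = 500, tol: float = 1e-5) -> ICBasis:
    """PCA-whitening to n_ic dimensions followed by symmetric FastICA.

    Deterministic given ``seed``.  Requires n_samples >= 5 * n_ic and
    n_ic <= rank of the data.  On non-convergence the best iterate is
    kept (scikit-learn emits a ConvergenceWarning).
    """
    X = np.asarray(patches, dtype=np.float64)
    n, l = X.shape
    if n < 5 * n_ic:
        raise ValueError(f"need >= {5 * n_ic} samples for {n_ic} ICs, got {n}")
    if n_ic > min(n, l):
        raise ValueError(f"n_ic={n_ic} exceeds data rank bound {min(n, l)}")
    pca = PCA(n_components=n_ic, whiten=True, random_state=seed)
    Z = pca.fit_transform(X)
    if pca.explained_variance_[-1] <= 1e-12:
        raise ValueError(f"data rank is below n_ic={n_ic}")
    ica = FastICA(whiten=False, algorithm="parallel", fun="logcosh",
                  max_iter=max_iter, tol=tol, random_state=seed)
    ica.fit(Z)
    whitener = pca.components_ / np.sqrt(pca.explained_variance_)[:, None]
    filters = ica.components_ @ whitener        # (n_ic, l): s = (X - mean) @ F.T
    filters /= np.linalg.norm(filters, axis=1, keepdims=True)
    return ICBasis(
        scale_id=scale_id,
        components=filters,
        mean=pca.mean_.copy(),
        variance_retained=float(pca.explained_variance_ratio_.sum()),
        n_ic=n_ic,
    )


def component_to_volume(vec: np.ndarray, diameter: int = 13, duration: int = 11) -> np.ndarray:
    """Unflatten a masked patch/filter vector back to duration x d x d.

    Out-of-mask pixels are zero-filled.
    """
    mask, order = circular_mask(diameter)
    vol = np.zeros((duration, diameter * diameter))
    vol[:, order] = np.asarray(vec).reshape(duration, len(order))
    return vol.reshape(duration, diameter, diameter)


# ---------------------------------------------------------------------------
# Gabor fitting
# ---------------------------------------------------------------------------

@dataclass
class GaborFit:
    """Fitted Gabor parameters for one frame (pixel units)."""

    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    theta: float
    phi: float
    freq: float
    r2: float = 0.0
    amplitude: float = 0.0
    degenerate: bool = False

    def params6(self) -> np.ndarray:
        """The canonical 6-vector used for IC clustering (freq excluded)."""
        return np.array([self.x0, self.y0, self.sigma_x, self.sigma_y, self.theta, self.phi])


@dataclass
class GaborSequenceFit:
    """Per-frame fits of one IC plus the highest-energy-frame summary."""

    frames: list[GaborFit]
    summary: GaborFit
    summary_frame: int


def gabor_frame(shape: tuple[int, int], x0: float, y0: float, sigma_x: float,
                sigma_y: float, theta: float, phi: float, freq: float,
                amplitude: float = 1.0) -> np.ndarray:
    """Render the Gabor model on a pixel grid (rows = y, cols = x)."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    ct, st = np.cos(theta), np.sin(theta)
    xp = (x - x0) * ct + (y - y0) * st
    yp = -(x - x0) * st + (y - y0) * ct
    env = np.exp(-(xp**2 / (2 * sigma_x**2) + yp**2 / (2 * sigma_y**2)))
    return amplitude * env * np.cos(2 * np.pi * freq * xp + phi)


def _gabor_residual(p: np.ndarray, ycoord: np.ndarray, xcoord: np.ndarray,
                    data: np.ndarray) -> np.ndarray:
    amp, x0, y0, sx, sy, th, ph, f = p
    ct, st = np.cos(th), np.sin(th)
    xp = (xcoord - x0) * ct + (ycoord - y0) * st
    yp = -(xcoord - x0) * st + (ycoord - y0) * ct
    model = amp * np.exp(-(xp**2 / (2 * sx**2) + yp**2 / (2 * sy**2))) * np.cos(
        2 * np.pi * f * xp + ph
    )
    return model - data


def _init_from_spectrum(frame: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """(theta, freq, phi) initial guess from the FFT peak of the frame."""
    F = np.fft.fftshift(np.fft.fft2(frame * mask))
    h, w = frame.shape
    cy, cx = h // 2, w // 2
    mag = np.abs(F)
    mag[cy, cx] = 0.0  # ignore DC
    ky, kx = np.unravel_index(int(np.argmax(mag)), mag.shape)
    fy = (ky - cy) / h
    fx = (kx - cx) / w
    freq = float(np.hypot(fx, fy))
    theta = float(np.arctan2(fy, fx)) % np.pi
    phi = float(np.angle(F[ky, kx]))
    return theta, max(freq, 0.02), phi


def _fit_gabor_frame(frame: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                     n_restarts: int = 4) -> GaborFit:
    h, w = frame.shape
    data = frame[mask]
    ss_tot = float(((data - data.mean()) ** 2).sum())
    if ss_tot <= 1e-20:
        # degenerate (e.g. all-zero) frame; sentinel parameters, r2 = 0
        return GaborFit(x0=w / 2, y0=h / 2, sigma_x=1.0, sigma_y=1.0, theta=0.0,
                        phi=0.0, freq=0.0, r2=0.0, amplitude=0.0, degenerate=True)
    ycoord, xcoord = np.mgrid[0:h, 0:w].astype(np.float64)
    ycoord, xcoord = ycoord[mask], xcoord[mask]

    energy = frame**2
    etot = energy.sum()
    x0 = float((np.arange(w)[None, :] * energy).sum() / etot)
    y0 = float((np.arange(h)[:, None] * energy).sum() / etot)
    sx0 = max(float(np.sqrt(((np.arange(w)[None, :] - x0) ** 2 * energy).sum() / etot)), 0.8)
    sy0 = max(float(np.sqrt(((np.arange(h)[:, None] - y0) ** 2 * energy).sum() / etot)), 0.8)
    theta0, freq0, phi0 = _init_from_spectrum(frame, mask)
    amp0 = float(np.abs(data).max())

    lo = [-10 * amp0 - 1e-6, -w, -h, 0.3, 0.3, -np.inf, -np.inf, 0.005]
    hi = [10 * amp0 + 1e-6, 2 * w, 2 * h, 4 * w, 4 * h, np.inf, np.inf, 0.5]
    starts = [np.array([amp0, x0, y0, max(sx0, sy0), min(sx0, sy0), theta0, phi0, freq0])]
    for _ in range(n_restarts):
        starts.append(np.array([
            amp0 * rng.uniform(0.5, 1.5),
            x0 + rng.uniform(-1.5, 1.5),
            y0 + rng.uniform(-1.5, 1.5),
            max(sx0, sy0) * rng.uniform(0.7, 1.4),
            min(sx0, sy0) * rng.uniform(0.7, 1.4),
            theta0 + rng.uniform(-0.4, 0.4),
            rng.uniform(0, 2 * np.pi),
            np.clip(freq0 * rng.uniform(0.7, 1.4), 0.01, 0.45),
        ]))
    best, best_cost = None, np.inf
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            res = optimize.least_squares(
                _gabor_residual, p0, args=(ycoord, xcoord, data),
                bounds=(lo, hi), method="trf", max_nfev=400, xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        return GaborFit(x0=w / 2, y0=h / 2, sigma_x=1.0, sigma_y=1.0, theta=0.0,
                        phi=0.0, freq=0.0, r2=0.0, amplitude=0.0, degenerate=True)
    amp, x0, y0, sx, sy, th, ph, f = best.x
    r2 = 1.0 - float((best.fun**2).sum()) / ss_tot
    fit = GaborFit(x0=float(x0), y0=float(y0), sigma_x=float(sx), sigma_y=float(sy),
                   theta=float(th), phi=float(ph), freq=float(f), r2=r2,
                   amplitude=float(amp))
    return canonicalize(fit)


def fit_gabor(component: np.ndarray, seed: int = 0, mask: np.ndarray | None = None,
              frames: str = "all", n_restarts: int = 4) -> GaborSequenceFit:
    """Fit Gabor functions to an IC given as a duration x h x w volume.

    Each frame is fitted independently by seeded multi-start nonlinear
    least squares (FFT-derived start plus 4 jittered restarts).  The
    summary fit is the fit of the highest-energy frame.  With
    ``frames="summary"`` only that frame is fitted (the per-frame list
    then holds the summary at its position and degenerate placeholders
    elsewhere), which is what the codebook pipeline uses.
    """
    component = np.asarray(component, dtype=np.float64)
    if component.ndim == 2:
        component = component[None]
    T, h, w = component.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool) if h != w or h % 2 == 0 else circular_mask(h)[0]
    energies = (component**2).reshape(T, -1).sum(axis=1)
    if energies.max() <= 0:
        raise ValueError("component has zero energy")
    top = int(np.argmax(energies))
    rng = np.random.default_rng(seed)
    fits: list[GaborFit] = []
    if frames == "all":
        for t in range(T):
            fits.append(_fit_gabor_frame(component[t], mask, rng, n_restarts))
    elif frames == "summary":
        placeholder = GaborFit(x0=w / 2, y0=h / 2, sigma_x=1.0, sigma_y=1.0,
                               theta=0.0, phi=0.0, freq=0.0, r2=0.0,
                               amplitude=0.0, degenerate=True)
        fits = [placeholder] * T
        fits[top] = _fit_gabor_frame(component[top], mask, rng, n_restarts)
    else:
        raise ValueError("frames must be 'all' or 'summary'")
    return GaborSequenceFit(frames=fits, summary=fits[top], summary_frame=top)


def canonicalize(fit: GaborFit) -> GaborFit:
    """Map Gabor parameters to their canonical intervals.

    Scales made positive and ordered sigma_x >= sigma_y (axis swap adds
    pi/2 to theta); a negative amplitude is folded into a pi phase shift;
    theta reduced mod pi with the compensating phase flip phi -> -phi per
    pi step; phi reduced mod 2 pi.  The envelope location is left
    unconverted.  Idempotent.
    """
    sx, sy = abs(fit.sigma_x), abs(fit.sigma_y)
    th, ph, amp = fit.theta, fit.phi, fit.amplitude
    if amp < 0:
        amp, ph = -amp, ph + np.pi
    if sx < sy:
        sx, sy = sy, sx
        th = th + np.pi / 2
    # reduce theta mod pi; each pi step negates the phase
    k = np.floor(th / np.pi)
    th = th - k * np.pi
    if int(k) % 2 != 0:
        ph = -ph
    if th >= np.pi:  # roundoff: a tiny negative theta reduces to exactly pi
        th -= np.pi
        ph = -ph
    ph = ph % (2 * np.pi)
    if ph >= 2 * np.pi:  # same roundoff at the phase boundary
        ph -= 2 * np.pi
    return GaborFit(x0=fit.x0, y0=fit.y0, sigma_x=sx, sigma_y=sy, theta=float(th),
                    phi=float(ph), freq=abs(fit.freq), r2=fit.r2,
                    amplitude=amp, degenerate=fit.degenerate)


# ---------------------------------------------------------------------------
# IC clustering
# ---------------------------------------------------------------------------

@dataclass
class ICClusterModel:
    """K-means partition of ICs in the 6-d canonical Gabor parameter space."""

    scale_id: int
    n_clusters: int
    centroids: np.ndarray        # (n_clusters, 6)
    assignment: np.ndarray       # (n_ic,) cluster index per IC

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)


def cluster_ics(fits: list[GaborFit], n_clusters: int, seed: int = 0,
                scale_id: int = 0) -> ICClusterModel:
    """Cluster IC Gabor descriptors with K-means (k-means++, 10 restarts).

    Plain Euclidean distance on (x0, y0, sigma_x, sigma_y, theta, phi),
    no standardization.  scikit-learn's K-means relocates empty clusters
    to far points, so every cluster is nonempty.
    """
    X = np.stack([f.params6() for f in fits])
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_clusters > n_distinct:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds {n_distinct} distinct descriptors"
        )
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return ICClusterModel(scale_id=scale_id, n_clusters=n_clusters,
                          centroids=km.cluster_centers_, assignment=labels)
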