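"""NAS codebook: RMS cluster features, structural clusters and selection.

A patch-sequence vector P is mapped to one nonnegative feature per IC
cluster,

    a_i = sqrt( (1/m_i) sum_{j in cluster i} (P . A_j)^2 ),

the root mean square of its projections on the cluster's m_i filters.
Per scale, K-means over these feature vectors yields structural clusters;
a natural action structure (NAS) is the triple of structural-cluster
indices a patch sequence receives at the three coupled scales.  NASs
occurring more than Mc times in training survive, and for every ordered
class pair the Nc survivors with the largest frequency margin are kept;
the union is the discriminative NAS vocabulary.  Histograms of selected
NASs, optionally pooled over an n-m-k spatial-temporal grid, are the
code-word representation consumed by the classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from nasrec.icbank import ICBasis, ICClusterModel

__all__ = [
    "feature_vector",
    "feature_matrix",
    "StructuralClusterModel",
    "fit_structural_clusters",
    "assign_structural",
    "assign_nas",
    "NASSelection",
    "select_nas",
    "NASHistogram",
    "nas_histogram",
    "nas_sharing_stats",
    "nas_correlation",
    "nas_info_content",
]

NASIndex = tuple[int, ...]


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _cluster_pool(ic_model: ICClusterModel) -> list[np.ndarray]:
    return [ic_model.members(c) for c in range(ic_model.n_clusters)]


def feature_matrix(patches: np.ndarray, basis: ICBasis, ic_model: ICClusterModel) -> np.ndarray:
    """RMS cluster features for a (n, l) batch -> (n, n_clusters)."""
    P = np.atleast_2d(np.asarray(patches, dtype=np.float64))
    if P.shape[1] != basis.components.shape[1]:
        raise ValueError(
            f"patch length {P.shape[1]} != filter length {basis.components.shape[1]}"
        )
    proj2 = (P @ basis.components.T) ** 2
    out = np.empty((P.shape[0], ic_model.n_clusters))
    for c, members in enumerate(_cluster_pool(ic_model)):
        out[:, c] = np.sqrt(proj2[:, members].mean(axis=1))
    return out


def feature_vector(patch: np.ndarray, basis: ICBasis, ic_model: ICClusterModel) -> np.ndarray:
    """RMS cluster features of a single flattened patch vector."""
    return feature_matrix(patch[None], basis, ic_model)[0]


# ---------------------------------------------------------------------------
# Structural clusters / NAS assignment
# ---------------------------------------------------------------------------

@dataclass
class StructuralClusterModel:
    scale_id: int
    n_clusters: int
    centroids: np.ndarray  # (n_clusters, n_features)

    def assign(self, features: np.ndarray) -> np.ndarray:
        """Nearest-centroid index per row; ties go to the lowest index."""
        F = np.atleast_2d(features)
        d2 = ((F[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def fit_structural_clusters(features: np.ndarray, n_clusters: int, seed: int = 0,
                            scale_id: int = 0) -> StructuralClusterModel:
    """Seeded K-means (k-means++, 5 restarts) over RMS feature vectors."""
    F = np.asarray(features, dtype=np.float64)
    if F.shape[0] < n_clusters:
        raise ValueError(f"{F.shape[0]} samples < {n_clusters} clusters")
    km = KMeans(n_clusters=n_clusters, n_init=5, random_state=seed)
    km.fit(F)
    return StructuralClusterModel(scale_id=scale_id, n_clusters=n_clusters,
                                  centroids=km.cluster_centers_)


def assign_structural(features_per_scale: list[np.ndarray],
                      models: list[StructuralClusterModel]) -> list[NASIndex]:
    """Batch NAS assignment from per-scale feature matrices (aligned rows)."""
    if len(features_per_scale) != len(models):
        raise ValueError("one feature matrix per structural model required")
    per_scale = [m.assign(f) for f, m in zip(features_per_scale, models)]
    return [tuple(int(per_scale[s][i]) for s in range(len(models)))
            for i in range(len(per_scale[0]))]


def assign_nas(feature_triple: list[np.ndarray],
               models: list[StructuralClusterModel]) -> NASIndex:
    """NAS index of one patch-sequence triple given fitted per-scale models."""
    for m in models:
        if m.centroids is None or len(m.centroids) == 0:
            raise RuntimeError("structural model not fitted")
    return assign_structural([f[None] if f.ndim == 1 else f for f in feature_triple], models)[0]


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass
class NASSelection:
    Mc: int
    Nc: int
    selected: list[NASIndex]
    provenance: dict[NASIndex, list[tuple[tuple[str, str], int]]] = field(default_factory=dict)

    @property
    def index(self) -> dict[NASIndex, int]:
        return {nas: i for i, nas in enumerate(self.selected)}


def select_nas(table: pd.DataFrame, labels: list[str], Mc: int, Nc: int) -> NASSelection:
    """Discriminative NAS selection from a per-video count table.

    ``table``: rows = videos, columns = NAS indices (tuples), values =
    occurrence counts; ``labels``: class label per row.  NASs with total
    training occurrences <= Mc are dropped.  For every ordered class pair
    (A, B) the survivors are ranked by the margin f_A - f_B of mean
    per-video relative frequencies (descending), ties broken by smaller
    f_B then smaller NAS id (lexicographic tuple order); the top Nc per
    pair are kept and the union, in pair-then-rank order, is the
    selection.
    """
    if Nc < 1:
        raise ValueError("Nc must be >= 1")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes for discriminative selection")
    table = table.reindex(sorted(table.columns), axis=1)
    totals = table.sum(axis=0)
    survivors = totals.index[totals > Mc]
    if len(survivors) == 0:
        return NASSelection(Mc=Mc, Nc=Nc, selected=[])
    row_tot = table.sum(axis=1).replace(0, 1)
    rel = table[survivors].div(row_tot, axis=0)
    lab = np.asarray(labels)
    freq = {c: rel[lab == c].mean(axis=0) for c in classes}

    selected: list[NASIndex] = []
    seen: set[NASIndex] = set()
    provenance: dict[NASIndex, list[tuple[tuple[str, str], int]]] = {}
    for a in classes:
        for b in classes:
            if a == b:
                continue
            score = freq[a] - freq[b]
            # descending score, then ascending f_B, then ascending NAS id
            order = sorted(
                survivors,
                key=lambda n: (-score[n], freq[b][n], n),
            )
            for rank, nas in enumerate(order[:Nc]):
                provenance.setdefault(nas, []).append(((a, b), rank))
                if nas not in seen:
                    seen.add(nas)
                    selected.append(nas)
    return NASSelection(Mc=Mc, Nc=Nc, selected=selected, provenance=provenance)


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

@dataclass
class NASHistogram:
    """Per-grid-cell counts of selected NASs for one video.

    counts has shape (n*m*k, n_selected); cells are ordered y-band major,
    then x-band, then t-band; NAS columns follow the selection order.
    """

    video_id: str
    counts: np.ndarray
    grid: tuple[int, int, int]

    @property
    def vector(self) -> np.ndarray:
        return self.counts.ravel()

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _band(coord: float, extent: float, nbands: int) -> int:
    # equal-width half-open bands, last band closed
    return min(int(coord * nbands / extent), nbands - 1)


def nas_histogram(point_nas: list[tuple[tuple[int, int, int], NASIndex]],
                  selection: NASSelection, grid: tuple[int, int, int],
                  dims: tuple[int, int, int], video_id: str = "") -> NASHistogram:
    """Pool selected-NAS occurrences over an n-m-k grid.

    ``point_nas``: ((y, x, t), nas) per interest point; ``dims``:
    (H, W, T) of the video.  Points whose NAS is not selected are
    dropped; each retained point increments the cell containing it.
    """
    n, m, k = grid
    if n * m * k < 1:
        raise ValueError("grid must have at least one cell")
    H, W, T = dims
    idx = selection.index
    counts = np.zeros((n * m * k, len(selection.selected)), dtype=np.int64)
    for (y, x, t), nas in point_nas:
        col = idx.get(nas)
        if col is None:
            continue
        cell = (_band(y, H, n) * m + _band(x, W, m)) * k + _band(t, T, k)
        counts[cell, col] += 1
    return NASHistogram(video_id=video_id, counts=counts, grid=grid)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def nas_sharing_stats(table: pd.DataFrame, labels: list[str]) -> tuple[pd.Series, pd.Series]:
    """How many classes each NAS occurs in, plus the sharing distribution.

    A NAS occurs in a class iff its total count over that class's videos
    is >= 1.  NASs absent everywhere are excluded.  The distribution over
    sharing levels 1..n_classes is in percent and sums to 100.
    """
    lab = np.asarray(labels)
    classes = sorted(set(labels))
    per_class = pd.DataFrame({c: table[lab == c].sum(axis=0) for c in classes})
    levels = (per_class >= 1).sum(axis=1)
    levels = levels[levels > 0]
    dist = levels.value_counts().reindex(range(1, len(classes) + 1), fill_value=0)
    dist = 100.0 * dist / len(levels) if len(levels) else dist.astype(float)
    return levels, dist


def nas_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between per-video count vectors of NAS pairs.

    Zero-variance NASs get all their correlations (incl. the diagonal)
    defined as 0.
    """
    if table.shape[0] < 3:
        raise ValueError("need >= 3 videos for correlations")
    X = table.to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    bad = sd == 0
    C[bad, :] = 0.0
    C[:, bad] = 0.0
    C = np.nan_to_num(C, nan=0.0)
    return pd.DataFrame(C, index=table.columns, columns=table.columns)


def nas_info_content(table: pd.DataFrame, labels: list[str],
                     var_floor: float = 1e-6, relative: bool = False) -> pd.DataFrame:
    """Per-NAS, per-class one-vs-rest accuracy of a Gaussian frequency model.

    For each NAS and class, univariate Gaussians are fitted to the
    per-video relative frequency under "class" and "rest" (variance
    floored), and each video is classified leave-one-video-out by the
    higher likelihood with equal priors.  Classes with fewer than 2
    videos are skipped with a warning.  With ``relative=True`` the table
    is taken to hold per-video frequencies already and is not
    renormalized.
    """
    lab = np.asarray(labels)
    classes = sorted(set(labels))
    if relative:
        rel = table.to_numpy(dtype=np.float64)
    else:
        row_tot = table.sum(axis=1).replace(0, 1)
        rel = table.div(row_tot, axis=0).to_numpy(dtype=np.float64)
    n_videos = rel.shape[0]
    out = {}
    for c in classes:
        in_c = lab == c
        if in_c.sum() < 2 or (~in_c).sum() < 2:
            warnings.warn(f"class {c!r} has too few videos; skipped")
            continue
        correct = np.zeros(rel.shape[1])
        for i in range(n_videos):
            keep = np.arange(n_videos) != i
            g1 = rel[keep & in_c]
            g0 = rel[keep & ~in_c]
            mu1, mu0 = g1.mean(axis=0), g0.mean(axis=0)
            v1 = np.maximum(g1.var(axis=0), var_floor)
            v0 = np.maximum(g0.var(axis=0), var_floor)
            x = rel[i]
            ll1 = -0.5 * np.log(v1) - (x - mu1) ** 2 / (2 * v1)
            ll0 = -0.5 * np.log(v0) - (x - mu0) ** 2 / (2 * v0)
            pred_c = ll1 >= ll0
            correct += pred_c == in_c[i]
        out[c] = correct / n_videos
    return pd.DataFrame(out, index=table.columns)
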