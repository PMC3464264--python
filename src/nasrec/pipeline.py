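"""End-to-end orchestration: codebook building, training and evaluation.

The pipeline runs detector -> patches -> IC bank -> codebook on training
videos only, then encodes every video as a histogram of selected NASs
and trains either classifier.  Grouped cross-validation
(leave-one-subject-out) keeps all clips of one subject out per fold, so
no subject identity leaks between fitting and testing.  Robustness
variants re-extract features from spatially rescaled test videos with
the fold's trained models, or add calibrated noise to both halves and
retrain.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nasrec import classify as _classify
from nasrec.codebook import (
    NASIndex,
    NASSelection,
    assign_structural,
    feature_matrix,
    fit_structural_clusters,
    nas_histogram,
    select_nas,
)
from nasrec.config import PipelineConfig
from nasrec.detector import detect_interest_points
from nasrec.icbank import cluster_ics, component_to_volume, fit_ica, fit_gabor
from nasrec.patches import circular_mask, extract_patches
from nasrec.synthvid import DatasetItem, VideoVolume, rescale_video

logger = logging.getLogger("nasrec")

__all__ = [
    "VideoFeatures",
    "NASCodebook",
    "extract_video_features",
    "build_codebook",
    "encode_video",
    "ProtocolResult",
    "run_protocol",
    "train_eval",
]


# ---------------------------------------------------------------------------
# Per-video feature extraction (label-independent; cacheable)
# ---------------------------------------------------------------------------

@dataclass
class VideoFeatures:
    """Interest points and patch-sequence triples of one video."""

    coords: np.ndarray    # (n_points, 3) as (y, x, t)
    patches: np.ndarray   # (n_points, n_scales, l)
    dims: tuple[int, int, int]  # (H, W, T)


def extract_video_features(video: VideoVolume, config: PipelineConfig) -> VideoFeatures:
    points = detect_interest_points(video, config.detector)
    patches = extract_patches(video, points, config.scales)
    coords = (
        np.array([[p.y, p.x, p.t] for p in points], dtype=np.int64)
        if points else np.empty((0, 3), dtype=np.int64)
    )
    T, H, W = video.shape
    return VideoFeatures(coords=coords, patches=patches, dims=(H, W, T))


# ---------------------------------------------------------------------------
# Codebook bundle
# ---------------------------------------------------------------------------

@dataclass
class NASCodebook:
    """Everything needed to map a video to NAS indices."""

    bases: list            # per-scale ICBasis
    ic_models: list        # per-scale ICClusterModel
    structural: list       # per-scale StructuralClusterModel
    mask_order: np.ndarray
    config: PipelineConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def nas_of_patches(self, patches: np.ndarray) -> list[NASIndex]:
        """(n, n_scales, l) patch array -> NAS index per row."""
        if patches.shape[0] == 0:
            return []
        feats = [
            feature_matrix(patches[:, s, :], self.bases[s], self.ic_models[s])
            for s in range(len(self.bases))
        ]
        return assign_structural(feats, self.structural)


def _subsample(patches: np.ndarray, fraction: float, floor: int,
               rng: np.random.Generator) -> np.ndarray:
    n = patches.shape[0]
    keep = max(min(n, floor), int(round(n * fraction)))
    if keep >= n:
        return patches
    idx = rng.choice(n, size=keep, replace=False)
    return patches[np.sort(idx)]


def build_codebook(train_features: list[VideoFeatures], config: PipelineConfig,
                   seed: int | None = None) -> NASCodebook:
    """Fit per-scale IC bases, IC clusters and structural clusters.

    Training patch sequences are pooled over videos (optionally
    subsampled by ``config.train_fraction`` with a seeded draw), one ICA
    and one clustering pass per scale.
    """
    seed = config.seed if seed is None else seed
    pooled = np.concatenate([f.patches for f in train_features if f.patches.shape[0]])
    n_scales = config.scales.n_scales
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DE]))
    mask, order = circular_mask(config.scales.target[0])
    bases, ic_models, structural = [], [], []
    for s in range(n_scales):
        t0 = time.time()
        X = _subsample(pooled[:, s, :], config.train_fraction, 5 * config.n_ic, rng)
        basis = fit_ica(X, config.n_ic, seed=seed + s, scale_id=s)
        fits = []
        for i in range(config.n_ic):
            vol = component_to_volume(
                basis.components[i], config.scales.target[0], config.scales.target[1]
            )
            gf = fit_gabor(vol, seed=seed * 101 + s * 17 + i, mask=mask,
                           frames="summary", n_restarts=config.gabor_restarts)
            fits.append(gf.summary)
        ic_model = cluster_ics(fits, config.n_ic_clusters, seed=seed + 7 + s, scale_id=s)
        feats = feature_matrix(pooled[:, s, :], basis, ic_model)
        struct = fit_structural_clusters(
            feats, config.n_structural, seed=seed + 13 + s, scale_id=s
        )
        bases.append(basis)
        ic_models.append(ic_model)
        structural.append(struct)
        logger.info("scale %d codebook fitted in %.1fs (var retained %.3f)",
                    s, time.time() - t0, basis.variance_retained)
    return NASCodebook(bases=bases, ic_models=ic_models, structural=structural,
                       mask_order=order, config=config)


def encode_video(feats: VideoFeatures, codebook: NASCodebook) -> list[tuple[tuple[int, int, int], NASIndex]]:
    """Per-point ((y, x, t), NAS) list for one video."""
    nas = codebook.nas_of_patches(feats.patches)
    return [((int(y), int(x), int(t)), n) for (y, x, t), n in zip(feats.coords, nas)]


def _count_table(video_nas: list[list[tuple[tuple[int, int, int], NASIndex]]]) -> pd.DataFrame:
    rows = []
    for pn in video_nas:
        counts: dict[NASIndex, int] = {}
        for _, nas in pn:
            counts[nas] = counts.get(nas, 0) + 1
        rows.append(counts)
    return pd.DataFrame(rows).fillna(0.0).astype(np.int64)


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    test_subjects: tuple[int, ...]
    confusion: pd.DataFrame
    accuracy: float
    n_selected: int


@dataclass
class ProtocolResult:
    classes: list[str]
    folds: list[FoldResult]
    variants: dict[str, "ProtocolResult"] = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        total = sum(f.confusion.to_numpy().sum() for f in self.folds)
        correct = sum(np.trace(f.confusion.to_numpy()) for f in self.folds)
        return float(correct / total)

    @property
    def confusion(self) -> pd.DataFrame:
        out = sum(f.confusion for f in self.folds)
        return out


def _confusion(y_true: list[str], y_pred: list[str], classes: list[str]) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def _folds(dataset: list[DatasetItem], split) -> list[tuple[list[int], list[int]]]:
    subjects = sorted({it.subject_id for it in dataset})
    if split == "loso":
        out = []
        for s in subjects:
            train = [i for i, it in enumerate(dataset) if it.subject_id != s]
            test = [i for i, it in enumerate(dataset) if it.subject_id == s]
            out.append((train, test))
        return out
    train_subj, test_subj = split
    if set(train_subj) & set(test_subj):
        raise ValueError("protocol error: subject appears in both train and test")
    train = [i for i, it in enumerate(dataset) if it.subject_id in train_subj]
    test = [i for i, it in enumerate(dataset) if it.subject_id in test_subj]
    return [(train, test)]


def _add_noise(video: VideoVolume, snr_db: float, rng: np.random.Generator) -> VideoVolume:
    std = float(video.frames.std()) * 10.0 ** (-snr_db / 20.0)
    noisy = video.frames + rng.normal(0.0, std, size=video.frames.shape)
    return VideoVolume(np.clip(noisy, 0.0, 1.0), frame_rate=video.frame_rate)


def _run_folds(dataset, feats_by_item, test_feats_override, config, classifier,
               split) -> ProtocolResult:
    classes = sorted({it.label for it in dataset})
    folds = []
    for fold_id, (train_idx, test_idx) in enumerate(_folds(dataset, split)):
        t0 = time.time()
        fold_seed = config.seed + 1000 * (fold_id + 1)
        train_feats = [feats_by_item[i] for i in train_idx]
        codebook = build_codebook(train_feats, config, seed=fold_seed)
        train_nas = [encode_video(feats_by_item[i], codebook) for i in train_idx]
        train_labels = [dataset[i].label for i in train_idx]
        table = _count_table(train_nas)
        if classifier == "svm":
            mc, nc = config.Mc, config.Nc
        else:
            mc, nc = config.Mc_lda, config.Nc_lda
        selection = select_nas(table, train_labels, mc, nc)

        def hists(idx_list, nas_list, feats_map):
            out = []
            for i, pn in zip(idx_list, nas_list):
                h = nas_histogram(pn, selection, config.grid, feats_map[i].dims)
                out.append(h)
            return out

        test_map = test_feats_override or feats_by_item
        test_nas = [encode_video(test_map[i], codebook) for i in test_idx]
        test_labels = [dataset[i].label for i in test_idx]

        if classifier == "svm":
            Xtr = np.stack([
                _classify.normalize_histogram(h.counts)
                for h in hists(train_idx, train_nas, feats_by_item)
            ])
            model = _classify.train_svm(Xtr, train_labels, C=config.svm_C)
            Xte = np.stack([
                _classify.normalize_histogram(h.counts)
                for h in hists(test_idx, test_nas, test_map)
            ])
            preds, _ = _classify.predict_svm(model, Xte)
        elif classifier == "lda":
            sel_index = selection.index
            def tokens(pn):
                return np.array([sel_index[n] for _, n in pn if n in sel_index],
                                dtype=np.int64)
            vocab = len(selection.selected)
            models = {}
            for c in classes:
                docs = [tokens(pn) for pn, lab in zip(train_nas, train_labels) if lab == c]
                models[c] = _classify.fit_lda(
                    docs, K=config.lda_topics, seed=fold_seed, n_vocab=vocab,
                    max_iter=60,
                )
            preds = []
            for pn in test_nas:
                doc = tokens(pn)
                if doc.size == 0:
                    preds.append(classes[0])  # no selected NAS observed
                else:
                    preds.append(_classify.classify_lda(models, doc)[0])
        else:
            raise ValueError("classifier must be 'svm' or 'lda'")

        conf = _confusion(test_labels, preds, classes)
        acc = float(np.trace(conf.to_numpy()) / max(conf.to_numpy().sum(), 1))
        folds.append(FoldResult(
            test_subjects=tuple(sorted({dataset[i].subject_id for i in test_idx})),
            confusion=conf, accuracy=acc, n_selected=len(selection.selected),
        ))
        logger.info("fold %d (%s): acc %.3f, %d NASs, %.1fs", fold_id, classifier,
                    acc, len(selection.selected), time.time() - t0)
    return ProtocolResult(classes=classes, folds=folds)


def run_protocol(dataset: list[DatasetItem], config: PipelineConfig,
                 protocol: _classify.EvalProtocol | None = None,
                 classifier: str = "svm") -> ProtocolResult:
    """Grouped cross-validation with optional robustness variants.

    Scale variants rescale the *test* videos only and reuse each fold's
    trained models; the noise variant adds calibrated Gaussian noise to
    both halves and retrains from scratch.
    """
    protocol = protocol or _classify.EvalProtocol()
    feats = {i: extract_video_features(it.video, config) for i, it in enumerate(dataset)}
    result = _run_folds(dataset, feats, None, config, classifier, protocol.split)
    for factor in protocol.scale_factors:
        scaled = {
            i: extract_video_features(rescale_video(it.video, factor), config)
            for i, it in enumerate(dataset)
        }
        result.variants[f"scale_{factor:g}"] = _run_folds(
            dataset, feats, scaled, config, classifier, protocol.split
        )
    if protocol.noise_snr_db is not None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x401]))
        noisy_feats = {
            i: extract_video_features(_add_noise(it.video, protocol.noise_snr_db, rng), config)
            for i, it in enumerate(dataset)
        }
        result.variants[f"noise_{protocol.noise_snr_db:g}db"] = _run_folds(
            dataset, noisy_feats, None, config, classifier, protocol.split
        )
    return result


def train_eval(dataset: list[DatasetItem], config: PipelineConfig,
               classifier: str = "svm",
               protocol: _classify.EvalProtocol | None = None) -> dict:
    """Run the protocol and assemble a JSON-serializable metrics report."""
    res = run_protocol(dataset, config, protocol=protocol, classifier=classifier)
    report = {
        "classifier": classifier,
        "classes": res.classes,
        "mean_accuracy": res.mean_accuracy,
        "per_fold_accuracy": [f.accuracy for f in res.folds],
        "selected_nas_per_fold": [f.n_selected for f in res.folds],
        "confusion": res.confusion.to_numpy().tolist(),
        "config": config.to_dict(),
        "variants": {
            name: {
                "mean_accuracy": v.mean_accuracy,
                "confusion": v.confusion.to_numpy().tolist(),
            }
            for name, v in res.variants.items()
        },
    }
    return report


def manifest_hash(payload: dict) -> str:
    """Stable content hash for run manifests / stage caching."""
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
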