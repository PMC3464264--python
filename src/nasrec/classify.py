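"""Recognition back ends over NAS code words.

Two classifiers are provided.  A one-vs-rest SVM with the 1-chi^2
histogram kernel

    K(x, y) = 1 - 1/2 sum_i (x_i - y_i)^2 / (x_i + y_i)

operates on grid-pooled NAS histograms, each grid cell L1-normalized so
masses are comparable across videos.  A per-class latent Dirichlet
allocation model, fitted by variational EM (Blei-style mean-field with a
Dirichlet-Newton update for alpha), treats the selected NASs of a video
as a bag of code words; classification assigns the class whose model
attains the highest converged per-document evidence lower bound (ELBO).
During EM the topic-word matrix beta is the exact maximizer of the bound
(so the ELBO trace is non-decreasing); for scoring unseen documents beta
is smoothed with a symmetric pseudocount so unseen words keep finite
likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, polygamma, psi
from sklearn.svm import SVC

__all__ = [
    "chi2_kernel",
    "normalize_histogram",
    "SVMModel",
    "train_svm",
    "predict_svm",
    "LDAModel",
    "fit_lda",
    "classify_lda",
    "document_elbo",
    "topic_of_word",
    "EvalProtocol",
    "run_protocol",
]


# ---------------------------------------------------------------------------
# chi^2 kernel and SVM
# ---------------------------------------------------------------------------

def chi2_kernel(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray | float:
    """1 - chi^2/2 similarity between nonnegative histograms.

    Accepts single vectors (returns a float) or (n, d) matrices (returns
    the (n, m) Gram block).  Coordinates with x_i + y_i = 0 contribute 0,
    so K(x, x) = 1 and disjoint unit-mass histograms give 0.
    """
    X = np.asarray(x, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    Y = X if y is None else np.atleast_2d(np.asarray(y, dtype=np.float64))
    if (X < 0).any() or (Y < 0).any():
        raise ValueError("chi2 kernel requires nonnegative histograms")
    # chi2[a, b] = sum_i (X[a,i]-Y[b,i])^2 / (X[a,i]+Y[b,i])
    num = (X[:, None, :] - Y[None, :, :]) ** 2
    den = X[:, None, :] + Y[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    K = 1.0 - 0.5 * terms.sum(axis=2)
    if single and (y is None or np.asarray(y).ndim == 1):
        return float(K[0, 0])
    return K


def normalize_histogram(counts: np.ndarray) -> np.ndarray:
    """L1-normalize each grid cell (row) of a (cells, words) count array.

    Each nonempty cell is scaled to unit mass and the whole vector is
    divided by the number of cells, so complete histograms always carry
    total mass 1 regardless of how many points each cell captured --
    equal masses keep the 1-chi^2 Gram positive semidefinite.  Empty
    cells stay zero.  Returns the flattened normalized vector.
    """
    c = np.atleast_2d(np.asarray(counts, dtype=np.float64))
    sums = c.sum(axis=1, keepdims=True)
    return ((c / np.where(sums > 0, sums, 1.0)) / c.shape[0]).ravel()


@dataclass
class SVMModel:
    classes: list[str]
    machines: list[SVC] = field(repr=False)
    X_train: np.ndarray = field(repr=False)
    C: float = 0.125


def train_svm(histograms: np.ndarray, labels: list[str], C: float = 0.125) -> SVMModel:
    """One-vs-rest SVM with the precomputed 1-chi^2 kernel.

    ``histograms`` must already be cell-normalized (see
    :func:`normalize_histogram`).  A Gram matrix with minimum eigenvalue
    below -1e-8 triggers a warning and a small diagonal jitter.
    """
    X = np.asarray(histograms, dtype=np.float64)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    G = chi2_kernel(X)
    min_eig = float(np.linalg.eigvalsh(G).min())
    if min_eig < -1e-8:
        warnings.warn(f"chi2 Gram min eigenvalue {min_eig:.3e}; adding jitter")
        G = G + (1e-8 - min_eig) * np.eye(len(X))
    y = np.asarray(labels)
    machines = []
    for c in classes:
        svc = SVC(kernel="precomputed", C=C, tol=1e-8)
        svc.fit(G, (y == c).astype(int))
        machines.append(svc)
    return SVMModel(classes=classes, machines=machines, X_train=X, C=C)


def predict_svm(model: SVMModel, histograms: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Predicted labels and the (n, n_classes) decision-value matrix.

    The label is the argmax of per-class decision values; exact ties go
    to the earlier class in sorted order.
    """
    X = np.atleast_2d(np.asarray(histograms, dtype=np.float64))
    K = chi2_kernel(X, model.X_train)
    dec = np.column_stack([m.decision_function(K) for m in model.machines])
    preds = [model.classes[i] for i in np.argmax(dec, axis=1)]
    return preds, dec


# ---------------------------------------------------------------------------
# Variational LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    K: int
    C: int
    alpha: np.ndarray            # (K,)
    beta: np.ndarray             # (K, C), rows sum to 1 (unsmoothed MLE)
    elbo_trace: list[float] = field(default_factory=list)
    smoothing: float = 0.01

    @property
    def beta_smoothed(self) -> np.ndarray:
        b = self.beta + self.smoothing / self.C
        return b / b.sum(axis=1, keepdims=True)


def _doc_counts(doc: np.ndarray, C: int) -> tuple[np.ndarray, np.ndarray]:
    words, counts = np.unique(np.asarray(doc, dtype=np.int64), return_counts=True)
    if words.size and (words[0] < 0 or words[-1] >= C):
        raise ValueError("word id out of vocabulary range")
    return words, counts.astype(np.float64)


def _e_step_doc(words: np.ndarray, counts: np.ndarray, alpha: np.ndarray,
                log_beta_w: np.ndarray, max_iter: int = 100,
                tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field update for one document.

    log_beta_w: (K, n_unique) log word probabilities for the doc's words.
    Returns gamma (K,) and phi (n_unique, K).
    """
    K = alpha.shape[0]
    gamma = alpha + counts.sum() / K
    phi = np.full((words.size, K), 1.0 / K)
    for _ in range(max_iter):
        log_phi = psi(gamma)[None, :] + log_beta_w.T
        log_phi -= log_phi.max(axis=1, keepdims=True)
        phi = np.exp(log_phi)
        phi /= phi.sum(axis=1, keepdims=True)
        new_gamma = alpha + counts @ phi
        if np.abs(new_gamma - gamma).max() < tol:
            gamma = new_gamma
            break
        gamma = new_gamma
    return gamma, phi


def _doc_bound(words: np.ndarray, counts: np.ndarray, alpha: np.ndarray,
               log_beta_w: np.ndarray, gamma: np.ndarray, phi: np.ndarray) -> float:
    dig = psi(gamma) - psi(gamma.sum())
    bound = gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * dig).sum()
    bound += (counts[:, None] * phi * dig[None, :]).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        lb = np.where(phi > 0, log_beta_w.T, 0.0)
        plogp = np.where(phi > 0, phi * np.log(np.where(phi > 0, phi, 1.0)), 0.0)
    bound += (counts[:, None] * phi * lb).sum()
    bound -= gammaln(gamma.sum()) - gammaln(gamma).sum() + ((gamma - 1) * dig).sum()
    bound -= (counts[:, None] * plogp).sum()
    return float(bound)


def _update_alpha(alpha: np.ndarray, suff: np.ndarray, M: int,
                  n_iter: int = 20) -> np.ndarray:
    """Newton step(s) for the Dirichlet alpha (Blei appendix A.2).

    suff = sum_d (psi(gamma_d) - psi(sum gamma_d)); the Hessian is
    diagonal plus rank one, inverted in closed form.  Step-halving keeps
    alpha positive and the objective non-decreasing.
    """

    def objective(a: np.ndarray) -> float:
        return float(M * (gammaln(a.sum()) - gammaln(a).sum()) + (a - 1) @ suff)

    a = alpha.copy()
    for _ in range(n_iter):
        g = M * (psi(a.sum()) - psi(a)) + suff
        h = -M * polygamma(1, a)
        z = M * polygamma(1, a.sum())
        c = (g / h).sum() / (1.0 / z + (1.0 / h).sum())
        step = (g - c) / h
        obj0 = objective(a)
        scale = 1.0
        for _ in range(30):
            cand = a - scale * step
            if (cand > 1e-8).all() and objective(cand) >= obj0:
                a = cand
                break
            scale *= 0.5
        else:
            break
        if np.abs(g).max() < 1e-8:
            break
    return a


def fit_lda(docs: list[np.ndarray], K: int, seed: int = 0, n_vocab: int | None = None,
            max_iter: int = 200, tol: float = 1e-5, fit_alpha: bool = True,
            alpha_warmup: int = 8) -> LDAModel:
    """Variational EM for LDA on bags of word ids.

    Empty documents are dropped with a warning.  Iterates until the
    relative ELBO change falls below ``tol`` or ``max_iter`` EM rounds.
    beta is initialized as a seeded perturbation of uniform; alpha
    updates start after ``alpha_warmup`` EM rounds (before the topics
    separate, the near-uniform variational posteriors would drive the
    Dirichlet MLE toward +inf and lock the model in a blended optimum).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    docs = [np.asarray(d, dtype=np.int64) for d in docs]
    kept = [d for d in docs if d.size > 0]
    if len(kept) < len(docs):
        warnings.warn(f"dropped {len(docs) - len(kept)} empty documents")
    if not kept:
        raise ValueError("no non-empty documents")
    C = n_vocab if n_vocab is not None else int(max(d.max() for d in kept)) + 1
    rng = np.random.default_rng(seed)
    beta = 1.0 + 0.01 * rng.random((K, C))
    beta /= beta.sum(axis=1, keepdims=True)
    alpha = np.full(K, 1.0)
    doc_wc = [_doc_counts(d, C) for d in kept]
    M = len(kept)

    trace: list[float] = []
    prev = -np.inf
    for em_round in range(max_iter):
        with np.errstate(divide="ignore"):
            log_beta = np.where(beta > 0, np.log(np.where(beta > 0, beta, 1.0)), -1e30)
        beta_acc = np.zeros_like(beta)
        suff = np.zeros(K)
        bound = 0.0
        for words, counts in doc_wc:
            gamma, phi = _e_step_doc(words, counts, alpha, log_beta[:, words])
            bound += _doc_bound(words, counts, alpha, log_beta[:, words], gamma, phi)
            np.add.at(beta_acc.T, words, counts[:, None] * phi)
            suff += psi(gamma) - psi(gamma.sum())
        trace.append(bound)
        if prev > -np.inf and abs(bound - prev) < tol * abs(prev):
            break
        prev = bound
        row = beta_acc.sum(axis=1, keepdims=True)
        beta = beta_acc / np.where(row > 0, row, 1.0)
        if fit_alpha and K > 1 and em_round >= alpha_warmup:
            alpha = _update_alpha(alpha, suff, M)
    return LDAModel(K=K, C=C, alpha=alpha, beta=beta, elbo_trace=trace)


def document_elbo(model: LDAModel, doc: np.ndarray) -> float:
    """Converged variational lower bound on log p(doc | model).

    Uses the smoothed beta so documents containing words unseen during
    training keep a finite score.
    """
    words, counts = _doc_counts(doc, model.C)
    if words.size == 0:
        raise ValueError("empty document")
    log_beta = np.log(model.beta_smoothed)
    gamma, phi = _e_step_doc(words, counts, model.alpha, log_beta[:, words])
    return _doc_bound(words, counts, model.alpha, log_beta[:, words], gamma, phi)


def classify_lda(models: dict[str, LDAModel], doc: np.ndarray) -> tuple[str, dict[str, float]]:
    """Assign a document to the per-class model with the highest ELBO.

    Ties go to the earlier class in sorted order.
    """
    scores = {c: document_elbo(m, doc) for c, m in sorted(models.items())}
    best = max(sorted(scores), key=lambda c: scores[c])
    return best, scores


def topic_of_word(model: LDAModel, w: int) -> int:
    """Topic with the highest beta_{z,w}; ties resolve to the lowest z."""
    if not 0 <= w < model.C:
        raise ValueError(f"word {w} outside vocabulary of size {model.C}")
    return int(np.argmax(model.beta[:, w]))


# ---------------------------------------------------------------------------
# Evaluation protocol (implemented by the pipeline orchestrator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalProtocol:
    """Cross-validation and robustness settings.

    ``split`` is "loso" (leave-one-subject-out) or a fixed
    (train_subjects, test_subjects) pair; perturbations are applied to
    the test half (spatial rescale) or to both halves with retraining
    (additive noise), following the robustness protocol.
    """

    split: str | tuple[tuple[int, ...], tuple[int, ...]] = "loso"
    scale_factors: tuple[float, ...] = ()
    noise_snr_db: float | None = None


def run_protocol(dataset, config, protocol: EvalProtocol | None = None, classifier: str = "svm"):
    """Grouped cross-validation over a dataset; see :mod:`nasrec.pipeline`."""
    from nasrec.pipeline import run_protocol as _run

    return _run(dataset, config, protocol=protocol, classifier=classifier)
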