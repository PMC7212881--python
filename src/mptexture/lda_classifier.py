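"""Two-class linear discriminant analysis over texture-feature vectors.

The classifier is the classical Gaussian discriminant with a pooled
within-class covariance: class means μ_k, covariance Σ estimated as the
within-class scatter divided by (N − K), and priors π_k either empirical
(class frequencies) or uniform.  The posterior "probability of class
assignment" for a feature vector x is

    p(k | x) ∝ π_k · exp(δ_k(x)),   δ_k(x) = xᵀ Σ⁻¹ μ_k − ½ μ_kᵀ Σ⁻¹ μ_k,

normalized over the two classes, with the frozen encoding 0 = nontumor,
1 = tumor.  A small ridge λ·I (default λ = 1e-6·trace(Σ)/dim) keeps Σ
invertible when some features are nearly constant, e.g. for SHG channels of
nontumor tissue; λ = 0 reproduces the strict classical estimator.

Patients (samples) are the unit of the train/test split: all FoVs of a
patient fall into exactly one of the two sets, preventing leakage of
within-patient texture correlations into the test accuracy.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

CLASS_LABELS = ("nontumor", "tumor")  # frozen encoding: index 0 / 1


class LDAError(Exception):
    """Invalid input to LDA fitting or prediction."""


class SingularCovarianceError(LDAError):
    """Pooled covariance is singular at λ=0."""


class SplitError(LDAError):
    """A patient-level split left a class empty in train or test."""


class ManifestMismatchError(LDAError):
    """Feature vector does not match the model's feature manifest."""


@dataclass(frozen=True)
class FovPrediction:
    """Posterior tumor probability of one FoV."""

    p_tumor: float
    provenance: tuple = ()
    channel_set: tuple = ()

    @property
    def p_nontumor(self) -> float:
        return 1.0 - self.p_tumor


@dataclass(frozen=True)
class LDAModel:
    """A trained two-class linear discriminant."""

    class_means: np.ndarray          # (2, d): rows ordered (nontumor, tumor)
    pooled_covariance: np.ndarray    # (d, d), after regularization
    priors: np.ndarray               # (2,), sums to 1
    feature_names: tuple[str, ...]
    config_hash: str = ""
    regularization: float = 0.0
    priors_mode: str = "empirical"
    class_labels: tuple[str, str] = CLASS_LABELS

    def __post_init__(self) -> None:
        means = np.asarray(self.class_means, dtype=float)
        cov = np.asarray(self.pooled_covariance, dtype=float)
        priors = np.asarray(self.priors, dtype=float)
        d = means.shape[1]
        if means.shape != (2, d) or cov.shape != (d, d) or priors.shape != (2,):
            raise LDAError("inconsistent model dimensions")
        if self.feature_names and len(self.feature_names) != d:
            raise LDAError("feature manifest length does not match dimensions")
        if abs(priors.sum() - 1.0) > 1e-12 or priors.min() < 0:
            raise LDAError("priors must be nonnegative and sum to 1")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise LDAError("pooled covariance must be symmetric")
        object.__setattr__(self, "class_means", means)
        object.__setattr__(self, "pooled_covariance", cov)
        object.__setattr__(self, "priors", priors)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_labels": list(self.class_labels),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
            "feature_names": list(self.feature_names),
            "config_hash": self.config_hash,
            "regularization": self.regularization,
            "priors_mode": self.priors_mode,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LDAModel":
        d = json.loads(Path(path).read_text())
        return cls(class_means=np.array(d["class_means"]),
                   pooled_covariance=np.array(d["pooled_covariance"]),
                   priors=np.array(d["priors"]),
                   feature_names=tuple(d["feature_names"]),
                   config_hash=d.get("config_hash", ""),
                   regularization=float(d.get("regularization", 0.0)),
                   priors_mode=d.get("priors_mode", "empirical"),
                   class_labels=tuple(d.get("class_labels", CLASS_LABELS)))


def split_by_patient(patients: Mapping[str, str] | Sequence[tuple[str, str]],
                     proportion: float, seed: int) -> tuple[list[str], list[str]]:
    """Randomly assign patients (not FoVs) to training and test sets.

    ``patients`` maps sample_id → class label.  ``proportion`` is the
    training fraction.  The split is reproducible from ``seed``; an error is
    raised if either class is missing from either set (re-draw with another
    seed).
    """
    items = dict(patients)
    if not items:
        raise SplitError("no patients to split")
    if not (0 < proportion < 1):
        raise SplitError(f"proportion must be in (0, 1), got {proportion}")
    ids = sorted(items)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(proportion * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    for name, subset in (("training", train), ("test", test)):
        labels = {items[i] for i in subset}
        missing = set(CLASS_LABELS) - labels
        if missing:
            raise SplitError(
                f"{name} set lacks class(es) {sorted(missing)}; re-draw with a "
                f"different seed")
    return train, test


def fit_lda(features: np.ndarray, labels: np.ndarray,
            priors_mode: str = "empirical",
            regularization: float | None = None,
            feature_names: Sequence[str] = (),
            config_hash: str = "") -> LDAModel:
    """Fit the pooled-covariance linear discriminant.

    ``labels`` are 0 (nontumor) / 1 (tumor).  ``regularization=None``
    selects the default ridge λ = 1e-6·trace(Σ)/dim; pass 0.0 for the strict
    classical estimator (raises on a singular covariance, naming the most
    deficient feature direction).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise LDAError("features must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise LDAError("features contain NaN/Inf")
    if set(np.unique(y)) != {0, 1}:
        raise LDAError("labels must contain both classes 0 and 1")
    n, d = X.shape
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise LDAError("need at least 2 FoVs per class")
    means = np.stack([X[y == k].mean(axis=0) for k in (0, 1)])
    scatter = np.zeros((d, d))
    for k in (0, 1):
        Z = X[y == k] - means[k]
        scatter += Z.T @ Z
    cov = scatter / (n - 2)
    if priors_mode == "empirical":
        priors = counts / n
    elif priors_mode == "uniform":
        priors = np.array([0.5, 0.5])
    else:
        raise LDAError(f"unknown priors_mode {priors_mode!r}")
    lam = 1e-6 * np.trace(cov) / d if regularization is None else float(regularization)
    if lam < 0:
        raise LDAError("regularization must be nonnegative")
    if lam == 0.0:
        try:
            np.linalg.cholesky(cov if cov.size else np.eye(1))
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(cov)
            weak = v[:, int(np.argmin(w))]
            name = (feature_names[int(np.argmax(np.abs(weak)))]
                    if feature_names else f"feature {int(np.argmax(np.abs(weak)))}")
            suggestion = 1e-6 * np.trace(cov) / d
            raise SingularCovarianceError(
                f"pooled covariance is singular along a direction dominated by "
                f"{name!r}; consider regularization λ ≈ {suggestion:.3g}") from None
    cov = cov + lam * np.eye(d)
    return LDAModel(class_means=means, pooled_covariance=cov, priors=priors,
                    feature_names=tuple(feature_names) or tuple(f"f{i}" for i in range(d)),
                    config_hash=config_hash, regularization=lam,
                    priors_mode=priors_mode)


def _posterior_matrix(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Vector of p_tumor for the rows of X (numerically stable softmax)."""
    W = np.linalg.solve(model.pooled_covariance, model.class_means.T)  # (d, 2)
    const = -0.5 * np.einsum("kd,dk->k", model.class_means, W) + np.log(model.priors)
    scores = X @ W + const                                             # (n, 2)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e[:, 1] / e.sum(axis=1)


def posterior(model: LDAModel, x: np.ndarray, provenance: tuple = (),
              channel_set: tuple = ()) -> FovPrediction:
    """Posterior tumor probability of one feature vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ManifestMismatchError(
            f"feature vector of length {x.shape} does not match the model's "
            f"{model.n_features}-entry manifest")
    p = float(_posterior_matrix(model, x[None, :])[0])
    return FovPrediction(p_tumor=p, provenance=provenance, channel_set=channel_set)


def predict_fovs(model: LDAModel, fovs: np.ndarray,
                 provenances: Sequence[tuple] | None = None,
                 channel_set: tuple = ()) -> list[FovPrediction]:
    """Order-preserving batch version of :func:`posterior`."""
    X = np.asarray(fovs, dtype=float)
    if X.size == 0:
        return []
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ManifestMismatchError(
            f"feature matrix of shape {X.shape} does not match the model's "
            f"{model.n_features}-entry manifest")
    if provenances is not None and len(provenances) != X.shape[0]:
        raise LDAError("one provenance per row required")
    ps = _posterior_matrix(model, X)
    return [FovPrediction(p_tumor=float(p),
                          provenance=(provenances[i] if provenances is not None else ()),
                          channel_set=channel_set)
            for i, p in enumerate(ps)]
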