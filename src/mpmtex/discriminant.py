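"""Linear and quadratic discriminant analysis with posterior probabilities.

The classifier is the Gaussian class-conditional model: each class k has a
mean vector mu_k and a covariance matrix (pooled across classes for the
linear model, per-class for the quadratic model); the posterior of class k
at a point x is

    P(k | x)  proportional to  pi_k * N(x; mu_k, Sigma_k)

evaluated in log-space with a stable normalization.  A tile is assigned to
"tumor" when its tumor posterior exceeds 0.5; an exact 0.5 resolves to
"normal" (conservative tie rule).

Covariances from moderate sample sizes in ~42 dimensions can be
ill-conditioned, so a ridge term eps * (trace/dim) * I is added whenever
the condition number exceeds 1e8; the eps actually applied is recorded in
the fitted model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureSpec, FeatureVector

log = logging.getLogger(__name__)

CONDITION_LIMIT = 1e8
CLASS_ORDER = ("normal", "tumor")


@dataclass
class DiscriminantModel:
    """Fitted Gaussian class-conditional model.

    ``covariances`` has shape (1, d, d) for the linear model (pooled
    within-class covariance) or (2, d, d) for the quadratic model
    (per-class covariances), in the class order ``classes``.
    """

    model_type: str
    classes: tuple[str, str]
    means: np.ndarray
    covariances: np.ndarray
    priors: np.ndarray
    feature_names: tuple[str, ...]
    ridge: float = 0.0
    n_per_class: tuple[int, int] = (0, 0)
    feature_spec: FeatureSpec | None = None

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def validate(self) -> "DiscriminantModel":
        if self.model_type not in ("linear", "quadratic"):
            raise ValueError(f"unknown model type {self.model_type!r}")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        for S in self.covariances:
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError("covariance not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError("covariance not positive definite")
        if self.feature_names and len(self.feature_names) != self.dim:
            raise ValueError("feature name count does not match model dimension")
        return self


@dataclass
class ClassificationResult:
    """Per-FoV classification outcome with provenance."""

    fov_id: str
    posterior_tumor: float
    predicted: str
    patient_id: str = ""
    sample_id: str = ""
    tile_row: int = -1
    tile_col: int = -1
    truth: str | None = None


def _regularize(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Add ridge eps*(trace/dim)*I until the condition number is tolerable."""
    d = S.shape[0]
    scale = float(np.trace(S)) / d
    if scale <= 0:
        scale = 1.0
    eps = 0.0
    eye = np.eye(d)
    while True:
        w = np.linalg.eigvalsh(S + eps * scale * eye)
        if w.min() > 0 and w.max() / w.min() <= CONDITION_LIMIT:
            break
        eps = 1e-10 if eps == 0.0 else eps * 10.0
        if eps > 1e3:
            raise np.linalg.LinAlgError("covariance cannot be regularized")
    if eps:
        log.info("ill-conditioned covariance: applied ridge eps=%g", eps)
        S = S + eps * scale * eye
    return S, eps


def _as_matrix(
    features: Sequence[FeatureVector] | pd.DataFrame | np.ndarray,
    feature_names: Sequence[str] | None = None,
):
    """Coerce feature input to an (n, d) float matrix plus provenance frame."""
    if isinstance(features, pd.DataFrame):
        names = list(feature_names) if feature_names is not None else [
            c
            for c in features.columns
            if c not in ("patient_id", "sample_id", "fov_id", "tile_row", "tile_col", "tissue_label")
        ]
        X = features[names].to_numpy(dtype=np.float64)
        prov = features
        return X, prov
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=np.float64), None
    X = np.vstack([fv.values for fv in features]).astype(np.float64)
    prov = pd.DataFrame(
        {
            "patient_id": [fv.patient_id for fv in features],
            "sample_id": [fv.sample_id for fv in features],
            "fov_id": [fv.fov_id for fv in features],
            "tile_row": [fv.tile_row for fv in features],
            "tile_col": [fv.tile_col for fv in features],
            "tissue_label": [fv.tissue_label for fv in features],
        }
    )
    return X, prov


def fit_discriminant(
    features,
    labels: Sequence[str] | None = None,
    model_type: str = "linear",
    priors_mode: str = "empirical",
    feature_names: Sequence[str] | None = None,
    feature_spec: FeatureSpec | None = None,
) -> DiscriminantModel:
    """Fit a linear or quadratic discriminant model.

    ``features`` may be a feature table (DataFrame with a ``tissue_label``
    column, in which case ``labels`` defaults to it), a list of
    FeatureVector, or a plain matrix with explicit ``labels``.

    Class means are per-class sample means.  The linear model pools the
    within-class scatter with divisor N - K; the quadratic model uses
    per-class covariances with divisor n_k - 1.
    """
    if model_type not in ("linear", "quadratic"):
        raise ValueError(f"unknown model type {model_type!r}")
    if priors_mode not in ("empirical", "uniform"):
        raise ValueError(f"unknown priors mode {priors_mode!r}")
    if isinstance(features, pd.DataFrame) and labels is None:
        labels = features["tissue_label"].to_list()
    elif labels is None:
        labels = [fv.tissue_label for fv in features]
    if feature_spec is not None and feature_names is None:
        feature_names = feature_spec.feature_names()
    X, _ = _as_matrix(features, feature_names)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite features in row {int(np.flatnonzero(bad)[0])}")
    present = set(y)
    if not set(CLASS_ORDER) <= present:
        raise ValueError(f"both classes required, got {sorted(present)}")

    d = X.shape[1]
    means = np.empty((2, d))
    counts = np.empty(2, dtype=int)
    scatters = []
    for k, cls in enumerate(CLASS_ORDER):
        Xk = X[y == cls]
        counts[k] = len(Xk)
        if counts[k] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        means[k] = Xk.mean(axis=0)
        centred = Xk - means[k]
        scatters.append(centred.T @ centred)

    ridge = 0.0
    if model_type == "linear":
        pooled = (scatters[0] + scatters[1]) / (counts.sum() - 2)
        pooled, ridge = _regularize(pooled)
        covs = pooled[None, :, :]
    else:
        regs = []
        for k in range(2):
            Sk = scatters[k] / (counts[k] - 1)
            Sk, eps = _regularize(Sk)
            ridge = max(ridge, eps)
            regs.append(Sk)
        covs = np.stack(regs)

    if priors_mode == "empirical":
        priors = counts / counts.sum()
    else:
        priors = np.array([0.5, 0.5])

    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(d)
    )
    return DiscriminantModel(
        model_type=model_type,
        classes=CLASS_ORDER,
        means=means,
        covariances=covs.astype(np.float64),
        priors=np.asarray(priors, dtype=np.float64),
        feature_names=names,
        ridge=float(ridge),
        n_per_class=(int(counts[0]), int(counts[1])),
        feature_spec=feature_spec,
    ).validate()


def _log_density_terms(model: DiscriminantModel):
    """Per-class (eigvecs, eigvals, logdet, mean) for log-density evaluation."""
    terms = []
    for k in range(2):
        S = model.covariances[0 if model.covariances.shape[0] == 1 else k]
        w, V = np.linalg.eigh(S)
        terms.append((V, w, float(np.log(w).sum()), model.means[k]))
    return terms


def posterior(model: DiscriminantModel, x) -> np.ndarray:
    """Posterior probabilities over (normal, tumor).

    Accepts one vector (returns shape (2,)) or an (n, d) matrix (returns
    (n, 2)).  Computed in log-space through the symmetric
    eigendecomposition of each covariance and normalized with logsumexp;
    rows sum to 1.
    """
    X = np.asarray(x, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.dim:
        raise ValueError(f"dimension mismatch: model {model.dim}, input {X.shape[1]}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    logp = np.empty((X.shape[0], 2))
    for k, (V, w, logdet, mu) in enumerate(_log_density_terms(model)):
        z = (X - mu) @ V
        maha = np.einsum("ij,j,ij->i", z, 1.0 / w, z)
        logp[:, k] = np.log(model.priors[k]) - 0.5 * (logdet + maha)
    # two-class logistic normalization: exact at the symmetry point and
    # overflow-safe (exp(+inf) -> posterior 0)
    with np.errstate(over="ignore"):
        p_tumor = 1.0 / (1.0 + np.exp(logp[:, 0] - logp[:, 1]))
    post = np.column_stack([1.0 - p_tumor, p_tumor])
    return post[0] if single else post


def classify_images(model: DiscriminantModel, features) -> list[ClassificationResult]:
    """Classify a batch of feature vectors.

    Predicted label is "tumor" iff the tumor posterior exceeds 0.5; an
    exact 0.5 yields "normal".  Input order is preserved.
    """
    names = model.feature_names if _names_available(model, features) else None
    X, prov = _as_matrix(features, names)
    post = posterior(model, X)
    p_tumor = post[:, 1]
    results = []
    for i in range(len(p_tumor)):
        pt = float(p_tumor[i])
        if pt == 0.5:
            log.info("tie posterior 0.5 resolved to 'normal'")
        pred = "tumor" if pt > 0.5 else "normal"
        if prov is not None:
            row = prov.iloc[i]
            results.append(
                ClassificationResult(
                    fov_id=str(row.get("fov_id", i)),
                    posterior_tumor=pt,
                    predicted=pred,
                    patient_id=str(row.get("patient_id", "")),
                    sample_id=str(row.get("sample_id", "")),
                    tile_row=int(row.get("tile_row", -1)),
                    tile_col=int(row.get("tile_col", -1)),
                    truth=row.get("tissue_label"),
                )
            )
        else:
            results.append(
                ClassificationResult(fov_id=str(i), posterior_tumor=pt, predicted=pred)
            )
    return results


def _names_available(model: DiscriminantModel, features) -> bool:
    if isinstance(features, pd.DataFrame):
        return all(n in features.columns for n in model.feature_names)
    return False


def results_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Tabular view of classification results (CSV-ready)."""
    return pd.DataFrame(
        {
            "fov_id": [r.fov_id for r in results],
            "patient_id": [r.patient_id for r in results],
            "sample_id": [r.sample_id for r in results],
            "tile_row": [r.tile_row for r in results],
            "tile_col": [r.tile_col for r in results],
            "posterior_tumor": [r.posterior_tumor for r in results],
            "predicted": [r.predicted for r in results],
            "truth": [r.truth for r in results],
        }
    )
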