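"""Standardisation and PCA feature reduction.

Columns are centred and scaled with the *population* standard deviation
(divisor ``N``); the covariance of the standardised matrix is then taken
with divisor ``N - 1``. Both divisors are deliberate: the mismatch only
rescales every eigenvalue by the same factor, so explained-variance ratios
and the retained component count are unaffected.

The retained dimensionality ``K`` is the smallest count whose cumulative
explained-variance percentage reaches the retention threshold (default 95).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class StandardizationParams:
    """Column means and population standard deviations of the training data."""

    mu: np.ndarray
    sigma: np.ndarray
    zero_variance: np.ndarray  # boolean flags for constant columns

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != sigma.shape or mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D and equal length")
        if np.any(sigma < 0):
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "zero_variance", np.asarray(self.zero_variance, dtype=bool))

    def apply(self, D: np.ndarray) -> np.ndarray:
        """Standardise rows of ``D``; constant training columns map to zeros."""
        D = np.asarray(D, dtype=float)
        if D.shape[-1] != len(self.mu):
            raise ValueError(f"expected {len(self.mu)} columns, got {D.shape[-1]}")
        safe_sigma = np.where(self.zero_variance, 1.0, self.sigma)
        SD = (D - self.mu) / safe_sigma
        SD[..., self.zero_variance] = 0.0
        return SD


def fit_standardizer(D: np.ndarray) -> StandardizationParams:
    """Column means and population (divisor ``N``) standard deviations."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] < 2:
        raise ValueError("need a 2-D matrix with N >= 2 rows")
    mu = D.mean(axis=0)
    sigma = D.std(axis=0, ddof=0)
    return StandardizationParams(mu=mu, sigma=sigma, zero_variance=sigma == 0)


@dataclass(frozen=True)
class PcaModel:
    """Eigendecomposition of the training covariance with retained-K projection.

    ``explained_pct`` holds the per-component explained-variance percentages
    (summing to 100); ``K`` is minimal for the retention threshold.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # F x F, columns sorted by descending eigenvalue
    K: int
    threshold: float = 95.0
    standardizer: StandardizationParams | None = None

    def __post_init__(self):
        lam = np.asarray(self.eigenvalues, dtype=float)
        phi = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(lam) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")
        if not 1 <= self.K <= len(lam):
            raise ValueError("K out of range")
        object.__setattr__(self, "eigenvalues", lam)
        object.__setattr__(self, "eigenvectors", phi)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def explained_pct(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.total_variance

    @property
    def components(self) -> np.ndarray:
        """F x K matrix of the retained eigenvectors."""
        return self.eigenvectors[:, : self.K]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "K": self.K,
            "threshold": self.threshold,
        }
        if self.standardizer is not None:
            payload["mu"] = self.standardizer.mu.tolist()
            payload["sigma"] = self.standardizer.sigma.tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaModel":
        payload = json.loads(Path(path).read_text())
        std = None
        if "mu" in payload:
            sigma = np.asarray(payload["sigma"], dtype=float)
            std = StandardizationParams(
                mu=np.asarray(payload["mu"], dtype=float), sigma=sigma, zero_variance=sigma == 0
            )
        return cls(
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            eigenvectors=np.asarray(payload["eigenvectors"], dtype=float),
            K=payload["K"],
            threshold=payload["threshold"],
            standardizer=std,
        )


def fit_pca(SD: np.ndarray, threshold: float = 95.0, standardizer: StandardizationParams | None = None) -> PcaModel:
    """Fit PCA on an already-standardised matrix.

    The covariance ``SD.T @ SD / (N - 1)`` is eigendecomposed; components are
    sorted by descending eigenvalue with each eigenvector's largest-magnitude
    entry made positive; ``K`` is the smallest count whose cumulative
    explained percentage reaches ``threshold``.
    """
    SD = np.asarray(SD, dtype=float)
    if SD.ndim != 2 or SD.shape[0] < 2:
        raise ValueError("need a 2-D matrix with N >= 2 rows")
    if not np.all(np.isfinite(SD)):
        raise ValueError("non-finite entries in standardised matrix")
    N = SD.shape[0]
    cov = SD.T @ SD / (N - 1)
    lam, phi = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    phi = phi[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    flips = np.sign(phi[np.argmax(np.abs(phi), axis=0), np.arange(phi.shape[1])])
    flips[flips == 0] = 1.0
    phi = phi * flips

    total = lam.sum()
    if total <= 0:
        K = 1
    else:
        cum_pct = 100.0 * np.cumsum(lam) / total
        K = int(np.searchsorted(cum_pct, threshold - 1e-12) + 1)
        K = min(K, len(lam))
    return PcaModel(eigenvalues=lam, eigenvectors=phi, K=K, threshold=threshold, standardizer=standardizer)


def project(rows: np.ndarray, model: PcaModel) -> np.ndarray:
    """Project standardised rows onto the retained components (length ``K``)."""
    rows = np.asarray(rows, dtype=float)
    F = model.eigenvectors.shape[0]
    if rows.shape[-1] != F:
        raise ValueError(f"expected row length {F}, got {rows.shape[-1]}")
    return rows @ model.components


def fit_reducer(D_train: np.ndarray, threshold: float = 95.0) -> PcaModel:
    """Convenience: fit standardiser + PCA on raw training rows."""
    std = fit_standardizer(D_train)
    return fit_pca(std.apply(D_train), threshold=threshold, standardizer=std)


def transform(D: np.ndarray, model: PcaModel) -> np.ndarray:
    """Standardise raw rows with the model's training statistics, then project."""
    if model.standardizer is None:
        raise ValueError("model was fitted without a standardizer")
    return project(model.standardizer.apply(D), model)
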