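"""Column standardization fitted on training data and re-applied elsewhere.

Covariates (and, for models that regress on it, survival time) are scaled
to zero mean and unit standard deviation. Parameters are always fitted on
the training split only and stored so validation data can be transformed
with the training statistics — never its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column mean/sd of the fit data.

    ``constant`` flags columns whose sd was below tolerance; those columns
    are passed through centred only (their stored sd is 1), so degenerate
    covariates cannot blow up a fold.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray
    ddof: int = 1  # sample-sd convention, recorded for auditability

    @property
    def n_columns(self) -> int:
        return self.mean.shape[0]


def fit_normalizer(X: np.ndarray, ddof: int = 1) -> NormalizationParams:
    """Fit per-column standardization parameters on ``X`` (n x p, n >= 2)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    constant = sd <= _EPS
    sd = np.where(constant, 1.0, sd)
    return NormalizationParams(mean=mean, sd=sd, constant=constant, ddof=ddof)


def apply_normalizer(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Standardize ``X`` with previously fitted ``params``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != params.n_columns:
        raise ValueError(f"expected {params.n_columns} columns, got {X.shape[1]}")
    return (X - params.mean) / params.sd


def invert_normalizer(params: NormalizationParams, Z: np.ndarray) -> np.ndarray:
    """Undo :func:`apply_normalizer` (round-trip identity)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return Z * params.sd + params.mean
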