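"""Ridge-regression genomic evaluation (RR-BLUP) on the -1/0/1 coding.

Marker effects are shrunk toward zero with penalty ``lambda``; the default
penalty is the classic variance-ratio plug-in
``lambda = ((1 - h2)/h2) * sum_l 2 p_l (1 - p_l)`` with allele frequencies
taken from the reference panel, appropriate when the heritability is treated
as known. Prediction always uses the raw genotype coding (the adjusted
relationship matrix used for selection never enters evaluation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .popgen import GenotypeMatrix, HaplotypePanel, allele_frequency

__all__ = ["EvaluationModel", "fit_ridge", "predict_gebv", "default_lambda"]

_LAMBDA_FLOOR = 1e-8


@dataclass
class EvaluationModel:
    """Fitted shrunken marker effects with their intercept and penalty."""

    marker_effects_hat: np.ndarray
    intercept: float
    ridge_lambda: float
    reference_size: int


def fit_ridge(
    X_ref: GenotypeMatrix,
    y: np.ndarray,
    ridge_lambda: float,
    method: str = "auto",
) -> EvaluationModel:
    """Fit marker effects by ridge regression of centered phenotypes on X'.

    ``method`` selects the L x L primal normal equations or the n x n dual
    (kernel) form; ``"auto"`` picks whichever system is smaller. The two
    routes agree to numerical precision and both are exposed for testing.
    """
    y = np.asarray(y, dtype=float)
    n = X_ref.n_individuals
    L = X_ref.n_loci
    if y.shape != (n,):
        raise ValueError("phenotype length must match the reference size")
    if n < 2:
        raise ValueError("at least two reference individuals are required")
    if ridge_lambda <= 0:
        raise ValueError("ridge_lambda must be positive")
    intercept = float(y.mean())
    y_c = y - intercept
    if np.allclose(y_c, 0.0):
        warnings.warn("all phenotypes equal: returning zero marker effects")
        return EvaluationModel(np.zeros(L), intercept, ridge_lambda, n)
    Xf = X_ref.X.astype(float)  # L x n
    if method == "auto":
        method = "primal" if L <= n else "dual"
    if method == "primal":
        A = Xf @ Xf.T + ridge_lambda * np.eye(L)
        a_hat = scipy.linalg.solve(A, Xf @ y_c, assume_a="pos")
    elif method == "dual":
        K = Xf.T @ Xf + ridge_lambda * np.eye(n)
        a_hat = Xf @ scipy.linalg.solve(K, y_c, assume_a="pos")
    else:
        raise ValueError("method must be 'auto', 'primal' or 'dual'")
    return EvaluationModel(a_hat, intercept, ridge_lambda, n)


def predict_gebv(model: EvaluationModel, X_target: GenotypeMatrix) -> np.ndarray:
    """GEBV_i = intercept + sum_l a_hat_l X[l, i]."""
    if X_target.n_loci != model.marker_effects_hat.shape[0]:
        raise ValueError("target locus count does not match the fitted model")
    return model.intercept + model.marker_effects_hat @ X_target.X.astype(float)


def default_lambda(panel: HaplotypePanel, h2: float) -> float:
    """Variance-ratio ridge penalty from the panel's allele frequencies."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    p = allele_frequency(panel)
    sum_het = float(np.sum(2.0 * p * (1.0 - p)))
    if h2 == 1.0:
        return _LAMBDA_FLOOR
    return max(((1.0 - h2) / h2) * sum_het, _LAMBDA_FLOOR)
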