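"""Genomic relationship matrices for contribution optimization.

The uncentered relationship matrix ``G = X'X`` under the -1/0/1 coding counts
shared homozygous states: at one locus a shared homozygote contributes +1,
opposite homozygotes -1, and any pair involving a heterozygote 0. The
heterozygote-by-homozygote (He x Ho) count matrix ``Q`` lets those pairs be
re-weighted: ``G_adj = G + beta * Q`` assigns the per-locus value ``beta`` to
every He x Ho pair. Negative ``beta`` favors candidates carrying many loci in
He x Ho relationship with the rest of the population, i.e. candidates with an
excess of individual heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import GenotypeMatrix

__all__ = [
    "RelationshipSet",
    "HetHomVectors",
    "compute_grm",
    "compute_het_hom_counts",
    "compute_adjusted_grm",
    "project_pd",
    "default_eig_floor",
    "het_hom_vectors",
    "coancestry",
    "build_relationship_set",
]


@dataclass
class RelationshipSet:
    """G, Q, beta, the adjusted matrix and its positive-definite projection."""

    G: np.ndarray
    Q: np.ndarray
    beta: float
    Gstar: np.ndarray
    Gstar_pd: np.ndarray
    eig_floor: float

    @property
    def n_individuals(self) -> int:
        return self.G.shape[0]


@dataclass
class HetHomVectors:
    """Per-locus contribution-weighted heterozygote / homozygote proportions."""

    He: np.ndarray
    Ho: np.ndarray


def compute_grm(X: GenotypeMatrix) -> np.ndarray:
    """Uncentered realized relationship matrix G = X'X.

    Diagonal entries count the homozygous loci of each individual;
    off-diagonals count shared minus opposite homozygous states. No MAF
    centering and no heterozygosity scaling, so entries stay on the
    locus-count scale.
    """
    Xf = X.X.astype(np.float64)
    G = Xf.T @ Xf
    return (G + G.T) / 2.0


def compute_het_hom_counts(X: GenotypeMatrix) -> np.ndarray:
    """Q_ij = number of loci where exactly one of the pair is heterozygous.

    Symmetric with a zero diagonal (an individual cannot be in He x Ho
    relationship with itself).
    """
    het = (X.X == 0).astype(np.float64)
    hom = 1.0 - het
    Q = het.T @ hom
    return Q + Q.T


def compute_adjusted_grm(G: np.ndarray, Q: np.ndarray, beta: float) -> np.ndarray:
    """G + beta * Q: sets the per-locus value of every He x Ho pair to beta."""
    if not (-1.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [-1, 1]")
    return G + beta * Q


def default_eig_floor(M: np.ndarray) -> float:
    """Relative eigenvalue floor: 1e-8 times max(largest eigenvalue, 1)."""
    lam_max = float(np.linalg.eigvalsh((M + M.T) / 2.0)[-1])
    return 1e-8 * max(lam_max, 1.0)


def project_pd(M: np.ndarray, eig_floor: float | None = None) -> np.ndarray:
    """Spectral projection onto matrices with eigenvalues >= ``eig_floor``.

    Eigenvalues below the floor are raised to it; the result is the closest
    positive-definite matrix in spectral norm, at distance
    ``max(0, eig_floor - lambda_min(M))`` from the symmetrized input.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix entries must be finite")
    S = (M + M.T) / 2.0
    if eig_floor is None:
        eig_floor = default_eig_floor(S)
    if eig_floor <= 0:
        raise ValueError("eig_floor must be positive")
    lam, V = np.linalg.eigh(S)
    if lam[0] >= eig_floor:
        return S
    lam_clipped = np.maximum(lam, eig_floor)
    P = (V * lam_clipped) @ V.T
    return (P + P.T) / 2.0


def het_hom_vectors(X: GenotypeMatrix, c: np.ndarray) -> HetHomVectors:
    """Contribution-weighted per-locus heterozygote/homozygote proportions.

    ``He_l`` is the summed contribution of parents heterozygous at locus l,
    ``Ho_l`` the homozygous complement; they sum to 1 at every locus. The
    quadratic form satisfies ``c'Qc = 2 He'Ho`` (each unordered He x Ho pair
    is counted twice in the symmetric Q).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < -1e-12) or abs(c.sum() - 1.0) > 1e-8:
        raise ValueError("contributions must be nonnegative and sum to 1")
    het = (X.X == 0).astype(np.float64)
    He = het @ c
    Ho = (1.0 - het) @ c
    return HetHomVectors(He=He, Ho=Ho)


def coancestry(
    c: np.ndarray,
    M: np.ndarray,
    n_loci: int | None = None,
    normalized: bool = True,
) -> float:
    """Quadratic form c'Mc, per-locus normalized by default.

    With the unmodified G this is the expected inbreeding of the
    contribution-weighted parental pool under panmixia ("true" coancestry
    when M = G regardless of the beta used for selection). Division by the
    locus count puts it on the [-1, 1] per-locus scale.
    """
    c = np.asarray(c, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1] or M.shape[0] != c.shape[0]:
        raise ValueError("dimension mismatch between c and M")
    if np.any(c < -1e-12) or abs(c.sum() - 1.0) > 1e-8:
        raise ValueError("contributions must be nonnegative and sum to 1")
    value = float(c @ M @ c)
    if normalized:
        if n_loci is None or n_loci <= 0:
            raise ValueError("n_loci must be given (and positive) when normalizing")
        value /= n_loci
    return value


def build_relationship_set(
    X: GenotypeMatrix, beta: float, eig_floor: float | None = None
) -> RelationshipSet:
    """Assemble G, Q, the beta-adjusted matrix and its PD projection."""
    G = compute_grm(X)
    Q = compute_het_hom_counts(X)
    Gstar = compute_adjusted_grm(G, Q, beta)
    if eig_floor is None:
        eig_floor = default_eig_floor(Gstar)
    Gstar_pd = project_pd(Gstar, eig_floor)
    return RelationshipSet(
        G=G, Q=Q, beta=beta, Gstar=Gstar, Gstar_pd=Gstar_pd, eig_floor=eig_floor
    )
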