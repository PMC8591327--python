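"""Genotype containers, coding conversions and the additive trait model.

Phased genotypes are stored haplotype-major as 0/1 allele indicators; the
-1/0/1 genotype coding used by the relationship matrices is always derived
from the haplotypes, never stored alongside them, so phase and code cannot
disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "GenotypeMatrix",
    "GeneticMap",
    "TraitModel",
    "encode_genotypes",
    "allele_frequency",
    "maf_filter",
    "shuffle_alleles",
    "true_breeding_value",
    "simulate_phenotypes",
    "haplotype_r2",
    "adjacent_r2",
]


@dataclass
class HaplotypePanel:
    """Phased diploid panel: rows ``2k`` and ``2k+1`` are individual ``k``.

    Parameters
    ----------
    alleles
        ``(2N, L)`` array of 0/1 allele indicators.
    individual_ids
        ``N`` labels, one per individual.
    generation
        Nonoverlapping-generation index, 0 for founders.
    """

    alleles: np.ndarray
    individual_ids: list[str]
    generation: int = 0

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (2N x L) array")
        if self.alleles.shape[0] != 2 * len(self.individual_ids):
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.individual_ids)} individuals (expected 2 per individual)"
            )
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele indicators must be 0 or 1")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        self.individual_ids = list(self.individual_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def haplotypes_of(self, k: int) -> np.ndarray:
        """The two haplotype rows of individual ``k`` as a ``(2, L)`` view."""
        return self.alleles[2 * k : 2 * k + 2]

    def subset_loci(self, index: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            self.alleles[:, np.asarray(index)], self.individual_ids, self.generation
        )


@dataclass
class GenotypeMatrix:
    """Loci-by-individuals genotype matrix in the -1/0/1 coding.

    The two homozygous states map to -1 and +1 and the heterozygote to 0;
    no allele-frequency centering or heterozygosity scaling is applied.
    """

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (L x N)")
        if self.X.size and not np.isin(self.X, (-1, 0, 1)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1}")

    @property
    def n_loci(self) -> int:
        return self.X.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.X.shape[1]


@dataclass
class GeneticMap:
    """Per-locus chromosome assignment and genetic position in centimorgans."""

    locus_ids: list[str]
    chromosome: np.ndarray
    pos_cM: np.ndarray

    def __post_init__(self) -> None:
        self.locus_ids = list(self.locus_ids)
        self.chromosome = np.asarray(self.chromosome)
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        if not (len(self.locus_ids) == len(self.chromosome) == len(self.pos_cM)):
            raise ValueError("locus_ids, chromosome and pos_cM must have equal length")
        for chrom in pd.unique(self.chromosome):
            pos = self.pos_cM[self.chromosome == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions on chromosome {chrom!r} are not sorted")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def chromosomes(self) -> list:
        """Chromosome ids in order of first appearance."""
        return list(pd.unique(self.chromosome))

    def loci_on(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.chromosome == chrom)

    def subset(self, index: np.ndarray) -> "GeneticMap":
        index = np.asarray(index)
        return GeneticMap(
            [self.locus_ids[i] for i in index],
            self.chromosome[index],
            self.pos_cM[index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus_id": self.locus_ids, "chrom": self.chromosome, "pos_cM": self.pos_cM}
        )


@dataclass
class TraitModel:
    """Additive trait: per-locus effects on the -1/0/1 scale plus heritability."""

    effects: np.ndarray
    h2: float

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("allelic effects must be finite")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")

    def subset(self, index: np.ndarray) -> "TraitModel":
        return TraitModel(self.effects[np.asarray(index)], self.h2)


def encode_genotypes(panel: HaplotypePanel) -> GenotypeMatrix:
    """Derive the L x N -1/0/1 genotype matrix from a phased panel.

    ``X[l, i] = h1 + h2 - 1`` for the two allele indicators of individual
    ``i`` at locus ``l``: (1,1) -> 1, (0,0) -> -1, heterozygote -> 0.
    """
    a = panel.alleles
    X = (a[0::2].astype(np.int16) + a[1::2] - 1).T
    return GenotypeMatrix(X.astype(np.int8))


def allele_frequency(panel: HaplotypePanel) -> np.ndarray:
    """Per-locus frequency of the '1' allele over the 2N haplotypes."""
    if panel.n_individuals == 0:
        raise ValueError("cannot compute allele frequencies of an empty panel")
    return panel.alleles.mean(axis=0)


def maf_filter(
    panel: HaplotypePanel, threshold: float
) -> tuple[HaplotypePanel, np.ndarray]:
    """Keep loci whose minor allele frequency strictly exceeds ``threshold``.

    Returns the filtered panel together with the kept locus index, so the
    caller can subset the genetic map and allelic effects consistently.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    p = allele_frequency(panel)
    keep = np.flatnonzero(np.minimum(p, 1.0 - p) > threshold)
    return panel.subset_loci(keep), keep


def shuffle_alleles(panel: HaplotypePanel, seed) -> HaplotypePanel:
    """Permute alleles among haplotypes independently at each locus.

    Per-locus allele counts (hence frequencies) are exactly preserved while
    linkage disequilibrium between loci is destroyed; used to build the
    LD-free counterpart of a panel.
    """
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random(panel.alleles.shape), axis=0)
    shuffled = np.take_along_axis(panel.alleles, perm, axis=0)
    return HaplotypePanel(shuffled, panel.individual_ids, panel.generation)


def true_breeding_value(X: GenotypeMatrix, trait: TraitModel) -> np.ndarray:
    """TBV_i = sum_l a_l X[l, i] under the additive model."""
    if X.n_loci != trait.effects.shape[0]:
        raise ValueError(
            f"{X.n_loci} loci in genotypes but {trait.effects.shape[0]} effects"
        )
    return trait.effects @ X.X


def simulate_phenotypes(
    tbv: np.ndarray, h2: float, sigma_g2: float, seed
) -> np.ndarray:
    """Add a Normal(0, (1-h2)*sigma_g2) environmental deviate to each TBV.

    ``sigma_g2`` is the genetic variance the caller wants the heritability to
    refer to (typically the variance of the current generation's TBV).
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]; h2 = 0 leaves the scaling undefined")
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be nonnegative")
    tbv = np.asarray(tbv, dtype=float)
    rng = np.random.default_rng(seed)
    sd = np.sqrt((1.0 - h2) * sigma_g2)
    return tbv + rng.normal(0.0, sd, size=tbv.shape)


def haplotype_r2(panel: HaplotypePanel, l1: int, l2: int) -> float:
    """Squared haplotype correlation (LD r^2) between two loci.

    Returns NaN if either locus is monomorphic in the panel.
    """
    a = panel.alleles[:, l1].astype(float)
    b = panel.alleles[:, l2].astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def adjacent_r2(panel: HaplotypePanel, gmap: GeneticMap | None = None) -> float:
    """Mean LD r^2 over adjacent polymorphic locus pairs.

    With a map, pairs spanning a chromosome boundary are excluded.
    """
    vals = []
    for l in range(panel.n_loci - 1):
        if gmap is not None and gmap.chromosome[l] != gmap.chromosome[l + 1]:
            continue
        r2 = haplotype_r2(panel, l, l + 1)
        if np.isfinite(r2):
            vals.append(r2)
    return float(np.mean(vals)) if vals else float("nan")
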