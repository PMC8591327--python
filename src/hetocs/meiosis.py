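"""Gamete formation with Poisson (Haldane, no-interference) crossovers.

Per chromosome the crossover count is Poisson with mean equal to the map
length in Morgans and crossover positions are uniform in genetic distance,
which yields Haldane recombination fractions r = (1 - exp(-2d))/2 between
loci d Morgans apart. No mutation is introduced: every offspring allele is a
copy of a parental allele at the same locus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mating import MatePlan
from .popgen import GeneticMap, HaplotypePanel

__all__ = ["make_gamete", "make_offspring"]


def _chromosome_blocks(gmap: GeneticMap) -> list[tuple[np.ndarray, np.ndarray]]:
    """(locus index, cM positions) per chromosome, in map order."""
    return [
        (idx, gmap.pos_cM[idx])
        for chrom in gmap.chromosomes()
        for idx in [gmap.loci_on(chrom)]
    ]


def make_gamete(
    parent_haplotypes: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant haplotype from a parent's two phased haplotypes.

    Each chromosome starts on a fair-coin parental haplotype and switches at
    each crossover; a zero-length chromosome (or none drawn) transmits one
    parental haplotype intact.
    """
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.shape != (2, gmap.n_loci):
        raise ValueError("parent haplotypes must be 2 x L and aligned with the map")
    gamete = np.empty(gmap.n_loci, dtype=parent_haplotypes.dtype)
    for idx, pos in _chromosome_blocks(gmap):
        length_morgan = (pos[-1] - pos[0]) / 100.0 if pos.size else 0.0
        start = int(rng.integers(2))
        k = int(rng.poisson(length_morgan)) if length_morgan > 0 else 0
        if k == 0:
            gamete[idx] = parent_haplotypes[start, idx]
            continue
        xo = np.sort(rng.uniform(pos[0], pos[-1], size=k))
        # haplotype in use at a locus flips once per crossover to its left
        use = (start + np.searchsorted(xo, pos, side="left")) % 2
        gamete[idx] = parent_haplotypes[use, idx]
    return gamete


def make_offspring(
    panel: HaplotypePanel, plan: MatePlan, gmap: GeneticMap, seed
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Realize a mate plan: one offspring per pair-count unit.

    Each offspring receives one independent gamete from each parent; the
    output panel's generation counter is the input's plus one. Also returns
    the pedigree (offspring id, both parent ids, generation).
    """
    if plan.pair_counts.shape[0] != panel.n_individuals:
        raise ValueError("mate plan does not match the panel size")
    if gmap.n_loci != panel.n_loci:
        raise ValueError("map and panel disagree on locus count")
    rng = np.random.default_rng(seed)
    gen = panel.generation + 1
    alleles = np.empty((2 * plan.n_offspring, panel.n_loci), dtype=np.int8)
    ids, rows = [], []
    k = 0
    for i, j, cnt in plan.pairs():
        for _ in range(cnt):
            alleles[2 * k] = make_gamete(panel.haplotypes_of(i), gmap, rng)
            alleles[2 * k + 1] = make_gamete(panel.haplotypes_of(j), gmap, rng)
            child = f"g{gen}_{k}"
            ids.append(child)
            rows.append(
                {
                    "id": child,
                    "parent1": panel.individual_ids[i],
                    "parent2": panel.individual_ids[j],
                    "generation": gen,
                }
            )
            k += 1
    pedigree = pd.DataFrame(rows, columns=["id", "parent1", "parent2", "generation"])
    return HaplotypePanel(alleles, ids, generation=gen), pedigree
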