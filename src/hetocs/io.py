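"""Tabular and VCF input/output.

All tabular files are tab-separated with headers. Phased VCF is read through
cyvcf2 (records with unphased genotypes are rejected — phase is load-bearing
for meiosis) and written as plain VCF 4.2 text with synthesized integer
positions derived from the centimorgan coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mating import MatePlan
from .popgen import GeneticMap, HaplotypePanel, TraitModel

__all__ = [
    "read_haplotypes_tsv",
    "write_haplotypes_tsv",
    "read_map_tsv",
    "write_map_tsv",
    "read_effects_tsv",
    "write_effects_tsv",
    "read_vcf",
    "write_vcf",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_plan_tsv",
    "read_plan_tsv",
]


def write_haplotypes_tsv(panel: HaplotypePanel, path, locus_ids=None) -> None:
    """Rows = haplotypes ('<id>|0' and '<id>|1'), columns = loci."""
    if locus_ids is None:
        locus_ids = [f"locus_{l}" for l in range(panel.n_loci)]
    hap_ids = [f"{iid}|{h}" for iid in panel.individual_ids for h in (0, 1)]
    df = pd.DataFrame(panel.alleles, index=hap_ids, columns=list(locus_ids))
    df.to_csv(path, sep="\t", index_label="haplotype_id")


def read_haplotypes_tsv(path, generation: int = 0) -> tuple[HaplotypePanel, list[str]]:
    """Inverse of :func:`write_haplotypes_tsv`; returns (panel, locus ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] % 2 != 0:
        raise ValueError("haplotype TSV must contain an even number of rows")
    ids = []
    for k in range(0, df.shape[0], 2):
        a = str(df.index[k]).rsplit("|", 1)[0]
        b = str(df.index[k + 1]).rsplit("|", 1)[0]
        if a != b:
            raise ValueError(f"rows {k} and {k + 1} belong to different individuals")
        ids.append(a)
    panel = HaplotypePanel(df.to_numpy(), ids, generation=generation)
    return panel, [str(c) for c in df.columns]


def write_map_tsv(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    return GeneticMap(
        [str(x) for x in df["locus_id"]], df["chrom"].to_numpy(), df["pos_cM"].to_numpy()
    )


def write_effects_tsv(effects: np.ndarray, locus_ids, path) -> None:
    pd.DataFrame({"locus_id": list(locus_ids), "effect": np.asarray(effects)}).to_csv(
        path, sep="\t", index=False
    )


def read_effects_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df["effect"].to_numpy(dtype=float), [str(x) for x in df["locus_id"]]


def _bp_positions(pos_cM: np.ndarray) -> np.ndarray:
    """Strictly increasing integer pseudo-positions from cM coordinates."""
    bp = np.round(np.asarray(pos_cM) * 1e4).astype(np.int64) + 1
    for i in range(1, len(bp)):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return bp


def write_vcf(panel: HaplotypePanel, gmap: GeneticMap, path) -> None:
    """Phased VCF 4.2 ('|' separated GT) with per-chromosome pseudo-bp."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gmap.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        for chrom in gmap.chromosomes():
            idx = gmap.loci_on(chrom)
            bp = _bp_positions(gmap.pos_cM[idx])
            for l, pos in zip(idx, bp):
                gts = "\t".join(
                    f"{panel.alleles[2 * k, l]}|{panel.alleles[2 * k + 1, l]}"
                    for k in range(panel.n_individuals)
                )
                fh.write(
                    f"{chrom}\t{pos}\t{gmap.locus_ids[l]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
                )


def read_vcf(path, generation: int = 0) -> tuple[HaplotypePanel, list[str]]:
    """Load a phased VCF; unphased genotype records raise a clear error."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    columns, locus_ids = [], []
    for variant in vcf:
        gts = variant.genotypes  # [allele1, allele2, phased_flag] per sample
        col = np.empty(2 * len(ids), dtype=np.int8)
        for k, gt in enumerate(gts):
            if len(gt) < 3 or not gt[2]:
                raise ValueError(
                    f"unphased genotype at {variant.CHROM}:{variant.POS} "
                    f"(sample {ids[k]}): phased '|' genotypes are required"
                )
            if gt[0] < 0 or gt[1] < 0:
                raise ValueError(
                    f"missing genotype at {variant.CHROM}:{variant.POS} is not supported"
                )
            col[2 * k] = gt[0]
            col[2 * k + 1] = gt[1]
        columns.append(col)
        locus_ids.append(variant.ID if variant.ID not in (None, ".") else
                         f"{variant.CHROM}_{variant.POS}")
    if not columns:
        raise ValueError("VCF contains no variants")
    alleles = np.stack(columns, axis=1)
    return HaplotypePanel(alleles, ids, generation=generation), locus_ids


def write_matrix_tsv(M: np.ndarray, ids, path) -> None:
    pd.DataFrame(np.asarray(M), index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", index_label="id"
    )


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_plan_tsv(plan: MatePlan, ids, path) -> None:
    ids = list(ids)
    rows = [
        {"parent_i": ids[i], "parent_j": ids[j], "count": cnt}
        for i, j, cnt in plan.pairs()
    ]
    pd.DataFrame(rows, columns=["parent_i", "parent_j", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_plan_tsv(path, ids) -> MatePlan:
    ids = list(ids)
    pos = {iid: k for k, iid in enumerate(ids)}
    df = pd.read_csv(path, sep="\t")
    n = len(ids)
    P = np.zeros((n, n), dtype=np.int64)
    for _, row in df.iterrows():
        i, j = pos[str(row["parent_i"])], pos[str(row["parent_j"])]
        P[i, j] += int(row["count"])
        P[j, i] += int(row["count"])
    return MatePlan(pair_counts=P, n_offspring=int(df["count"].sum()))
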