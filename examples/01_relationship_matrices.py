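"""Relationship matrices on a tiny phased panel.

Builds a 3-individual, 4-locus panel, derives the -1/0/1 genotype coding,
and prints G = X'X, the He x Ho count matrix Q, and the adjusted matrix
G + beta*Q for beta = -0.5 (heterozygote-favoring).
"""

import numpy as np

import hetocs as h

# genotype columns: A=(1,1,0,-1), B=(1,-1,0,0), C=(0,1,1,1)
X = np.array([[1, 1, 0], [1, -1, 1], [0, 0, 1], [-1, 0, 1]])
hap = np.zeros((6, 4), dtype=np.int8)
for i in range(3):
    for l in range(4):
        if X[l, i] == 1:
            hap[2 * i, l] = hap[2 * i + 1, l] = 1
        elif X[l, i] == 0:
            hap[2 * i + 1, l] = 1
panel = h.HaplotypePanel(hap, ["A", "B", "C"])

Xg = h.encode_genotypes(panel)
rel = h.build_relationship_set(Xg, beta=-0.5)

print("genotypes (loci x individuals):\n", Xg.X)
print("\nG = X'X (diagonal = homozygous-locus counts):\n", rel.G)
print("\nQ (per-pair He x Ho locus counts, zero diagonal):\n", rel.Q)
print("\nG* = G - 0.5 Q (He x Ho pairs now worth -0.5 per locus):\n", rel.Gstar)

c = np.full(3, 1 / 3)
print("\nuniform-contribution coancestry c'Gc / L =",
      h.coancestry(c, rel.G, n_loci=4))
print("same with G*: ", h.coancestry(c, rel.Gstar, n_loci=4),
      " (lower: the negative beta rewards He x Ho pairs)")
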