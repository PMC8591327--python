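"""Which factor drives the outcome? Sequential ANOVA of a scenario grid.

Runs a small alpha x beta x mating grid (3 replicates each, 5 generations)
and decomposes the final-generation gain into the sequential contributions
of alpha, beta, alpha^2 and mate allocation.
"""

import hetocs as h

panel, gmap = h.simulate_founders(h.FounderSpec(seed=7))
effects = h.draw_effects(panel.n_loci, seed=8, founder_panel=panel,
                         target_tbv_sd=25.9)

df = h.run_grid(panel, gmap, effects,
                alphas=(0.1, 0.5, 0.9), betas=(-0.5, 0.5),
                mate_modes=("lp", "random"),
                n_generations=5, n_replicates=3, root_seed=2)
final = df[df.generation == 5]

res = h.anova_type1(final, model=1, response="gain")
print(res.table.to_string(index=False, float_format=lambda v: f"{v:10.4g}"))
print(f"\nadjusted R2 = {res.adj_r2:.3f}")
print("pct_variance: share of the total sum of squares entering with each")
print("term, in model order (alpha, beta, alpha^2, mate allocation).")
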