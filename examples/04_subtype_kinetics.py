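"""Receptor-subtype kinetics: α leads early, β catches up and overtakes late.

Runs the interaction contrast per receptor at each time, counts gate-passing
genes, and fits the fold-fold total-least-squares slope (β on α) at 24 h.
"""

import dataclasses

import trsubtype as ts
import trsubtype.diffexpr as de

config = ts.SimulationConfig(n_genes=1000, seed=5)
specs = ts.draw_gene_effects(config)

de_by_time = {}
for t in config.times:
    sub_cfg = dataclasses.replace(config, times=(t,))
    matrix, designs = ts.simulate_timecourse(specs, sub_cfg)
    fit = de.fit_cell_means(matrix, designs)
    moderation = de.moderate_variances(fit.s2, fit.df)
    de_by_time[t] = {
        r: de.test_contrast(fit, moderation, de.interaction_contrast(r))
        for r in ("TRA", "TRB")
    }

for t in config.times:
    s = ts.concordance(de_by_time[t]["TRA"], de_by_time[t]["TRB"], time_hr=t)
    print(
        f"{t:>4.0f} h: {s.n_alpha:4d} genes with TRA, {s.n_beta:4d} with TRB, "
        f"overlap {s.n_overlap:4d}, r = {s.pearson_r:.2f}, slope = {s.slope:.2f}"
    )

classes = ts.kinetic_classify(de_by_time)
print("\nkinetic classes:", classes["kinetic_class"].value_counts().to_dict())
# More genes pass with TRα at 3 h, more with TRβ at 24 h, and the 24 h slope
# exceeds 1: the β-preferential late subset tilts the fold-fold cloud.
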