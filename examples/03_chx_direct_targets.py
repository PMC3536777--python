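"""Call direct receptor targets from the cycloheximide arm.

A direct target keeps its T3 response when translation is blocked:
persistence = (T3+CHX minus CHX) / (T3 minus control) on the log2 scale.
Persistence >= 1 reads direct, <= 0.25 indirect, in between attenuated.
"""

import trsubtype as ts
import trsubtype.diffexpr as de

config = ts.SimulationConfig(n_genes=600, sigma_fixed=0.15, seed=3)
specs = ts.draw_gene_effects(config)
matrix, designs = ts.simulate_chx_arm(specs, config)

grouping = ("receptor", "ligand", "chx")
fit = de.fit_cell_means(matrix, designs, grouping)
moderation = de.moderate_variances(fit.s2, fit.df)

for receptor in ("TRA", "TRB"):
    result = de.test_contrast(fit, moderation, de.t3_contrast(receptor, chx=False))
    responsive = de.gate_significant(result)
    calls = ts.call_direct_targets(
        matrix, designs, receptor, probes=list(responsive.index)
    )
    counts = calls["call"].value_counts()
    binary_direct = (calls["binary_call"] == "direct").mean()
    print(
        f"{receptor}: {len(calls)} T3-responsive genes scored; "
        f"{counts.to_dict()}; {binary_direct:.0%} direct by the midpoint rule"
    )

flags = ts.chx_derepression_flags(matrix, designs)
selective = flags[flags["flag"].isin(["TRA", "TRB"])]
print(f"{len(selective)} genes de-repressed by CHX alone in only one receptor line")
# The strict >= 100%-persistence bar under-calls at realistic noise (an
# estimate centred at exactly 1.0 falls below it half the time — hence the
# large "attenuated" band), while the midpoint-rule binary call tracks the
# generator's direct_fraction (default 80%).
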