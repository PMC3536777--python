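"""Per-gene EC50 estimation and subtype comparison.

Fits the four-parameter Hill model to a simulated T3 dose series for both
receptor lines and flags genes whose β/α EC50 ratio interval excludes 1
(subtype-shifted concentration dependence).
"""

import numpy as np

import trsubtype as ts
import trsubtype.dose_response as dr

config = ts.SimulationConfig(
    n_genes=6,
    archetype_proportions={a: (1.0 if a == "OI" else 0.0) for a in ts.ARCHETYPES},
    effect_mu_log=float(np.log(2.0)),  # robustly induced targets
    sigma_fixed=0.15,
    seed=9,
)
specs = ts.draw_gene_effects(config)
matrix, designs = ts.simulate_dose_series(specs, config)

print(f"{'gene':>6} {'EC50 a (nM)':>12} {'EC50 b (nM)':>12} {'true a':>8} {'true b':>8} shifted")
for spec in specs:
    fits = {}
    for receptor in ("TRA", "TRB"):
        sel = [d for d in designs if d.receptor == receptor]
        doses = np.array([d.dose_nM for d in sel])
        responses = matrix.data.loc[spec.probe_id, [d.sample_id for d in sel]].to_numpy()
        fits[receptor] = dr.fit_hill(
            doses, responses, direction="induced", n_boot=100, seed=11
        )
    comparison = dr.compare_ec50(fits["TRA"], fits["TRB"])
    print(
        f"{spec.probe_id:>6} {fits['TRA'].ec50:12.3f} {fits['TRB'].ec50:12.3f} "
        f"{spec.ec50['TRA']:8.3f} {spec.ec50['TRB']:8.3f} {comparison.shifted}"
    )
# Estimated EC50s track the generating values (most in the low-nM range);
# genes with genuinely different per-receptor EC50s come out flagged.
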