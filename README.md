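# trsubtype

Comparative analysis of gene regulation by the two thyroid-hormone receptor
subtypes, TRα and TRβ.

The two receptors are close homologues that bind the same hormone (T3) yet
drive distinct physiology. A classic way to dissect this is to express equal
levels of each receptor in a common cell background (e.g. a liver-derived
line plus parental controls), treat with vehicle or saturating T3 over a
time course, and ask per gene: how much of the response comes from the
*unliganded* receptor, how much from the hormone, how the two subtypes'
kinetics and dose requirements differ, and which responses are *direct*
(persisting when protein synthesis is blocked with cycloheximide).
`trsubtype` implements that full analysis as a Python library, together with
a synthetic-data generator that emulates the experimental design so every
stage can be validated against known ground truth.

## What it computes

**Factorial differential expression.** Per cell line and time point, genes
are modelled on a cell-means parameterisation over `receptor × ligand`
cells. Per-gene residual variances s²_g (pooled within cells, df = n − k)
are shrunk by empirical Bayes under the scaled inverse-chi-square hierarchy

    s̃²_g = (d₀·s₀² + df·s²_g) / (d₀ + df),

with (d₀, s₀²) estimated by moment-matching log s² via the digamma/trigamma
identities. Named contrasts give moderated t statistics with df + d₀ degrees
of freedom: the *unliganded effect* (receptor, vehicle) − (parental,
vehicle), the *ligand interaction* [(receptor, T3) − (receptor, vehicle)] −
[(parental, T3) − (parental, vehicle)], the within-receptor T3 effect, and
the liganded level versus parental baseline. Benjamini–Hochberg adjustment
and the inclusive gate |fold| ≥ 2 with adjusted p ≤ 0.05 flag responders.

**Pattern archetypes.** Each significant gene's (unliganded, liganded)
expression levels relative to parental cells, as linear fold changes clamped
to [0.5, 2], are assigned to the nearest of nine archetypes on the
{0.5, 1, 2}² grid — RR, RO, RI, OR, OO, OI, IR, IO, II (first letter:
level without hormone; second: level with hormone; R repressed, O baseline,
I induced) — by minimal Euclidean distance in fold-change space. OO is
recorded but excluded from the reported table.

**Direct-target calling.** From a four-condition cycloheximide arm
(control, T3, CHX, T3+CHX) the persistence ratio
Δ_CHX / Δ_free = (T3+CHX − CHX) / (T3 − control) classifies each
T3-responsive gene: ≥ 1.0 direct, ≤ 0.25 indirect, attenuated between.
Receptor-selective de-repression by CHX alone is flagged separately.

**Subtype concordance and kinetics.** Per-time counts of gate-passing genes
per receptor, their overlap, the fold–fold Pearson r and total-least-squares
slope (β on α), and kinetic classes: alpha_early, beta_late
(β-preferential at 24 h), concordant, discordant_other.

**Dose response.** Four-parameter Hill fits per gene and receptor,
response(d) = bottom + (top − bottom)·d^h/(d^h + EC50^h), multi-started over
a log-spaced EC50 grid, with replicate-bootstrap intervals and a paired
bootstrap on the β/α EC50 ratio to flag subtype-shifted concentration
dependence.

## Worked example

`examples/04_subtype_kinetics.py` simulates 1000 genes under the default
study conditions and compares the receptors per time point:

```
   3 h:  380 genes with TRA,  120 with TRB, overlap  115, r = 0.95, slope = 0.52
   6 h:  380 genes with TRA,  284 with TRB, overlap  266, r = 0.98, slope = 0.80
  24 h:  272 genes with TRA,  474 with TRB, overlap  267, r = 0.97, slope = 1.52

kinetic classes: {'alpha_early': 265, 'concordant': 111, 'beta_late': 72, 'discordant_other': 48}
```

Reading: the same genes respond with both receptors (r ≥ 0.95 throughout),
but TRα responses emerge earlier (380 vs 120 gate-passers at 3 h) while TRβ
dominates by 24 h (474 vs 272), and the fold–fold slope rises above 1 as a
β-preferential late subset emerges. The other examples cover simulation +
differential testing (`01`), the pattern table (`02`), CHX direct-target
calls (`03`), per-gene EC50s (`05`) and the end-to-end pipeline (`06`).

A thin CLI wraps the same stages:

```bash
trsubtype simulate --seed 3 --outdir simout
trsubtype de --matrix simout/timecourse_matrix.tsv --design simout/timecourse_design.tsv \
    --contrast interaction --receptor TRA --time 3 --out de.tsv
trsubtype run-all --seed 3 --outdir run
```

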