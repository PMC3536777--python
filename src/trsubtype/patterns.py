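"""Regulation-pattern classification by nearest archetype.

Each significant probe is summarised by a two-component fold-change vector:
its expression level with unliganded receptor and its level with receptor
plus T3, both as linear fold changes relative to parental cells (mirror
patterns such as RO — repressed without hormone, restored to baseline by T3
— therefore describe genuinely T3-responsive genes, while RR/II are
constitutive). Nine hypothetical patterns are defined
on a 3x3 grid of {repressed = 0.5, no effect = 1, induced = 2} per axis and
labelled by two letters (first = unliganded axis, second = ligand axis):
RR, RO, RI, OR, OO, OI, IR, IO, II.

Fold changes are first clamped to [0.5, 2] to limit the influence of
extremes, then assigned to the archetype at minimal Euclidean distance *in
linear fold-change space* — deliberately not log space, which makes the
metric asymmetric around 1 (a documented property, not a bug). OO ("no
substantial effect despite statistical significance") is recorded but left
out of the reported pattern table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ARCHETYPE_ORDER = ("RR", "RO", "RI", "OR", "OO", "OI", "IR", "IO", "II")
_LETTER_FC = {"R": 0.5, "O": 1.0, "I": 2.0}
#: label -> (unliganded fold change, ligand fold change)
ARCHETYPE_VECTORS = {
    label: (_LETTER_FC[label[0]], _LETTER_FC[label[1]]) for label in ARCHETYPE_ORDER
}
REPORTED_ARCHETYPES = tuple(a for a in ARCHETYPE_ORDER if a != "OO")

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PatternAssignment:
    probe_id: str
    label: str
    distance: float
    clamped_vector: tuple[float, float]
    input_vector: tuple[float, float]
    tie: bool = False


def clamp_fold_change(fc: float) -> float:
    """Clamp a linear fold change to [0.5, 2]; identity inside the band."""
    if not np.isfinite(fc) or fc <= 0:
        raise ValueError(f"fold change must be positive and finite, got {fc}")
    return float(min(max(fc, 0.5), 2.0))


def assign_pattern(fc_u: float, fc_l: float, probe_id: str = "") -> PatternAssignment:
    """Assign the archetype at minimal Euclidean distance to the clamped vector.

    Ties (within 1e-12) are broken by the canonical archetype listing order
    and flagged on the returned record.
    """
    cu, cl = clamp_fold_change(fc_u), clamp_fold_change(fc_l)
    best_label, best_dist = None, np.inf
    tie = False
    for label in ARCHETYPE_ORDER:
        au, al = ARCHETYPE_VECTORS[label]
        dist = float(np.hypot(cu - au, cl - al))
        if dist < best_dist - _TIE_TOL:
            best_label, best_dist, tie = label, dist, False
        elif abs(dist - best_dist) <= _TIE_TOL:
            tie = True
    return PatternAssignment(
        probe_id=probe_id, label=best_label, distance=best_dist,
        clamped_vector=(cu, cl), input_vector=(float(fc_u), float(fc_l)), tie=tie,
    )


def classify_probe_set(
    de_unliganded: pd.DataFrame,
    de_ligand: pd.DataFrame,
    alpha: float = 0.05,
    eligibility: str = "either",
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify eligible probes and tabulate per-pattern counts.

    Parameters
    ----------
    de_unliganded, de_ligand : contrast result tables (index = probe ids,
        columns including ``log2fc`` and ``p_adj``) for the unliganded and
        ligand axes; must cover the same probes.
    alpha : adjusted-p eligibility threshold.
    eligibility : which contrast must pass alpha — ``either`` (default),
        ``ligand_only``, ``unliganded_only`` or ``both``.

    Returns
    -------
    assignments : DataFrame (probe_id, label, distance, fc_u, fc_l, tie)
        for every eligible probe, OO included.
    counts : per-label counts over the eight reported patterns (OO excluded).
    """
    if set(de_unliganded.index) != set(de_ligand.index):
        raise ValueError("the two contrast tables must cover the same probes")
    de_ligand = de_ligand.loc[de_unliganded.index]
    pu = de_unliganded["p_adj"].to_numpy()
    pl = de_ligand["p_adj"].to_numpy()
    if eligibility == "either":
        eligible = (pu <= alpha) | (pl <= alpha)
    elif eligibility == "both":
        eligible = (pu <= alpha) & (pl <= alpha)
    elif eligibility == "ligand_only":
        eligible = pl <= alpha
    elif eligibility == "unliganded_only":
        eligible = pu <= alpha
    else:
        raise ValueError(f"unknown eligibility mode {eligibility!r}")
    fc_u = 2.0 ** de_unliganded["log2fc"].to_numpy()
    fc_l = 2.0 ** de_ligand["log2fc"].to_numpy()
    rows = []
    for i, probe in enumerate(de_unliganded.index):
        if not eligible[i]:
            continue
        a = assign_pattern(fc_u[i], fc_l[i], probe_id=str(probe))
        rows.append(
            {
                "probe_id": a.probe_id, "label": a.label, "distance": a.distance,
                "fc_u": a.clamped_vector[0], "fc_l": a.clamped_vector[1],
                "fc_u_raw": a.input_vector[0], "fc_l_raw": a.input_vector[1],
                "tie": a.tie,
            }
        )
    assignments = pd.DataFrame(
        rows,
        columns=["probe_id", "label", "distance", "fc_u", "fc_l",
                 "fc_u_raw", "fc_l_raw", "tie"],
    )
    counts = pd.Series(0, index=list(REPORTED_ARCHETYPES), name="n", dtype=int)
    if not assignments.empty:
        observed = assignments["label"].value_counts()
        for label in REPORTED_ARCHETYPES:
            counts[label] = int(observed.get(label, 0))
    return assignments, counts
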