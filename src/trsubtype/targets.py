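"""Direct-target calling from the cycloheximide (CHX) arm.

A gene whose T3 response does not require new protein synthesis is a direct
receptor target: pretreating with the translation inhibitor CHX should leave
its T3 response intact. The *persistence ratio* quantifies this per gene and
receptor at the early time point:

    persistence = (mean log2 T3+CHX - mean log2 CHX) / (mean log2 T3 - mean log2 control)

Signed division makes persistence of repression also read as ~1. The call is
three-way: ``direct`` at persistence >= 1.0 (response fully retained, the
"at least 100%" criterion), ``indirect`` at <= 0.25 (response essentially
abolished) and ``attenuated`` in between. A ``binary_call`` using the 0.5
midpoint between the two generative hypotheses (full persistence vs none) is
provided for benchmarking against known ground truth.

The module also flags receptor-selective de-repression by CHX alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffexpr
from .matrixio import ExpressionMatrix, SampleDesign

DIRECT_THRESHOLD = 1.0
INDIRECT_THRESHOLD = 0.25
DENOMINATOR_FLOOR = 0.1  # log2 units; below this the ratio is undefined


class PersistenceUndefinedError(ValueError):
    """The free T3 response is too small to form a meaningful ratio."""


@dataclass(frozen=True)
class DirectnessCall:
    probe_id: str
    receptor: str
    persistence: float
    call: str          # direct / attenuated / indirect
    binary_call: str   # direct / indirect (midpoint rule, for benchmarking)
    chx_alone_effect: float
    delta_free: float
    delta_chx: float


def _condition_means(
    matrix: ExpressionMatrix, designs: list[SampleDesign], receptor: str
) -> dict[str, np.ndarray]:
    groups: dict[str, list[str]] = {"ctl": [], "T3": [], "chx": [], "T3chx": []}
    for d in designs:
        if d.receptor != receptor:
            continue
        key = {(False, False): "ctl", (True, False): "T3",
               (False, True): "chx", (True, True): "T3chx"}[(d.ligand == "T3", d.chx)]
        groups[key].append(d.sample_id)
    for key, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(
                f"CHX arm needs >= 2 replicates of condition {key!r} for receptor {receptor}"
            )
    X = matrix.data
    return {k: X[ids].to_numpy().mean(axis=1) for k, ids in groups.items()}


def _ratio_and_calls(
    means: dict[str, np.ndarray],
    baseline_mode: str,
    floor: float,
    direct_threshold: float,
    indirect_threshold: float,
):
    delta_free = means["T3"] - means["ctl"]
    if baseline_mode == "chx":
        delta_chx = means["T3chx"] - means["chx"]
    elif baseline_mode == "control":
        delta_chx = means["T3chx"] - means["ctl"]
    else:
        raise ValueError(f"unknown baseline mode {baseline_mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(delta_free) >= floor, delta_chx / delta_free, np.nan)
    call = np.where(
        ratio >= direct_threshold, "direct",
        np.where(ratio <= indirect_threshold, "indirect", "attenuated"),
    )
    binary = np.where(ratio >= 0.5, "direct", "indirect")
    return delta_free, delta_chx, ratio, call, binary


def persistence_ratio(
    matrix: ExpressionMatrix,
    designs: list[SampleDesign],
    probe: str,
    receptor: str,
    baseline_mode: str = "chx",
    floor: float = DENOMINATOR_FLOOR,
) -> float:
    """Persistence ratio of one probe's T3 response under CHX.

    Raises :class:`PersistenceUndefinedError` when the free T3 response is
    below the denominator floor (default 0.1 log2 units).
    """
    means = _condition_means(matrix, designs, receptor)
    idx = matrix.probe_ids.index(probe)
    means = {k: v[[idx]] for k, v in means.items()}
    delta_free, _, ratio, _, _ = _ratio_and_calls(
        means, baseline_mode, floor, DIRECT_THRESHOLD, INDIRECT_THRESHOLD
    )
    if np.isnan(ratio[0]):
        raise PersistenceUndefinedError(
            f"|free T3 response| = {abs(delta_free[0]):.4g} < floor {floor} for probe {probe!r}"
        )
    return float(ratio[0])


def call_direct_targets(
    matrix: ExpressionMatrix,
    designs: list[SampleDesign],
    receptor: str,
    probes: list[str] | None = None,
    baseline_mode: str = "chx",
    floor: float = DENOMINATOR_FLOOR,
    direct_threshold: float = DIRECT_THRESHOLD,
    indirect_threshold: float = INDIRECT_THRESHOLD,
) -> pd.DataFrame:
    """Directness calls for a set of T3-responsive probes in one receptor line.

    ``probes`` should normally be the probes passing the T3 significance gate
    (defaults to every probe whose free response clears the denominator
    floor). Probes below the floor are dropped. Returns a DataFrame indexed
    by probe with persistence, three-way call, binary call and the
    CHX-alone effect.
    """
    means = _condition_means(matrix, designs, receptor)
    delta_free, delta_chx, ratio, call, binary = _ratio_and_calls(
        means, baseline_mode, floor, direct_threshold, indirect_threshold
    )
    chx_alone = means["chx"] - means["ctl"]
    table = pd.DataFrame(
        {
            "receptor": receptor,
            "persistence": ratio,
            "call": call,
            "binary_call": binary,
            "chx_alone_effect": chx_alone,
            "delta_free": delta_free,
            "delta_chx": delta_chx,
        },
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )
    if probes is not None:
        missing = [p for p in probes if p not in table.index]
        if missing:
            raise KeyError(f"probe(s) not in matrix: {missing[:5]}")
        table = table.loc[probes]
    return table[table["persistence"].notna()]


def chx_derepression_flags(
    matrix: ExpressionMatrix,
    designs: list[SampleDesign],
    receptors: tuple[str, str] = ("TRA", "TRB"),
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag probes de-repressed by CHX alone in one receptor line but not the other.

    Runs the CHX-alone contrast (vehicle+CHX vs vehicle) per receptor through
    the moderated pipeline, applies the standard gate, and labels each probe
    ``none``, one receptor's name (selective) or ``both``.
    """
    grouping = ("receptor", "ligand", "chx")
    fit = diffexpr.fit_cell_means(matrix, designs, grouping)
    moderation = diffexpr.moderate_variances(fit.s2, fit.df)
    passes = {}
    effects = {}
    for r in receptors:
        res = diffexpr.test_contrast(fit, moderation, diffexpr.chx_alone_contrast(r))
        gated = diffexpr.gate_significant(res, fold_cutoff, alpha)
        passes[r] = set(gated.index)
        effects[r] = res["log2fc"]
    a, b = receptors
    rows = []
    for probe in matrix.probe_ids:
        in_a, in_b = probe in passes[a], probe in passes[b]
        if in_a and in_b:
            flag = "both"
        elif in_a:
            flag = a
        elif in_b:
            flag = b
        else:
            flag = "none"
        rows.append(
            {
                "probe_id": probe, "flag": flag,
                f"chx_log2fc_{a}": float(effects[a][probe]),
                f"chx_log2fc_{b}": float(effects[b][probe]),
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")
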