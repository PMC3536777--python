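"""Receptor-subtype concordance and kinetics analytics.

Quantifies how similarly TRα and TRβ regulate the transcriptome: per-time
counts of gate-passing genes, fold-fold Pearson correlation and
total-least-squares slope (β on α), cross-receptor and cross-cell-line
overlap counts, kinetic response classes (early-α, late-β) and per-pattern
overlap tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import diffexpr
from .patterns import REPORTED_ARCHETYPES

BETA_PREFERENTIAL_FACTOR = 2.0  # |log2fc_beta| >= factor * |log2fc_alpha| at 24 h


@dataclass
class ConcordanceSummary:
    time_hr: float
    n_alpha: int
    n_beta: int
    n_overlap: int
    n_union: int
    pearson_r: float
    slope: float
    defined: bool


def tls_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Orthogonal-regression (total least squares) slope of y on x.

    Both axes are treated as noisy: the slope is the direction of the first
    principal axis of the centred point cloud.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([x - x.mean(), y - y.mean()])
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[0]
    if v[0] == 0:
        return np.inf
    return float(v[1] / v[0])


def concordance(
    de_alpha: pd.DataFrame,
    de_beta: pd.DataFrame,
    time_hr: float = np.nan,
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
) -> ConcordanceSummary:
    """Fold-fold concordance of the two receptors' contrast results.

    Counts gate-passing probes per receptor and their overlap; Pearson r and
    the TLS slope are computed over the union of passers.
    """
    if set(de_alpha.index) != set(de_beta.index):
        raise ValueError("result tables must cover the same probes")
    de_beta = de_beta.loc[de_alpha.index]
    pass_a = set(diffexpr.gate_significant(de_alpha, fold_cutoff, alpha).index)
    pass_b = set(diffexpr.gate_significant(de_beta, fold_cutoff, alpha).index)
    union = sorted(pass_a | pass_b)
    if not union:
        return ConcordanceSummary(time_hr, 0, 0, 0, 0, np.nan, np.nan, defined=False)
    x = de_alpha.loc[union, "log2fc"].to_numpy()
    y = de_beta.loc[union, "log2fc"].to_numpy()
    if len(union) < 2 or np.std(x) == 0 or np.std(y) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return ConcordanceSummary(
        time_hr=time_hr,
        n_alpha=len(pass_a),
        n_beta=len(pass_b),
        n_overlap=len(pass_a & pass_b),
        n_union=len(union),
        pearson_r=r,
        slope=tls_slope(x, y) if len(union) >= 2 else np.nan,
        defined=True,
    )


def kinetic_classify(
    de_by_time: dict[float, dict[str, pd.DataFrame]],
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
    beta_factor: float = BETA_PREFERENTIAL_FACTOR,
) -> pd.DataFrame:
    """Classify each gate-passing probe by its response kinetics.

    ``de_by_time`` maps time -> {"TRA": results, "TRB": results}. Rules, in
    order of precedence:

    - ``alpha_early``: passes with TRα at a pre-final time strictly before
      any TRβ pass.
    - ``beta_late``: passes with TRβ at the final time with
      |log2fc_β| >= beta_factor * |log2fc_α| there (TRβ-preferential).
    - ``concordant``: first passes at the same time with final-time fold
      ratio < beta_factor both ways.
    - ``discordant_other``: everything else that passes at least once.
    """
    times = sorted(de_by_time)
    if len(times) < 2:
        raise ValueError("kinetic classification needs >= 2 time points")
    last = times[-1]
    pass_times: dict[str, dict[str, list[float]]] = {"TRA": {}, "TRB": {}}
    for t in times:
        for r in ("TRA", "TRB"):
            gated = diffexpr.gate_significant(de_by_time[t][r], fold_cutoff, alpha)
            for probe in gated.index:
                pass_times[r].setdefault(probe, []).append(t)
    fc_last = {r: de_by_time[last][r]["log2fc"] for r in ("TRA", "TRB")}
    probes = sorted(set(pass_times["TRA"]) | set(pass_times["TRB"]))
    rows = []
    for probe in probes:
        ta = min(pass_times["TRA"][probe]) if probe in pass_times["TRA"] else None
        tb = min(pass_times["TRB"][probe]) if probe in pass_times["TRB"] else None
        fa = abs(float(fc_last["TRA"].get(probe, 0.0)))
        fb = abs(float(fc_last["TRB"].get(probe, 0.0)))
        beta_passes_last = probe in pass_times["TRB"] and last in pass_times["TRB"][probe]
        if ta is not None and ta < last and (tb is None or ta < tb):
            cls = "alpha_early"
        elif beta_passes_last and fb >= beta_factor * fa:
            cls = "beta_late"
        elif ta is not None and tb is not None and ta == tb and (
            fb < beta_factor * max(fa, 1e-300) and fa < beta_factor * max(fb, 1e-300)
        ):
            cls = "concordant"
        else:
            cls = "discordant_other"
        rows.append(
            {
                "probe_id": probe, "kinetic_class": cls,
                "earliest_pass_alpha": ta, "earliest_pass_beta": tb,
                "abs_log2fc_alpha_last": fa, "abs_log2fc_beta_last": fb,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["probe_id", "kinetic_class", "earliest_pass_alpha",
                 "earliest_pass_beta", "abs_log2fc_alpha_last", "abs_log2fc_beta_last"],
    ).set_index("probe_id") if rows else pd.DataFrame(
        columns=["kinetic_class", "earliest_pass_alpha", "earliest_pass_beta",
                 "abs_log2fc_alpha_last", "abs_log2fc_beta_last"]
    )


def overlap_table(flagged: dict[str, pd.DataFrame]) -> dict:
    """Direction-stratified intersection counts across flagged gene sets.

    ``flagged`` maps a set name (e.g. ``"HepG2_TRA"``) to a gated result
    table with a ``direction`` column. Induced and repressed genes are
    counted separately; a probe induced in one set and repressed in another
    never counts toward an overlap and is reported under ``discordant``.

    Returns ``{"counts": {direction: {names_tuple: count}}, "sizes": ...,
    "discordant": sorted probe list}``.
    """
    names = sorted(flagged)
    direction_sets: dict[str, dict[str, set[str]]] = {"induced": {}, "repressed": {}}
    directions_seen: dict[str, set[str]] = {}
    for name in names:
        table = flagged[name]
        for direction in ("induced", "repressed"):
            members = set(table.index[table["direction"] == direction])
            direction_sets[direction][name] = members
            for probe in members:
                directions_seen.setdefault(probe, set()).add(direction)
    discordant = sorted(p for p, ds in directions_seen.items() if len(ds) > 1)
    counts: dict[str, dict[tuple[str, ...], int]] = {}
    sizes: dict[str, dict[str, int]] = {}
    for direction in ("induced", "repressed"):
        sets = {
            n: direction_sets[direction][n] - set(discordant) for n in names
        }
        sizes[direction] = {n: len(s) for n, s in sets.items()}
        counts[direction] = {}
        for k in range(2, len(names) + 1):
            for combo in combinations(names, k):
                inter = set.intersection(*(sets[n] for n in combo))
                counts[direction][combo] = len(inter)
    return {"counts": counts, "sizes": sizes, "discordant": discordant}


def pattern_overlap(
    assign_alpha: pd.DataFrame, assign_beta: pd.DataFrame
) -> pd.DataFrame:
    """Per-pattern counts for each receptor and their overlap.

    For each of the eight reported patterns, counts probes assigned that
    label with TRα, with TRβ, and with both (same probe, same label).
    """
    by_label_a = {
        label: set(assign_alpha.loc[assign_alpha["label"] == label, "probe_id"])
        for label in REPORTED_ARCHETYPES
    }
    by_label_b = {
        label: set(assign_beta.loc[assign_beta["label"] == label, "probe_id"])
        for label in REPORTED_ARCHETYPES
    }
    rows = []
    for label in REPORTED_ARCHETYPES:
        rows.append(
            {
                "pattern": label,
                "n_alpha": len(by_label_a[label]),
                "n_beta": len(by_label_b[label]),
                "n_overlap": len(by_label_a[label] & by_label_b[label]),
            }
        )
    return pd.DataFrame(rows).set_index("pattern")
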