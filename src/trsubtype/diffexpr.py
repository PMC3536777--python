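"""Per-gene linear modelling with empirical-Bayes variance moderation.

Each cell line is analysed on a cell-means parameterisation: samples are
grouped into design cells (by default ``receptor x ligand``), per-gene cell
means and a pooled within-cell residual variance are computed, the per-gene
variances are shrunk toward a common prior by fitting the scaled
inverse-chi-square hierarchy by moment matching on ``log s^2``, and named
contrasts over the cell means yield moderated t statistics.

Both of the study's analysis styles are expressed as contrasts over this one
parameterisation: the *unliganded effect* ``(receptor, vehicle) - (parental,
vehicle)`` and the factorial *ligand interaction* ``[(receptor, T3) -
(receptor, vehicle)] - [(parental, T3) - (parental, vehicle)]``; a plain
within-receptor T3 effect is also provided. Significance gating is the
inclusive ``>= fold_cutoff`` and BH-adjusted ``p <= alpha`` rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrixio import ExpressionMatrix, SampleDesign

DEFAULT_GROUPING: tuple[str, ...] = ("receptor", "ligand")


class DesignError(ValueError):
    """A contrast or grouping is inconsistent with the available samples."""


def cell_key_of(design: SampleDesign, grouping: tuple[str, ...] = DEFAULT_GROUPING) -> str:
    return "|".join(str(getattr(design, f)) for f in grouping)


def cell(receptor: str, ligand: str, chx: bool | None = None) -> str:
    """Build a cell key for the default groupings used in this package."""
    key = f"{receptor}|{ligand}"
    if chx is not None:
        key += f"|{chx}"
    return key


@dataclass
class ContrastSpec:
    """Named linear contrast over design cells (weights sum to 0)."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total) > 1e-9:
            raise DesignError(f"contrast {self.name!r} weights sum to {total}, expected 0")


def unliganded_contrast(receptor: str, chx: bool | None = None) -> ContrastSpec:
    """Receptor over-expression effect without hormone, versus parental."""
    return ContrastSpec(
        f"unliganded_{receptor}",
        {cell(receptor, "vehicle", chx): 1.0, cell("parental", "vehicle", chx): -1.0},
    )


def interaction_contrast(receptor: str, chx: bool | None = None) -> ContrastSpec:
    """Ligand x over-expression interaction (difference of T3 differences)."""
    return ContrastSpec(
        f"interaction_{receptor}",
        {
            cell(receptor, "T3", chx): 1.0,
            cell(receptor, "vehicle", chx): -1.0,
            cell("parental", "T3", chx): -1.0,
            cell("parental", "vehicle", chx): 1.0,
        },
    )


def liganded_contrast(receptor: str, chx: bool | None = None) -> ContrastSpec:
    """Liganded expression level versus the parental baseline.

    This is the pattern classifier's ligand axis: where the gene sits with
    receptor + T3 relative to untreated parental cells (unliganded effect
    plus T3 response combined).
    """
    return ContrastSpec(
        f"liganded_{receptor}",
        {cell(receptor, "T3", chx): 1.0, cell("parental", "vehicle", chx): -1.0},
    )


def t3_contrast(receptor: str, chx: bool | None = None) -> ContrastSpec:
    """Plain T3 effect within one receptor line."""
    return ContrastSpec(
        f"t3_{receptor}" + ("_chx" if chx else ""),
        {cell(receptor, "T3", chx): 1.0, cell(receptor, "vehicle", chx): -1.0},
    )


def chx_alone_contrast(receptor: str) -> ContrastSpec:
    """CHX-alone effect within one receptor line (vehicle samples)."""
    return ContrastSpec(
        f"chx_{receptor}",
        {cell(receptor, "vehicle", True): 1.0, cell(receptor, "vehicle", False): -1.0},
    )


@dataclass
class CellMeansFit:
    """Per-gene cell means with pooled residual variance."""

    means: pd.DataFrame            # genes x cells
    s2: np.ndarray                 # pooled within-cell variance per gene
    df: int                        # residual degrees of freedom
    n_per_cell: dict[str, int]
    avg_expr: np.ndarray           # grand mean log2 intensity per gene
    grouping: tuple[str, ...] = DEFAULT_GROUPING


def fit_cell_means(
    matrix: ExpressionMatrix,
    designs: list[SampleDesign],
    grouping: tuple[str, ...] = DEFAULT_GROUPING,
) -> CellMeansFit:
    """Arithmetic cell means and pooled within-cell residual variance.

    ``s2`` is the one-way ANOVA residual mean square with
    ``df = n_samples - n_cells``; an error is raised when every cell is a
    singleton (no residual degrees of freedom).
    """
    matrix.check_design(designs)
    cells: dict[str, list[str]] = {}
    for d in designs:
        cells.setdefault(cell_key_of(d, grouping), []).append(d.sample_id)
    n_samples = len(designs)
    df = n_samples - len(cells)
    if df <= 0:
        raise DesignError("no residual degrees of freedom: every design cell is a singleton")
    X = matrix.data
    means = {}
    rss = np.zeros(len(X.index))
    for key, sample_ids in cells.items():
        block = X[sample_ids].to_numpy()
        m = block.mean(axis=1)
        means[key] = m
        rss += ((block - m[:, None]) ** 2).sum(axis=1)
    return CellMeansFit(
        means=pd.DataFrame(means, index=X.index),
        s2=rss / df,
        df=df,
        n_per_cell={k: len(v) for k, v in cells.items()},
        avg_expr=X.to_numpy().mean(axis=1),
        grouping=tuple(grouping),
    )


def trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for all x > 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


@dataclass
class ModeratedVariances:
    """Empirical-Bayes shrunken variances and the fitted prior."""

    s2_tilde: np.ndarray
    d0: float                      # prior degrees of freedom (inf = total shrinkage)
    s0_2: float                    # prior variance
    df: int = 0
    moderated: bool = True

    @property
    def df_total(self) -> float:
        return self.df + self.d0


def moderate_variances(
    s2: np.ndarray, df: int, prior_df: float | None = None
) -> ModeratedVariances:
    """Shrink per-gene variances toward a moment-matched common prior.

    The hierarchy is the scaled inverse-chi-square model: given the true
    residual variance, ``df * s2 / sigma^2 ~ chi2(df)`` and ``1/sigma^2 ~
    chi2(d0) / (d0 * s0^2)``. ``(d0, s0^2)`` are estimated from the mean and
    variance of ``log s2`` using the digamma/trigamma identities of the
    log-F marginal, and each gene's posterior variance is

        s2_tilde = (d0 * s0^2 + df * s2) / (d0 + df).

    ``prior_df`` overrides estimation (0 disables moderation entirely).
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is not None:
        if prior_df == 0:
            return ModeratedVariances(s2.copy(), 0.0, float(np.mean(s2)), df, moderated=False)
        d0 = float(prior_df)
        s0_2 = float(np.exp(np.mean(np.log(s2[s2 > 0]))))
        return ModeratedVariances((d0 * s0_2 + df * s2) / (d0 + df), d0, s0_2, df)
    positive = s2 > 0
    if positive.sum() < 10:
        warnings.warn(
            "fewer than 10 genes with positive residual variance; skipping moderation",
            stacklevel=2,
        )
        return ModeratedVariances(s2.copy(), 0.0, float(np.mean(s2)), df, moderated=False)
    z = np.log(s2[positive])
    # centre z so that e estimates log sigma_g^2 for each gene
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = float(2.0 * trigamma_inverse(np.array(e_var)))
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        # observed spread no larger than chi-square sampling noise: infinite
        # prior df; under that model E[s2] = s0^2, so match the raw mean
        d0 = np.inf
        s0_2 = float(np.mean(s2))
        s2_tilde = np.full_like(s2, s0_2)
    return ModeratedVariances(s2_tilde, d0, s0_2, df)


def test_contrast(
    fit: CellMeansFit,
    moderation: ModeratedVariances,
    contrast: ContrastSpec,
) -> pd.DataFrame:
    """Moderated t test of one contrast; returns the per-probe result table.

    Columns: ``log2fc, avg_expr, t_mod, p_raw, p_adj, df_total``. The
    standard error combines the moderated variance with the contrast's
    effective sample size ``sum(w_c^2 / n_c)``.
    """
    missing = [c for c in contrast.weights if c not in fit.means.columns]
    if missing:
        raise DesignError(
            f"contrast {contrast.name!r} references empty/unknown cell(s): {missing}"
        )
    log2fc = np.zeros(len(fit.means.index))
    scale = 0.0
    for key, w in contrast.weights.items():
        log2fc = log2fc + w * fit.means[key].to_numpy()
        scale += w * w / fit.n_per_cell[key]
    df_total = moderation.df_total if np.isfinite(moderation.df_total) else np.inf
    se = np.sqrt(moderation.s2_tilde * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), np.sign(log2fc) * np.inf)
    t_mod = np.where((se == 0) & (log2fc == 0), 0.0, t_mod)
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "avg_expr": fit.avg_expr,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": adjust_bh(p_raw),
            "df_total": df_total,
        },
        index=fit.means.index,
    )
    result.index.name = "probe_id"
    return result


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gate_significant(
    results: pd.DataFrame, fold_cutoff: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Inclusive significance gate: |fold change| >= cutoff and p_adj <= alpha.

    Returns the passing subset with a ``direction`` column
    (``induced``/``repressed`` from the sign of log2fc).
    """
    if results.empty:
        raise ValueError("results table is empty")
    mask = (np.abs(results["log2fc"]) >= np.log2(fold_cutoff)) & (results["p_adj"] <= alpha)
    passed = results.loc[mask].copy()
    passed["direction"] = np.where(passed["log2fc"] > 0, "induced", "repressed")
    return passed


def run_de(
    matrix: ExpressionMatrix,
    designs: list[SampleDesign],
    contrast: ContrastSpec,
    grouping: tuple[str, ...] = DEFAULT_GROUPING,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: cell means -> moderation -> contrast test."""
    fit = fit_cell_means(matrix, designs, grouping)
    moderation = moderate_variances(fit.s2, fit.df, prior_df=prior_df)
    return test_contrast(fit, moderation, contrast)
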