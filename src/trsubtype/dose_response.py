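"""Hill dose-response fitting and per-gene EC50 comparison across receptors.

The four-parameter Hill model on log2 expression is

    response(d) = bottom + (top - bottom) * d^h / (d^h + EC50^h)

with dose 0 sitting exactly on the lower asymptote (no log-dose transform of
the model; the optimiser works on log10 EC50). Fits are multi-started over a
log-spaced EC50 grid spanning the dose range to avoid local minima, and
confidence intervals come from bootstrapping replicates within each dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class DoseResponseError(ValueError):
    pass


@dataclass
class DoseResponseFit:
    probe_id: str
    receptor: str
    ec50: float
    hill: float
    bottom: float
    top: float
    rss: float
    converged: bool
    non_responsive: bool
    wrong_direction: bool
    extrapolated: bool
    ec50_ci: tuple[float, float] | None
    boot_ec50: np.ndarray | None

    @property
    def repressed(self) -> bool:
        return self.top < self.bottom


def hill_curve(d: np.ndarray, bottom: float, top: float, ec50: float, h: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d ** h / (d ** h + ec50 ** h), 0.0)
    return bottom + (top - bottom) * frac


def _fit_once(doses, responses, start, bounds, fix_hill):
    def residuals(params):
        if fix_hill is None:
            bottom, top, log_ec50, h = params
        else:
            bottom, top, log_ec50 = params
            h = fix_hill
        return hill_curve(doses, bottom, top, 10.0 ** log_ec50, h) - responses

    return optimize.least_squares(
        residuals, start, bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=2000,
    )


def _best_fit(doses, responses, fix_hill):
    positive = doses[doses > 0]
    lo, hi = positive.min(), positive.max()
    starts_ec50 = np.geomspace(lo, hi, 6)
    b0 = responses[doses == 0].mean() if np.any(doses == 0) else responses.min()
    t0 = responses[doses == doses.max()].mean()
    log_bounds = (np.log10(lo) - 2.0, np.log10(hi) + 2.0)
    best = None
    for e0 in starts_ec50:
        if fix_hill is None:
            start = [b0, t0, np.log10(e0), 1.0]
            bounds = ([-np.inf, -np.inf, log_bounds[0], 0.05],
                      [np.inf, np.inf, log_bounds[1], 10.0])
        else:
            start = [b0, t0, np.log10(e0)]
            bounds = ([-np.inf, -np.inf, log_bounds[0]],
                      [np.inf, np.inf, log_bounds[1]])
        try:
            res = _fit_once(doses, responses, start, bounds, fix_hill)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise DoseResponseError("all optimisation starts failed")
    return best


def fit_hill(
    doses,
    responses,
    direction: str | None = None,
    fix_hill: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
    probe_id: str = "",
    receptor: str = "",
) -> DoseResponseFit:
    """Least-squares Hill fit of one gene's dose series.

    Parameters
    ----------
    doses, responses : parallel arrays; repeated doses are replicates.
        Requires >= 4 distinct doses including 0.
    direction : expected response direction (``induced``/``repressed``) or
        None; a confidently wrong-signed amplitude sets ``wrong_direction``.
    fix_hill : constrain the Hill slope (e.g. 1.0); free by default.
    n_boot : bootstrap resamples of replicates-within-dose for the EC50
        interval; 0 skips the bootstrap.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise DoseResponseError("doses and responses must have the same length")
    if not np.all(np.isfinite(responses)) or not np.all(np.isfinite(doses)):
        raise DoseResponseError("doses and responses must be finite")
    distinct = np.unique(doses)
    if len(distinct) < 4:
        raise DoseResponseError("need at least 4 distinct doses")
    if 0.0 not in distinct:
        raise DoseResponseError("dose series must include dose 0")

    best = _fit_once_wrapper(doses, responses, fix_hill)
    bottom, top, log_ec50, h = best
    ec50 = float(10.0 ** log_ec50)
    fitted = hill_curve(doses, bottom, top, ec50, h)
    rss = float(np.sum((fitted - responses) ** 2))

    # amplitude significance versus the flat model (F-test)
    n = len(responses)
    p_full = 3 if fix_hill is not None else 4
    rss_flat = float(np.sum((responses - responses.mean()) ** 2))
    non_responsive = False
    if rss_flat <= 1e-300:
        non_responsive = True
        p_flat_test = 1.0
    elif n > p_full and rss > 0:
        f = ((rss_flat - rss) / (p_full - 1)) / (rss / (n - p_full))
        p_flat_test = float(stats.f.sf(max(f, 0.0), p_full - 1, n - p_full))
        non_responsive = p_flat_test > 0.05
    else:
        p_flat_test = 0.0

    wrong_direction = False
    if direction is not None and not non_responsive:
        sign = 1.0 if direction == "induced" else -1.0
        wrong_direction = sign * (top - bottom) < 0
    positive = distinct[distinct > 0]
    extrapolated = not (positive.min() <= ec50 <= positive.max())

    boot_ec50 = None
    ec50_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = {d: np.nonzero(doses == d)[0] for d in distinct}
        positive_all = distinct[distinct > 0]
        log_bounds = (np.log10(positive_all.min()) - 2.0, np.log10(positive_all.max()) + 2.0)
        if fix_hill is None:
            start = [bottom, top, np.clip(log_ec50, *log_bounds), h]
            bounds = ([-np.inf, -np.inf, log_bounds[0], 0.05],
                      [np.inf, np.inf, log_bounds[1], 10.0])
        else:
            start = [bottom, top, np.clip(log_ec50, *log_bounds)]
            bounds = ([-np.inf, -np.inf, log_bounds[0]],
                      [np.inf, np.inf, log_bounds[1]])
        draws = []
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups.values()]
            )
            try:
                # restart from the point estimate: resampled surfaces are close
                res = _fit_once(doses[idx], responses[idx], start, bounds, fix_hill)
                draws.append(float(10.0 ** res.x[2]))
            except Exception:
                draws.append(np.nan)
        boot_ec50 = np.asarray(draws)
        valid = boot_ec50[np.isfinite(boot_ec50)]
        if len(valid) >= 10:
            ec50_ci = (float(np.percentile(valid, 2.5)), float(np.percentile(valid, 97.5)))

    return DoseResponseFit(
        probe_id=probe_id, receptor=receptor, ec50=ec50, hill=float(h),
        bottom=float(bottom), top=float(top), rss=rss, converged=True,
        non_responsive=non_responsive, wrong_direction=wrong_direction,
        extrapolated=extrapolated, ec50_ci=ec50_ci, boot_ec50=boot_ec50,
    )


def _fit_once_wrapper(doses, responses, fix_hill):
    """Multi-start fit returning (bottom, top, log10_ec50, h)."""
    best = _best_fit(doses, responses, fix_hill)
    if fix_hill is None:
        bottom, top, log_ec50, h = best.x
    else:
        bottom, top, log_ec50 = best.x
        h = fix_hill
    return float(bottom), float(top), float(log_ec50), float(h)


@dataclass
class Ec50Comparison:
    ratio: float                  # ec50_beta / ec50_alpha
    ci: tuple[float, float] | None
    shifted: bool | None          # interval excludes 1


def compare_ec50(fit_alpha: DoseResponseFit, fit_beta: DoseResponseFit) -> Ec50Comparison:
    """EC50 ratio (β/α) with a bootstrap interval; flags subtype shifts.

    Requires both fits converged; the interval pairs the two fits' bootstrap
    draws index-wise and the gene is flagged ``shifted`` when the interval
    excludes 1.
    """
    if not (fit_alpha.converged and fit_beta.converged):
        raise DoseResponseError("both fits must have converged to compare EC50s")
    ratio = fit_beta.ec50 / fit_alpha.ec50
    if fit_alpha.boot_ec50 is None or fit_beta.boot_ec50 is None:
        return Ec50Comparison(ratio=float(ratio), ci=None, shifted=None)
    a = fit_alpha.boot_ec50
    b = fit_beta.boot_ec50
    m = min(len(a), len(b))
    draws = b[:m] / a[:m]
    draws = draws[np.isfinite(draws)]
    if len(draws) < 10:
        return Ec50Comparison(ratio=float(ratio), ci=None, shifted=None)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return Ec50Comparison(
        ratio=float(ratio), ci=(float(lo), float(hi)), shifted=bool(lo > 1.0 or hi < 1.0)
    )
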