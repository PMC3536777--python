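"""End-to-end orchestration: simulate -> normalize -> DE -> patterns -> CHX
-> subtype comparison -> EC50, with a reproducible manifest.

``run_pipeline`` executes the stages in dependency order against a
:class:`RunConfig`, writing every intermediate and summary table as
tab-delimited text under the output directory, plus a ``manifest.json``
recording the tool version, config hash, seed and per-stage record counts.
Re-running with the same config reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, diffexpr, dose_response, matrixio, patterns, simulate, targets

__version__ = "0.1.0"

logger = logging.getLogger("trsubtype")


@dataclass
class RunConfig:
    """Pipeline-level configuration (gates, modes, output location)."""

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    fold_cutoff: float = 2.0
    alpha: float = 0.05
    eligibility: str = "either"          # pattern-classifier eligibility mode
    chx_baseline: str = "chx"            # persistence denominator baseline
    gate_contrast: str = "interaction"   # or "t3": which ligand contrast is gated
    quantile_normalize: bool = True
    n_ec50_genes: int = 8                # top induced genes taken into the dose fits
    ec50_boot: int = 100
    outdir: str = "trsubtype_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        known_sim = {f.name for f in dataclasses.fields(simulate.SimulationConfig)}
        bad = set(sim_raw) - known_sim
        if bad:
            raise simulate.ConfigError(f"unknown simulation key(s): {sorted(bad)}")
        if "archetype_proportions" in sim_raw:
            sim_raw["archetype_proportions"] = dict(sim_raw["archetype_proportions"])
        if "kinetic_weights" in sim_raw:
            sim_raw["kinetic_weights"] = {
                r: {float(t): float(w) for t, w in d.items()}
                for r, d in sim_raw["kinetic_weights"].items()
            }
        for tuple_key in ("times", "dose_grid", "ec50_log10_range", "hill_range"):
            if tuple_key in sim_raw:
                sim_raw[tuple_key] = tuple(sim_raw[tuple_key])
        sim = simulate.SimulationConfig(**sim_raw)
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        bad = set(raw) - known
        if bad:
            raise simulate.ConfigError(f"unknown run key(s): {sorted(bad)}")
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        sim["kinetic_weights"] = {
            r: {f"{t:g}": w for t, w in wd.items()} for r, wd in sim["kinetic_weights"].items()
        }
        return d

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, entity: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {entity!r}: {cause}")
        self.stage = stage
        self.entity = entity


def _write(frame, path: Path) -> None:
    frame.to_csv(path, sep="\t", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.simulation.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "trsubtype",
        "version": __version__,
        "seed": config.simulation.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name: str):
        def runner(fn, entity: str = "-"):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise StageError(name, entity, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return runner

    sim = config.simulation

    # --- simulate ------------------------------------------------------------
    run = stage("simulate")
    specs = run(lambda: simulate.draw_gene_effects(sim), "gene effects")
    tc_matrix, tc_designs = run(lambda: simulate.simulate_timecourse(specs, sim), "timecourse")
    chx_matrix, chx_designs = run(lambda: simulate.simulate_chx_arm(specs, sim), "chx arm")
    ds_matrix, ds_designs = run(lambda: simulate.simulate_dose_series(specs, sim), "dose series")
    simulate.write_gene_specs(specs, outdir / "ground_truth.tsv")
    matrixio.write_matrix(tc_matrix, outdir / "timecourse_matrix.tsv")
    matrixio.write_design(tc_designs, outdir / "timecourse_design.tsv")
    matrixio.write_matrix(chx_matrix, outdir / "chx_matrix.tsv")
    matrixio.write_design(chx_designs, outdir / "chx_design.tsv")
    matrixio.write_matrix(ds_matrix, outdir / "dose_matrix.tsv")
    matrixio.write_design(ds_designs, outdir / "dose_design.tsv")
    manifest["stages"]["simulate"] = {
        "n_genes": len(specs),
        "timecourse_samples": len(tc_designs),
        "chx_samples": len(chx_designs),
        "dose_samples": len(ds_designs),
    }

    # --- normalize -----------------------------------------------------------
    if config.quantile_normalize:
        run = stage("normalize")
        tc_matrix = run(lambda: matrixio.quantile_normalize(tc_matrix), "timecourse")
        chx_matrix = run(lambda: matrixio.quantile_normalize(chx_matrix), "chx arm")
        matrixio.write_matrix(tc_matrix, outdir / "timecourse_matrix_qnorm.tsv")
    manifest["stages"]["normalize"] = {"applied": config.quantile_normalize}

    # --- differential expression ---------------------------------------------
    run = stage("de")
    de_tables: dict[float, dict[str, dict[str, object]]] = {}
    for t in sim.times:
        designs_t = [d for d in tc_designs if d.time_hr == t]
        sub = tc_matrix.subset_samples([d.sample_id for d in designs_t])
        fit = run(lambda s=sub, dz=designs_t: diffexpr.fit_cell_means(s, dz), f"time {t:g}h")
        moderation = diffexpr.moderate_variances(fit.s2, fit.df)
        de_tables[t] = {}
        for receptor in ("TRA", "TRB"):
            tables = {
                "unliganded": diffexpr.test_contrast(
                    fit, moderation, diffexpr.unliganded_contrast(receptor)
                ),
                "interaction": diffexpr.test_contrast(
                    fit, moderation, diffexpr.interaction_contrast(receptor)
                ),
                "t3": diffexpr.test_contrast(fit, moderation, diffexpr.t3_contrast(receptor)),
                "liganded": diffexpr.test_contrast(
                    fit, moderation, diffexpr.liganded_contrast(receptor)
                ),
            }
            de_tables[t][receptor] = tables
            for name, table in tables.items():
                gated = diffexpr.gate_significant(table, config.fold_cutoff, config.alpha)
                out = table.copy()
                out["pass_flag"] = out.index.isin(gated.index)
                _write(out, outdir / f"de_{name}_{receptor}_{t:g}h.tsv")
    manifest["stages"]["de"] = {
        "times": [f"{t:g}" for t in sim.times],
        "contrasts": ["unliganded", "interaction", "t3"],
    }

    # --- pattern classification ----------------------------------------------
    run = stage("patterns")
    t0 = min(sim.times)
    assignments = {}
    for receptor in ("TRA", "TRB"):
        assign, counts = run(
            lambda r=receptor: patterns.classify_probe_set(
                de_tables[t0][r]["unliganded"], de_tables[t0][r]["liganded"],
                alpha=config.alpha, eligibility=config.eligibility,
            ),
            receptor,
        )
        assignments[receptor] = assign
        assign.to_csv(outdir / f"patterns_{receptor}.tsv", sep="\t", index=False,
                      lineterminator="\n")
    table1 = compare.pattern_overlap(assignments["TRA"], assignments["TRB"])
    _write(table1, outdir / "pattern_table.tsv")
    manifest["stages"]["patterns"] = {
        "n_assigned_TRA": len(assignments["TRA"]),
        "n_assigned_TRB": len(assignments["TRB"]),
    }

    # --- CHX direct-target calls ---------------------------------------------
    run = stage("chx")
    grouping = ("receptor", "ligand", "chx")
    chx_fit = run(lambda: diffexpr.fit_cell_means(chx_matrix, chx_designs, grouping), "fit")
    chx_mod = diffexpr.moderate_variances(chx_fit.s2, chx_fit.df)
    chx_summary = {}
    for receptor in ("TRA", "TRB"):
        res = diffexpr.test_contrast(
            chx_fit, chx_mod, diffexpr.t3_contrast(receptor, chx=False)
        )
        gated = diffexpr.gate_significant(res, config.fold_cutoff, config.alpha)
        calls = run(
            lambda r=receptor, g=gated: targets.call_direct_targets(
                chx_matrix, chx_designs, r, probes=list(g.index),
                baseline_mode=config.chx_baseline,
            ),
            receptor,
        )
        merged = calls.join(gated[["log2fc", "direction"]])
        _write(merged, outdir / f"chx_calls_{receptor}.tsv")
        persist = merged[merged["call"] == "direct"]
        chx_summary[receptor] = {
            "induced_gated": int((merged["direction"] == "induced").sum()),
            "repressed_gated": int((merged["direction"] == "repressed").sum()),
            "induced_direct": int(((merged["direction"] == "induced")
                                   & (merged["call"] == "direct")).sum()),
            "repressed_direct": int(((merged["direction"] == "repressed")
                                     & (merged["call"] == "direct")).sum()),
        }
        _ = persist
    flags = targets.chx_derepression_flags(
        chx_matrix, chx_designs, fold_cutoff=config.fold_cutoff, alpha=config.alpha
    )
    _write(flags, outdir / "chx_derepression_flags.tsv")
    with open(outdir / "chx_summary.json", "w") as fh:
        json.dump(chx_summary, fh, indent=2)
    manifest["stages"]["chx"] = chx_summary

    # --- subtype comparison --------------------------------------------------
    run = stage("compare")
    gate_name = config.gate_contrast
    summaries = []
    for t in sim.times:
        s = run(
            lambda tt=t: compare.concordance(
                de_tables[tt]["TRA"][gate_name], de_tables[tt]["TRB"][gate_name],
                time_hr=tt, fold_cutoff=config.fold_cutoff, alpha=config.alpha,
            ),
            f"time {t:g}h",
        )
        summaries.append(dataclasses.asdict(s))
    de_by_time = {t: {r: de_tables[t][r][gate_name] for r in ("TRA", "TRB")} for t in sim.times}
    kinetics = compare.kinetic_classify(
        de_by_time, fold_cutoff=config.fold_cutoff, alpha=config.alpha
    )
    _write(kinetics, outdir / "kinetic_classes.tsv")
    _write(pd.DataFrame(summaries).set_index("time_hr"), outdir / "concordance.tsv")
    t_last = max(sim.times)
    flagged = {
        f"{sim.cell_line}_{r}": diffexpr.gate_significant(
            de_tables[t_last][r][gate_name], config.fold_cutoff, config.alpha
        )
        for r in ("TRA", "TRB")
    }
    overlaps = compare.overlap_table(flagged)
    overlap_rows = []
    for direction, combos in overlaps["counts"].items():
        for combo, n in combos.items():
            overlap_rows.append({"direction": direction, "sets": "&".join(combo), "n": n})
    for direction, sizes in overlaps["sizes"].items():
        for name, n in sizes.items():
            overlap_rows.append({"direction": direction, "sets": name, "n": n})
    pd.DataFrame(overlap_rows).to_csv(
        outdir / "overlap_counts.tsv", sep="\t", index=False, lineterminator="\n"
    )
    manifest["stages"]["compare"] = {
        "concordance": summaries,
        "n_kinetic_classified": len(kinetics),
        "n_discordant_direction": len(overlaps["discordant"]),
    }

    # --- dose response -------------------------------------------------------
    run = stage("ec50")
    t3_last = de_tables[t_last]["TRA"]["t3"]
    gated_induced = diffexpr.gate_significant(t3_last, config.fold_cutoff, config.alpha)
    gated_induced = gated_induced[gated_induced["direction"] == "induced"]
    top = gated_induced["log2fc"].sort_values(ascending=False).head(config.n_ec50_genes)
    ec50_rows = []
    ds_doses = {
        r: np.array([d.dose_nM for d in ds_designs if d.receptor == r])
        for r in ("TRA", "TRB")
    }
    ds_cols = {
        r: [d.sample_id for d in ds_designs if d.receptor == r] for r in ("TRA", "TRB")
    }
    for rank, probe in enumerate(top.index):
        fits = {}
        for receptor in ("TRA", "TRB"):
            responses = ds_matrix.data.loc[probe, ds_cols[receptor]].to_numpy()
            fits[receptor] = run(
                lambda rr=receptor, resp=responses: dose_response.fit_hill(
                    ds_doses[rr], resp, direction="induced", n_boot=config.ec50_boot,
                    seed=(sim.seed * 31 + rank) % (2**31 - 1),
                    probe_id=probe, receptor=rr,
                ),
                probe,
            )
        cmp_result = dose_response.compare_ec50(fits["TRA"], fits["TRB"])
        ec50_rows.append(
            {
                "probe_id": probe,
                "EC50_TRA_nM": fits["TRA"].ec50,
                "EC50_TRB_nM": fits["TRB"].ec50,
                "ratio_beta_over_alpha": cmp_result.ratio,
                "ratio_ci_low": cmp_result.ci[0] if cmp_result.ci else np.nan,
                "ratio_ci_high": cmp_result.ci[1] if cmp_result.ci else np.nan,
                "subtype_shifted": cmp_result.shifted,
                "hill_TRA": fits["TRA"].hill,
                "hill_TRB": fits["TRB"].hill,
            }
        )
    pd.DataFrame(ec50_rows).to_csv(
        outdir / "ec50_table.tsv", sep="\t", index=False, lineterminator="\n"
    )
    manifest["stages"]["ec50"] = {"n_genes_fit": len(ec50_rows)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
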