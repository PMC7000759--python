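"""End-to-end pipeline: simulate -> reduce -> stats / profiles -> backcalc.

Each stage reads the artifacts of the previous one from disk, so stages can
be re-run independently; every threshold, seed and exclusion decision is
logged. The stats stage mirrors the maternal-tag hypothesis structure:

* H1 - embryo focus and edge spot signatures, grouped by litter,
* H2 - embryo transect profiles, grouped by litter,
* H3 - vertebral-edge signatures of mothers together with their embryos,

each tested with PERMANOVA, CAP (with LOO cross-validation) and the
proportional chance criterion.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .backcalc import BackCalcParams, fraser_lee
from .config import MassConfig, PipelineConfig, default_mass_config
from .mvstats import cap_fit, euclidean_dm, permanova
from .profiles import classify_pattern, ratio_profiles
from .reduction import reduce_run, resample_transects
from .runio import (read_profiles, read_run, write_calls, write_csv,
                    write_profiles, write_run, write_signatures)
from .synthetic import StudyDesign, make_study

__all__ = ["STAGES", "run_pipeline"]

STAGES = ("simulate", "reduce", "stats", "profiles", "backcalc")

log = logging.getLogger("vertchem")


def _meta(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed}


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name} from stage '{stage}'; run it first")
    return path


def _stage_simulate(cfg: PipelineConfig, mass_config: MassConfig,
                    design: StudyDesign) -> dict:
    run, specimens, truth = make_study(design, mass_config)
    data_dir = Path(cfg.data_dir)
    write_run(run, data_dir, _meta(cfg))
    write_csv(specimens, data_dir / "specimens.csv", _meta(cfg))
    truth_df = specimens.copy()
    write_csv(truth_df, data_dir / "truth.csv",
              {**_meta(cfg), "drift_slopes": truth.drift_slopes})
    log.info("simulate: %d records, %d specimens", len(run), len(specimens))
    return {"manifest": data_dir / "manifest.csv", "specimens": data_dir / "specimens.csv"}


def _stage_reduce(cfg: PipelineConfig, mass_config: MassConfig) -> dict:
    data_dir = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    run = read_run(_require(data_dir / "manifest.csv", "simulate", "reduce"))
    result = reduce_run(run, mass_config, cfg.thresholds, seed=cfg.seed)
    write_signatures(result, out / "signatures.csv", _meta(cfg))
    write_profiles(result.profiles, out / "profiles_long.csv", meta=_meta(cfg))
    qc = {**result.qc, "retained_elements": result.retained_elements,
          "thresholds": cfg.thresholds.__dict__}
    (out / "qc.json").write_text(json.dumps(qc, indent=1, default=str))
    for rid, score in result.qc["excluded_replicates"].items():
        log.info("reduce: replicate %s excluded (outlyingness %.2f > %s)",
                 rid, score, cfg.thresholds.outlyingness_cutoff)
    for el, frac in result.qc["below_lod_fraction"].items():
        if el not in result.retained_elements:
            log.info("reduce: element %s omitted (%.1f%% of measures below LOD >= %d%%)",
                     el, 100 * frac, int(100 * cfg.thresholds.lod_fraction))
    return {"signatures": out / "signatures.csv", "profiles": out / "profiles_long.csv"}


def _signature_features(sig_df: pd.DataFrame, specimens: pd.DataFrame,
                        classes: list[str], target: str, internal_standard: str):
    sub = sig_df[(sig_df.retained) & (~sig_df.missing)
                 & (sig_df.element != internal_standard)
                 & (sig_df.target == target)]
    wide = sub.pivot_table(index="specimen_id", columns="element",
                           values="ratio_umol_mol", sort=True)
    info = specimens.set_index("specimen_id")
    keep = [sid for sid in wide.index if info.loc[sid, "cls"] in classes]
    wide = wide.loc[keep]
    groups = [info.loc[sid, "group"] for sid in wide.index]
    return wide, groups


def _test_battery(name: str, X, ids, groups, cfg: PipelineConfig) -> dict:
    dm = euclidean_dm(np.asarray(X, dtype=float), ids)
    perm = permanova(dm, groups, n_perm=cfg.n_permutations, seed=cfg.seed)
    cap = cap_fit(dm, groups, m=cfg.cap_m, n_perm=cfg.n_permutations, seed=cfg.seed)
    log.info("stats[%s]: PERMANOVA F=%.3f p=%.3f | CAP m=%d acc=%.1f%% "
             "(chance %.1f%%) p=%.3f", name, perm.pseudo_f, perm.p_value,
             cap.m, cap.loo_accuracy, cap.pcc.chance_accuracy, cap.p_value)
    return {
        "permanova": {"pseudo_f": perm.pseudo_f, "p": perm.p_value,
                      "df": [perm.df_between, perm.df_within]},
        "cap": {"m": cap.m, "g_prop": cap.g_prop, "trace_stat": cap.trace_stat,
                "p": cap.p_value, "loo_accuracy_pct": cap.loo_accuracy,
                "confusion": cap.confusion.tolist(),
                "groups": list(map(str, cap.group_labels))},
        "pcc": {"chance_pct": cap.pcc.chance_accuracy,
                "observed_pct": cap.pcc.observed_accuracy, "p": cap.pcc.p_value},
    }


def _stage_stats(cfg: PipelineConfig, mass_config: MassConfig) -> dict:
    out = Path(cfg.out_dir)
    data_dir = Path(cfg.data_dir)
    sig_df = pd.read_csv(_require(out / "signatures.csv", "reduce", "stats"))
    specimens = pd.read_csv(_require(data_dir / "specimens.csv", "simulate", "stats"))
    report: dict = {"seed": cfg.seed, "n_permutations": cfg.n_permutations}
    for name, classes, target in (
        ("H1_focus", ["embryo"], "focus"),
        ("H1_edge", ["embryo"], "edge"),
        ("H3_edge", ["embryo", "female"], "edge"),
    ):
        wide, groups = _signature_features(
            sig_df, specimens, classes, target, mass_config.internal_standard)
        if len(set(groups)) >= 2:
            report[name] = _test_battery(name, wide.to_numpy(), wide.index, groups, cfg)
    profiles = read_profiles(_require(out / "profiles_long.csv", "reduce", "stats"))
    info = specimens.set_index("specimen_id")
    embryo_profiles = [p for p in profiles if info.loc[p.specimen_id, "cls"] == "embryo"]
    if len(embryo_profiles) >= 2:
        retained = sorted(set(sig_df[sig_df.retained].element)
                          - {mass_config.internal_standard})
        _, features, _ = resample_transects(embryo_profiles, retained)
        groups = [info.loc[sid, "group"] for sid in features.index]
        if len(set(groups)) >= 2:
            report["H2_transects"] = _test_battery(
                "H2_transects", features.to_numpy(), features.index, groups, cfg)
    path = out / "stats_report.json"
    path.write_text(json.dumps(report, indent=1))
    return {"stats_report": path}


def _stage_profiles(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    profiles = read_profiles(_require(out / "profiles_long.csv", "reduce", "profiles"))
    window = cfg.thresholds.smoothing_window
    calls, smooth_rows = [], []
    for p in profiles:
        rp = ratio_profiles(p, window)
        calls.append(classify_pattern(rp, cfg.thresholds))
        smooth_rows.append(pd.DataFrame({
            "specimen_id": rp.specimen_id, "distance_um": rp.distance_um,
            "srba": rp.srba, "srba_smooth": rp.srba_smooth,
            "pbca": rp.pbca, "pbca_smooth": rp.pbca_smooth,
        }))
    write_calls(calls, out / "pattern_calls.csv", _meta(cfg))
    write_csv(pd.concat(smooth_rows, ignore_index=True),
              out / "smoothed_profiles.csv", _meta(cfg))
    n1 = sum(c.pattern == "1" for c in calls)
    n2 = sum(c.pattern == "2" for c in calls)
    log.info("profiles: %d calls (%d Pattern 1, %d Pattern 2, %d undetermined)",
             len(calls), n1, n2, len(calls) - n1 - n2)
    return {"calls": out / "pattern_calls.csv"}


def _stage_backcalc(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    data_dir = Path(cfg.data_dir)
    calls = pd.read_csv(_require(out / "pattern_calls.csv", "profiles", "backcalc"))
    specimens = pd.read_csv(_require(data_dir / "specimens.csv", "simulate", "backcalc"))
    params = BackCalcParams(slope=cfg.backcalc_slope, intercept=cfg.backcalc_intercept,
                            radius_unit=cfg.radius_unit)
    merged = calls.merge(specimens.rename(columns={"pattern": "true_pattern"}),
                         on="specimen_id", how="left")
    rows = []
    for row in merged.itertuples():
        if str(row.pattern) != "1":
            continue
        r_t_mm = row.shift_um / 1000.0
        l_t = fraser_lee(min(r_t_mm, row.radius_mm), row.radius_mm, row.length_cm, params)
        rows.append({
            "specimen_id": row.specimen_id, "cls": row.cls,
            "length_cm": row.length_cm, "radius_mm": row.radius_mm,
            "shift_um": row.shift_um, "l_shift_cm": l_t,
            "delta_l_cm": row.length_cm - l_t,
        })
    write_csv(pd.DataFrame(rows), out / "backcalc.csv", _meta(cfg))
    return {"backcalc": out / "backcalc.csv"}


def run_pipeline(cfg: PipelineConfig, stages=("all",),
                 mass_config: MassConfig | None = None,
                 design: StudyDesign | None = None) -> dict:
    """Execute the selected stages in pipeline order; returns artifact paths."""
    mass_config = mass_config or default_mass_config()
    design = design or StudyDesign(seed=cfg.seed)
    wanted = list(STAGES) if "all" in stages else [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES) - {"all"}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    artifacts: dict = {}
    for stage in wanted:
        log.info("stage %s (seed=%d, config=%s)", stage, cfg.seed, cfg.config_hash())
        if stage == "simulate":
            artifacts.update(_stage_simulate(cfg, mass_config, design))
        elif stage == "reduce":
            artifacts.update(_stage_reduce(cfg, mass_config))
        elif stage == "stats":
            artifacts.update(_stage_stats(cfg, mass_config))
        elif stage == "profiles":
            artifacts.update(_stage_profiles(cfg))
        elif stage == "backcalc":
            artifacts.update(_stage_backcalc(cfg))
    return artifacts
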