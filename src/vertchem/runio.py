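"""CSV readers and writers for runs, signatures, profiles and calls.

All tables are RFC-4180 CSV, UTF-8, "." decimal. Every artifact gets a
sidecar ``<name>.meta.json`` recording the package version, configuration
hash and root seed, so outputs are auditable without parsing CSV comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import AblationRecord, ROLES, RunSequence
from .reduction import ReductionResult, TransectProfile

__all__ = [
    "write_csv",
    "write_run",
    "read_run",
    "write_signatures",
    "read_signatures",
    "write_profiles",
    "read_profiles",
    "write_calls",
]

_VERSION = "0.1.0"

_MANIFEST_COLS = [
    "record_id", "role", "specimen_id", "target", "replicate", "order",
    "slide", "spot_um", "scan_speed_um_s", "scan_length_um", "scan_from_focus",
]


def write_csv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {"version": _VERSION, **(meta or {})}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def write_run(run: RunSequence, directory: str | Path, meta: dict | None = None) -> Path:
    """One CSV per ablation (time_s + one column per mass) plus a manifest."""
    directory = Path(directory)
    rec_dir = directory / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec in run.records:
        df = pd.DataFrame(rec.cps, columns=list(rec.masses))
        df.insert(0, "time_s", rec.time_s)
        df.to_csv(rec_dir / f"{rec.record_id}.csv", index=False)
    write_csv(run.manifest(), directory / "manifest.csv", meta)
    return directory


def read_run(manifest_path: str | Path, data_dir: str | Path | None = None) -> RunSequence:
    """Load and validate a run from a manifest and per-ablation CSVs."""
    manifest_path = Path(manifest_path)
    data_dir = Path(data_dir) if data_dir else manifest_path.parent / "records"
    man = pd.read_csv(manifest_path)
    missing_cols = [c for c in _MANIFEST_COLS if c not in man.columns]
    if missing_cols:
        raise ValueError(f"manifest lacks columns: {missing_cols}")
    bad_roles = sorted(set(man.role) - set(ROLES))
    if bad_roles:
        raise ValueError(f"manifest contains unknown roles: {bad_roles}")
    records: list[AblationRecord] = []
    masses: tuple[str, ...] | None = None
    for row in man.itertuples():
        path = data_dir / f"{row.record_id}.csv"
        if not path.exists():
            raise FileNotFoundError(f"record {row.record_id}: missing data file {path}")
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError(f"record {row.record_id}: no time_s column")
        rec_masses = tuple(c for c in df.columns if c != "time_s")
        if masses is None:
            masses = rec_masses
        elif rec_masses != masses:
            lost = sorted(set(masses) - set(rec_masses))
            raise ValueError(f"record {row.record_id}: missing mass columns {lost}")
        records.append(AblationRecord(
            record_id=row.record_id, role=row.role,
            time_s=df["time_s"].to_numpy(), cps=df[list(masses)].to_numpy(),
            masses=masses, order=int(row.order),
            specimen_id=row.specimen_id if isinstance(row.specimen_id, str) and row.specimen_id else None,
            target=row.target if isinstance(row.target, str) and row.target else None,
            replicate=None if row.replicate == -1 else int(row.replicate),
            slide=row.slide if isinstance(row.slide, str) and row.slide else None,
            spot_um=None if pd.isna(row.spot_um) else float(row.spot_um),
            scan_speed_um_s=None if pd.isna(row.scan_speed_um_s) else float(row.scan_speed_um_s),
            scan_length_um=None if pd.isna(row.scan_length_um) else float(row.scan_length_um),
            scan_from_focus=bool(row.scan_from_focus),
        ))
    run = RunSequence(records=records, masses=masses or ())
    if not run.of_role("nist612"):
        raise ValueError("no calibration standards (nist612) in run")
    return run


def write_signatures(result: ReductionResult, path: str | Path,
                     meta: dict | None = None) -> None:
    """Tidy signature table: one row per specimen x target x element."""
    rows = []
    for sig in result.signatures:
        for j, el in enumerate(sig.elements):
            rows.append({
                "specimen_id": sig.specimen_id, "target": sig.target, "element": el,
                "mean_ppm": sig.mean_ppm[j], "ratio_umol_mol": sig.ratio_umol_mol[j],
                "below_lod": bool(sig.below_lod[j]),
                "retained": el in result.retained_elements,
                "missing": sig.missing,
                "replicates_used": ";".join(sig.replicates_used),
                "replicates_excluded": ";".join(r for r, _ in sig.replicates_excluded),
            })
    write_csv(pd.DataFrame(rows), path, meta)


def read_signatures(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profiles(profiles: list[TransectProfile], path: str | Path,
                   masses: list[str] | None = None, meta: dict | None = None) -> None:
    """Long-format profile table: specimen, distance_um, mass, cps, ppm."""
    frames = []
    for p in profiles:
        keep = masses or list(p.masses)
        for el in keep:
            j = p.masses.index(el)
            frames.append(pd.DataFrame({
                "specimen_id": p.specimen_id, "distance_um": p.distance_um,
                "mass": el, "cps": p.net_cps[:, j], "ppm": p.ppm[:, j],
            }))
    write_csv(pd.concat(frames, ignore_index=True), path, meta)


def read_profiles(path: str | Path) -> list[TransectProfile]:
    df = pd.read_csv(path)
    profiles = []
    for sid, sub in df.groupby("specimen_id", sort=False):
        wide_cps = sub.pivot_table(index="distance_um", columns="mass",
                                   values="cps", sort=True)
        wide_ppm = sub.pivot_table(index="distance_um", columns="mass",
                                   values="ppm", sort=True)
        masses = tuple(wide_cps.columns)
        profiles.append(TransectProfile(
            specimen_id=str(sid), distance_um=wide_cps.index.to_numpy(),
            masses=masses, net_cps=wide_cps.to_numpy(), ppm=wide_ppm.to_numpy(),
        ))
    return profiles


def write_calls(calls, path: str | Path, meta: dict | None = None) -> None:
    rows = [{
        "specimen_id": c.specimen_id, "pattern": c.pattern,
        "peak_srba": c.peak_srba, "terminal_srba": c.terminal_srba,
        "focus_srba": c.focus_srba,
        "shift_um": np.nan if c.shift_um is None else c.shift_um,
        "pb_corroborated": c.pb_corroborated,
    } for c in calls]
    write_csv(pd.DataFrame(rows), path, meta)
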