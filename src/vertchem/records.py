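"""In-memory containers for ablation records and run sequences."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AblationRecord", "RunSequence", "ROLES"]

ROLES = ("gas_blank", "nist612", "macs3", "spot", "transect")


@dataclass
class AblationRecord:
    """One ablation: a time-resolved cps matrix plus role metadata.

    ``cps`` has shape (n_time_points, n_masses); columns follow ``masses``.
    Spot records carry ``spot_um``; transect records carry the scan geometry
    (``scan_length_um``, ``scan_speed_um_s``, and whether the scan started at
    the vertebral focus).
    """

    record_id: str
    role: str
    time_s: np.ndarray
    cps: np.ndarray
    masses: tuple[str, ...]
    order: int
    specimen_id: str | None = None
    target: str | None = None        # focus | edge | transect
    replicate: int | None = None
    slide: str | None = None
    spot_um: float | None = None
    scan_speed_um_s: float | None = None
    scan_length_um: float | None = None
    scan_from_focus: bool = True

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.cps = np.asarray(self.cps, dtype=float)
        if self.cps.shape != (len(self.time_s), len(self.masses)):
            raise ValueError(
                f"{self.record_id}: cps shape {self.cps.shape} does not match "
                f"{len(self.time_s)} time points x {len(self.masses)} masses"
            )
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError(f"{self.record_id}: time grid must be strictly increasing")
        if np.any(self.cps < 0):
            raise ValueError(f"{self.record_id}: raw cps must be nonnegative")

    def column(self, mass: str) -> np.ndarray:
        return self.cps[:, self.masses.index(mass)]


@dataclass
class RunSequence:
    """All ablation records of one acquisition run, ordered by acquisition."""

    records: list[AblationRecord]
    masses: tuple[str, ...]
    _by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.order)
        self._by_id = {}
        for rec in self.records:
            if rec.record_id in self._by_id:
                raise ValueError(f"duplicate record id {rec.record_id!r}")
            if rec.masses != self.masses:
                raise ValueError(f"{rec.record_id}: mass columns differ from run")
            self._by_id[rec.record_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> AblationRecord:
        return self._by_id[record_id]

    def of_role(self, role: str) -> list[AblationRecord]:
        return [r for r in self.records if r.role == role]

    def bracketing_blanks(self, rec: AblationRecord) -> tuple[AblationRecord, AblationRecord]:
        """Nearest gas blanks before and after a record, by acquisition order."""
        before = [b for b in self.records if b.role == "gas_blank" and b.order < rec.order]
        after = [b for b in self.records if b.role == "gas_blank" and b.order > rec.order]
        if not before or not after:
            raise ValueError(f"{rec.record_id}: no bracketing gas blanks in run")
        return before[-1], after[0]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "record_id": r.record_id, "role": r.role,
                "specimen_id": r.specimen_id or "", "target": r.target or "",
                "replicate": -1 if r.replicate is None else r.replicate,
                "order": r.order, "slide": r.slide or "",
                "spot_um": np.nan if r.spot_um is None else r.spot_um,
                "scan_speed_um_s": np.nan if r.scan_speed_um_s is None else r.scan_speed_um_s,
                "scan_length_um": np.nan if r.scan_length_um is None else r.scan_length_um,
                "scan_from_focus": r.scan_from_focus,
            })
        return pd.DataFrame(rows)
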