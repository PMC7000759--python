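"""Configuration for LA-ICP-MS vertebral microchemistry runs.

One :class:`MassConfig` describes the monitored isotope masses, the internal
standard, and the nominal concentrations of the external calibration glasses.
The same object parameterizes both the synthetic signal generator and the
signal reducer, so calibration is closed over the configuration and no
external certificate values are needed.

All processing thresholds live in :class:`Thresholds` with the study defaults
(Grubbs alpha 0.05, LOD = 3*SD of gas blanks, >=10% below-LOD element
omission, replicate outlyingness cutoff 10, 11-point smoothing window,
Sr:Ba pattern thresholds 200/600/400).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "IsotopeSpec",
    "MassConfig",
    "Thresholds",
    "PipelineConfig",
    "default_mass_config",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class IsotopeSpec:
    """One monitored isotope mass.

    ``atomic_mass`` is the standard atomic weight of the element (g/mol),
    used to convert mass-fraction concentrations to molar element:Ca ratios.
    ``nist612_ppm`` / ``macs3_ppm`` are the nominal concentrations of the
    calibration standards. ``blank_mean_cps``/``blank_sd_cps``,
    ``sensitivity_cps_per_ppm`` and ``base_ppm`` parameterize the forward
    model of the synthetic generator; the reducer never reads them, it
    estimates blanks and sensitivities from the run itself.
    """

    label: str
    element: str
    atomic_mass: float
    nist612_ppm: float
    macs3_ppm: float
    blank_mean_cps: float
    blank_sd_cps: float
    sensitivity_cps_per_ppm: float
    base_ppm: float

    def __post_init__(self) -> None:
        if self.atomic_mass <= 0:
            raise ValueError(f"{self.label}: atomic mass must be > 0")
        if self.nist612_ppm < 0 or self.macs3_ppm < 0:
            raise ValueError(f"{self.label}: standard concentrations must be >= 0")


# label, element, atomic weight, NIST-612 ppm, MACS-3 ppm, blank mean cps,
# blank SD cps, sensitivity cps/ppm, nominal vertebral ppm (generator truth).
_DEFAULT_TABLE = [
    ("Li7", "Li", 6.94, 40.0, 10.0, 50.0, 7.0, 300.0, 2.0),
    ("Mg24", "Mg", 24.305, 68.0, 1200.0, 400.0, 25.0, 500.0, 2500.0),
    ("Ca43", "Ca", 40.078, 85050.0, 380000.0, 800.0, 45.0, 6.0, 399000.0),
    ("Sc45", "Sc", 44.956, 41.0, 20.0, 40.0, 6.0, 900.0, 0.003),
    ("V51", "V", 50.942, 39.0, 60.0, 60.0, 8.0, 900.0, 0.004),
    ("Cr53", "Cr", 51.996, 36.0, 110.0, 150.0, 15.0, 700.0, 0.010),
    ("Mn55", "Mn", 54.938, 38.0, 550.0, 120.0, 12.0, 1000.0, 5.0),
    ("Fe57", "Fe", 55.845, 51.0, 11000.0, 2000.0, 90.0, 200.0, 150.0),
    ("Co59", "Co", 58.933, 35.0, 60.0, 30.0, 5.0, 1100.0, 0.3),
    ("Cu63", "Cu", 63.546, 37.0, 120.0, 200.0, 18.0, 800.0, 2.0),
    ("Ge72", "Ge", 72.630, 36.0, 50.0, 40.0, 6.0, 400.0, 0.008),
    ("Rb85", "Rb", 85.468, 31.0, 9.0, 60.0, 8.0, 1200.0, 1.5),
    ("Sr88", "Sr", 87.62, 78.0, 6700.0, 100.0, 10.0, 900.0, 2200.0),
    ("Y89", "Y", 88.906, 38.0, 26.0, 20.0, 4.0, 1300.0, 0.5),
    ("Cd114", "Cd", 112.414, 28.0, 65.0, 25.0, 5.0, 350.0, 0.3),
    ("Sn118", "Sn", 118.710, 38.0, 60.0, 80.0, 9.0, 500.0, 0.5),
    ("Ba137", "Ba", 137.327, 39.0, 58.0, 60.0, 8.0, 700.0, 10.0),
    ("Au197", "Au", 196.967, 5.0, 2.0, 15.0, 4.0, 600.0, 0.003),
    ("Pb208", "Pb", 207.2, 39.0, 55.0, 90.0, 10.0, 1500.0, 0.8),
    ("Th232", "Th", 232.038, 37.0, 60.0, 10.0, 3.0, 1200.0, 0.001),
    ("U238", "U", 238.029, 37.0, 155.0, 8.0, 3.0, 1400.0, 0.001),
]


@dataclass(frozen=True)
class MassConfig:
    """Monitored isotope set plus internal-standard bookkeeping.

    ``ca_mass_fraction`` is the assumed Ca mass fraction of vertebral
    bioapatite used as the sample internal-standard index when converting
    to absolute ppm; element:Ca molar ratios do not depend on it.
    """

    isotopes: tuple[IsotopeSpec, ...]
    internal_standard: str = "Ca43"
    ca_mass_fraction: float = 0.399
    acquisition_rate_hz: float = 5.0  # points per second (instrument config)

    def __post_init__(self) -> None:
        if self.internal_standard not in self.labels:
            raise ValueError(
                f"internal standard {self.internal_standard!r} not among monitored masses"
            )
        if not 0 < self.ca_mass_fraction < 1:
            raise ValueError("ca_mass_fraction must be in (0, 1)")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(iso.label for iso in self.isotopes)

    def __getitem__(self, label: str) -> IsotopeSpec:
        for iso in self.isotopes:
            if iso.label == label:
                return iso
        raise KeyError(label)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def internal_standard_ppm(self) -> float:
        """Assumed Ca concentration of the sample matrix (ppm by mass)."""
        return self.ca_mass_fraction * 1e6


def default_mass_config() -> MassConfig:
    return MassConfig(isotopes=tuple(IsotopeSpec(*row) for row in _DEFAULT_TABLE))


@dataclass(frozen=True)
class Thresholds:
    """All screening/classification thresholds, with study defaults."""

    grubbs_alpha: float = 0.05
    lod_sd_multiplier: float = 3.0
    lod_fraction: float = 0.10          # elements with >= this fraction below LOD dropped
    outlyingness_cutoff: float = 10.0   # replicate exclusion
    outlyingness_projections: int = 1000
    smoothing_window: int = 11
    srba_low: float = 200.0             # Pattern-2 ceiling
    srba_peak: float = 600.0            # Pattern-1 minimum peak
    srba_return: float = 400.0          # nearshore-return crossing level
    segment_fraction: float = 0.10      # terminal/initial segment length
    plateau_sd_multiplier: float = 10.0  # plateau = internal std > blank + k*SD
    plateau_trim_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.grubbs_alpha < 1:
            raise ValueError("grubbs_alpha must be in (0,1)")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if not 0 < self.segment_fraction <= 0.5:
            raise ValueError("segment_fraction must be in (0, 0.5]")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (serializes to YAML, round-trip stable)."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    n_permutations: int = 999
    seed: int = 0
    cap_m: int | None = None            # None -> LOO-maximizing auto choice
    backcalc_slope: float = 17.349      # cm per mm of vertebral radius
    backcalc_intercept: float = 14.516  # cm
    radius_unit: str = "mm"
    data_dir: str = "run"
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    thr = Thresholds(**raw.pop("thresholds"))
    return PipelineConfig(thresholds=thr, **raw)
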