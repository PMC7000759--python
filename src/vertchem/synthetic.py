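"""Synthetic LA-ICP-MS run generator with known ground truth.

Emulates the vertebral-microchemistry study design end to end: gas blanks
bracketing every ablation, NIST-612 calibration brackets (two replicates
before and after every fifth vertebral section), MACS-3 QC brackets per
slide, triplicate focus/edge spots on embryo vertebrae, edge spots on
pregnant females, and focus-to-birthmark transects on young-of-the-year.

The forward model per record is

    cps(t, mass) = blank(mass) + S(mass) * d(order, mass) * ppm(t, mass)

with Gaussian counting noise (variance proportional to the mean), a small
multiplicative flicker, rare single-point spikes, and a linear per-mass
sensitivity drift across the acquisition run. Litters carry multi-element
signatures shared exactly between a mother's vertebral edge and her embryos'
(the maternal tag); in utero Sr, Ba and Pb content follows one of two
gestation migration trajectories:

* Pattern 1 — Sr:Ba rises from a low nearshore baseline to an offshore peak
  (600-1200) and declines rapidly below 400 at the shift fraction, while
  Pb:Ca rises in the terminal segment (return to nearshore waters).
* Pattern 2 — Sr:Ba stays within 0-200 throughout, with Pb:Ca elevated at
  the focus (nearshore residency for the whole gestation).

All randomness flows from one root seed through per-record named substreams,
so individual records are reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .backcalc import BackCalcParams, radius_from_length
from .config import MassConfig, default_mass_config
from .records import AblationRecord, RunSequence

__all__ = [
    "StudyDesign",
    "NoiseParams",
    "TrajectoryParams",
    "MigrationTrajectory",
    "SyntheticTruth",
    "simulate_trajectory",
    "render_ablation",
    "make_study",
    "summarize_lengths",
]

SPOT_DIAMETER_UM = 83.0
SPOT_DURATION_S = 60.0
SCAN_SPEED_UM_S = 10.0
BLANK_DURATION_S = 60.0
LEAD_IN_S = 10.0
WASHOUT_S = 5.0

YOY_SITES = ("la_reforma", "teacapan", "salina_cruz")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of one synthetic study."""

    n_females: int = 4
    litter_sizes: tuple[int, ...] = (4, 3, 3, 4)
    n_yoy: int = 15
    pattern_mix: float = 11 / 15          # fraction of Pattern-1 mothers among YOY
    female_length_range_cm: tuple[float, float] = (240.0, 291.0)
    embryo_length_range_cm: tuple[float, float] = (41.0, 49.0)
    yoy_length_range_cm: tuple[float, float] = (49.2, 59.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 0 or self.n_yoy < 0 or any(s < 0 for s in self.litter_sizes):
            raise ValueError("counts must be nonnegative")
        if len(self.litter_sizes) != self.n_females:
            raise ValueError("litter_sizes must have one entry per female")
        if not 0 <= self.pattern_mix <= 1:
            raise ValueError("pattern_mix must be in [0, 1]")
        for lo, hi in (self.female_length_range_cm, self.embryo_length_range_cm,
                       self.yoy_length_range_cm):
            if not lo < hi:
                raise ValueError("length intervals need low < high")


@dataclass(frozen=True)
class NoiseParams:
    """Instrument noise controls. ``noise_scale=0`` gives the noiseless limit."""

    noise_scale: float = 1.0
    flicker: float = 0.02
    spike_prob: float = 0.01
    spike_mag: tuple[float, float] = (5.0, 20.0)
    replicate_sigma: float = 0.08   # lognormal positional heterogeneity between spot scans

    @classmethod
    def noiseless(cls) -> "NoiseParams":
        """Fully deterministic forward model (no noise, spikes or heterogeneity)."""
        return cls(noise_scale=0.0, flicker=0.0, spike_prob=0.0, replicate_sigma=0.0)


@dataclass(frozen=True)
class TrajectoryParams:
    """Shape parameters of the two gestation migration trajectories."""

    base_range: tuple[float, float] = (60.0, 160.0)
    peak_range: tuple[float, float] = (650.0, 1150.0)
    terminal_range: tuple[float, float] = (120.0, 300.0)
    shift_fraction: float = 0.85
    shift_jitter: float = 0.02
    rise_center: float = 0.4
    rise_width: float = 0.1
    fall_width: float = 0.015
    env_jitter_sd: float = 10.0
    env_ar: float = 0.8
    pb_low: float = 0.3
    pb_high_range: tuple[float, float] = (1.2, 2.2)
    p2_mean_range: tuple[float, float] = (80.0, 150.0)
    p2_pb_start_range: tuple[float, float] = (1.5, 2.5)
    p2_pb_decay: float = 0.07             # fraction of transect over which focus Pb decays


@dataclass(frozen=True)
class MigrationTrajectory:
    pattern: int
    n_points: int
    srba_env: np.ndarray                  # environmental Sr:Ba index per scan point
    pb_env: np.ndarray                    # environmental Pb index per scan point
    shift_fraction: float | None          # Pattern 1 only
    sr_scale: float = 1.0                 # persistent Sr uptake level of this track


@dataclass
class SyntheticTruth:
    """Ground truth for every generated record and specimen."""

    specimens: pd.DataFrame
    signatures: dict            # (group, target) -> ppm vector over masses
    trajectories: dict          # key (litter group or specimen id) -> MigrationTrajectory
    record_ppm: dict            # record_id -> ppm vector (spots) or matrix (transects)
    drift_slopes: dict          # mass label -> fractional slope over the run
    masses: tuple[str, ...]
    design: StudyDesign
    noise: NoiseParams


def _rng(root_seed: int, name: str) -> np.random.Generator:
    """Named substream: reproducible per record regardless of render order."""
    return np.random.default_rng([root_seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _ar1(rng: np.random.Generator, n: int, sd: float, ar: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1 - ar**2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = ar * out[i - 1] + eps[i]
    return out


def simulate_trajectory(pattern: int, n_points: int,
                        params: TrajectoryParams = TrajectoryParams(),
                        seed: int | np.random.Generator = 0) -> MigrationTrajectory:
    """Draw one gestation migration trajectory on a unit-length transect.

    Pattern 1 is a logistic rise from a nearshore baseline to an offshore
    peak followed by a rapid logistic decline beginning at the shift
    fraction; Pattern 2 is a constant low mean with AR(1) environmental
    jitter clipped inside the 0-200 nearshore band.
    """
    if pattern not in (1, 2):
        raise ValueError(f"pattern must be 1 or 2, got {pattern!r}")
    if n_points < 50:
        raise ValueError("transect trajectories need n_points >= 50")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_points)
    sr_scale = float(rng.lognormal(0.0, 0.15))
    if pattern == 1:
        base = rng.uniform(*params.base_range)
        peak = rng.uniform(*params.peak_range)
        term = rng.uniform(*params.terminal_range)
        shift = float(np.clip(
            params.shift_fraction + rng.uniform(-1, 1) * params.shift_jitter, 0.6, 0.95))
        rise = base + (peak - base) * _sigmoid((x - params.rise_center) / params.rise_width)
        srba = term + (rise - term) * _sigmoid((shift - x) / params.fall_width)
        jitter = np.clip(_ar1(rng, n_points, params.env_jitter_sd, params.env_ar), -30, 30)
        srba = np.clip(srba + jitter, 5.0, None)
        pb_high = rng.uniform(*params.pb_high_range)
        pb = params.pb_low + (pb_high - params.pb_low) * _sigmoid((x - shift) / 0.02)
        return MigrationTrajectory(1, n_points, srba, pb, shift, sr_scale)
    mean = rng.uniform(*params.p2_mean_range)
    jitter = _ar1(rng, n_points, params.env_jitter_sd, params.env_ar)
    srba = np.clip(mean + jitter, 5.0, 195.0)
    pb_start = rng.uniform(*params.p2_pb_start_range)
    pb = params.pb_low * 1.5 + (pb_start - params.pb_low * 1.5) * np.exp(-x / params.p2_pb_decay)
    return MigrationTrajectory(2, n_points, srba, pb, None, sr_scale)


# ---------------------------------------------------------------------------
# record rendering


def render_ablation(
    ppm,
    role: str,
    order: int,
    config: MassConfig,
    drift_slopes: dict,
    max_order: int,
    noise: NoiseParams = NoiseParams(),
    rng: np.random.Generator | int = 0,
    record_id: str = "rec",
    **meta,
) -> AblationRecord:
    """Render one ablation record from true concentrations.

    ``ppm`` is a per-mass vector for blanks/standards/spots (ignored for
    gas blanks) or an (n_scan_points, n_masses) matrix for transects. The
    plateau model is: lead-in baseline, signal, washout baseline.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rate = config.acquisition_rate_hz
    labels = config.labels
    blank_mean = np.array([config[m].blank_mean_cps for m in labels])
    sens = np.array([config[m].sensitivity_cps_per_ppm for m in labels])
    drift = np.array([
        1.0 + drift_slopes.get(m, 0.0) * (order / max(max_order, 1)) for m in labels
    ])

    if role == "gas_blank":
        n = int(round(BLANK_DURATION_S * rate))
        mean = np.tile(blank_mean, (n, 1))
    elif role == "transect":
        ppm = np.asarray(ppm, dtype=float)
        n_lead = int(round(LEAD_IN_S * rate))
        n_wash = int(round(WASHOUT_S * rate))
        signal = blank_mean + sens * drift * ppm
        mean = np.vstack([
            np.tile(blank_mean, (n_lead, 1)), signal, np.tile(blank_mean, (n_wash, 1)),
        ])
    else:  # nist612, macs3, spot: plateau of fixed duration
        ppm = np.asarray(ppm, dtype=float)
        n_lead = int(round(LEAD_IN_S * rate))
        n_plat = int(round(SPOT_DURATION_S * rate))
        n_wash = int(round(WASHOUT_S * rate))
        signal = blank_mean + sens * drift * ppm
        mean = np.vstack([
            np.tile(blank_mean, (n_lead, 1)),
            np.tile(signal, (n_plat, 1)),
            np.tile(blank_mean, (n_wash, 1)),
        ])

    cps = mean.copy()
    if noise.noise_scale > 0:
        cps = cps + np.sqrt(np.maximum(mean, 0)) * rng.standard_normal(mean.shape) \
            * noise.noise_scale
        cps = cps * (1.0 + noise.flicker * noise.noise_scale * rng.standard_normal(mean.shape))
    if noise.spike_prob > 0:
        mask = rng.random(mean.shape) < noise.spike_prob
        cps = np.where(mask, cps * rng.uniform(*noise.spike_mag, mean.shape), cps)
    cps = np.maximum(cps, 0.0)
    time_s = np.arange(mean.shape[0]) / rate
    return AblationRecord(
        record_id=record_id, role=role, time_s=time_s, cps=cps,
        masses=labels, order=order, **meta,
    )


# ---------------------------------------------------------------------------
# study assembly


def _litter_signature(rng: np.random.Generator, config: MassConfig) -> np.ndarray:
    """Multi-element ppm vector for one litter/period: lognormal litter effect."""
    ppm = np.empty(len(config.labels))
    for i, lab in enumerate(config.labels):
        iso = config[lab]
        if lab == config.internal_standard:
            ppm[i] = config.internal_standard_ppm
        else:
            ppm[i] = iso.base_ppm * rng.lognormal(0.0, 0.25)
    return ppm


def _replicate_ppm(env: np.ndarray, config: MassConfig, sigma: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-replicate ppm: positional heterogeneity on trace elements.

    Each spot scan ablates slightly different material; the Ca matrix is
    stoichiometric and stays fixed.
    """
    out = env.copy()
    if sigma > 0:
        j_ca = config.index(config.internal_standard)
        factors = rng.lognormal(0.0, sigma, len(env))
        factors[j_ca] = 1.0
        out = out * factors
    return out


def _srba_to_ppm(srba_env, pb_env, config: MassConfig, sr_scale: float = 1.0):
    """Map environmental indices to Sr/Ba/Pb concentrations.

    Sr ppm is modulated mildly with the offshore index so Sr:Ca rises while
    Ba:Ca falls (their observed inverse relation), and scaled by the track's
    persistent Sr uptake level; Ba ppm is set so the drift-corrected net cps
    ratio Sr:Ba equals the environmental index exactly; Pb ppm is
    proportional to the Pb index.
    """
    srba_env = np.asarray(srba_env, dtype=float)
    sr_iso, ba_iso, pb_iso = config["Sr88"], config["Ba137"], config["Pb208"]
    norm = srba_env / max(float(np.max(srba_env)), 1e-12)
    sr_ppm = sr_iso.base_ppm * sr_scale * (0.75 + 0.5 * norm)
    ba_ppm = sr_iso.sensitivity_cps_per_ppm * sr_ppm / (
        ba_iso.sensitivity_cps_per_ppm * srba_env)
    pb_ppm = pb_iso.base_ppm * np.asarray(pb_env, dtype=float)
    return sr_ppm, ba_ppm, pb_ppm


def _transect_ppm(traj: MigrationTrajectory, focus_sig: np.ndarray,
                  edge_sig: np.ndarray, config: MassConfig) -> np.ndarray:
    """Per-point ppm matrix along a transect.

    Elements other than Sr/Ba/Pb blend linearly from the focus-period to the
    edge-period signature; Sr/Ba/Pb follow the migration trajectory.
    """
    n = traj.n_points
    x = np.linspace(0.0, 1.0, n)[:, None]
    ppm = focus_sig[None, :] * (1 - x) + edge_sig[None, :] * x
    sr_ppm, ba_ppm, pb_ppm = _srba_to_ppm(traj.srba_env, traj.pb_env, config,
                                          traj.sr_scale)
    ppm[:, config.index("Sr88")] = sr_ppm
    ppm[:, config.index("Ba137")] = ba_ppm
    ppm[:, config.index("Pb208")] = pb_ppm
    ppm[:, config.index(config.internal_standard)] = config.internal_standard_ppm
    return ppm


def _spot_ppm_from_trajectory(sig: np.ndarray, traj: MigrationTrajectory,
                              end: str, config: MassConfig) -> np.ndarray:
    """Spot-period ppm vector with Sr/Ba/Pb taken from a trajectory endpoint."""
    idx = 0 if end == "focus" else -1
    sr, ba, pb = _srba_to_ppm(traj.srba_env, traj.pb_env, config, traj.sr_scale)
    out = sig.copy()
    out[config.index("Sr88")] = sr[idx]
    out[config.index("Ba137")] = ba[idx]
    out[config.index("Pb208")] = pb[idx]
    return out


def _scan_points(length_um: float, config: MassConfig) -> int:
    return int(round(length_um / SCAN_SPEED_UM_S * config.acquisition_rate_hz)) + 1


def summarize_lengths(lengths) -> dict:
    """Mean/SD/min/max summary of a set of total lengths (cm, sample SD)."""
    arr = np.asarray(list(lengths), dtype=float)
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def make_study(
    design: StudyDesign = StudyDesign(),
    config: MassConfig | None = None,
    noise: NoiseParams = NoiseParams(),
    traj_params: TrajectoryParams = TrajectoryParams(),
    backcalc: BackCalcParams = BackCalcParams(),
) -> tuple[RunSequence, pd.DataFrame, SyntheticTruth]:
    """Generate a complete synthetic acquisition run with ground truth.

    Returns the ordered run sequence (blanks, calibration standards, spots,
    transects), the specimen table, and the truth object that every record
    traces back to.
    """
    config = config or default_mass_config()
    needed = {"Sr88", "Ba137", "Pb208", config.internal_standard}
    if not needed <= set(config.labels):
        raise ValueError("config must monitor Sr88, Ba137, Pb208 and the internal standard")
    seed = design.seed
    labels = config.labels

    drift_rng = _rng(seed, "drift")
    drift_slopes = {m: float(drift_rng.uniform(-0.08, 0.12)) for m in labels}

    # --- specimens -------------------------------------------------------
    spec_rows = []
    len_rng = _rng(seed, "lengths")
    for f in range(design.n_females):
        group = f"L{f + 1}"
        l_c = float(len_rng.uniform(*design.female_length_range_cm))
        spec_rows.append({
            "specimen_id": f"F{f + 1}", "cls": "female", "group": group,
            "length_cm": l_c, "radius_mm": radius_from_length(l_c, backcalc),
            "pattern": 1, "shift_fraction": np.nan,
        })
        for e in range(design.litter_sizes[f]):
            l_e = float(len_rng.uniform(*design.embryo_length_range_cm))
            spec_rows.append({
                "specimen_id": f"E{f + 1}.{e + 1}", "cls": "embryo", "group": group,
                "length_cm": l_e, "radius_mm": radius_from_length(l_e, backcalc),
                "pattern": 1, "shift_fraction": np.nan,
            })
    n_p1 = int(round(design.pattern_mix * design.n_yoy))
    patterns = np.array([1] * n_p1 + [2] * (design.n_yoy - n_p1))
    _rng(seed, "yoy-patterns").shuffle(patterns)
    for y in range(design.n_yoy):
        l_c = float(len_rng.uniform(*design.yoy_length_range_cm))
        spec_rows.append({
            "specimen_id": f"Y{y + 1}", "cls": "yoy",
            "group": YOY_SITES[y % len(YOY_SITES)],
            "length_cm": l_c, "radius_mm": radius_from_length(l_c, backcalc),
            "pattern": int(patterns[y]), "shift_fraction": np.nan,
        })
    specimens = pd.DataFrame(
        spec_rows, columns=["specimen_id", "cls", "group", "length_cm",
                            "radius_mm", "pattern", "shift_fraction"],
    )

    # --- litter / per-specimen signatures and trajectories ----------------
    signatures: dict = {}
    trajectories: dict = {}
    for f in range(design.n_females):
        group = f"L{f + 1}"
        for target in ("focus", "edge"):
            signatures[(group, target)] = _litter_signature(
                _rng(seed, f"sig-{group}-{target}"), config)
    for _, row in specimens[specimens.cls == "yoy"].iterrows():
        sid = row.specimen_id
        for target in ("focus", "edge"):
            signatures[(sid, target)] = _litter_signature(
                _rng(seed, f"sig-{sid}-{target}"), config)

    def transect_length_um(row) -> float:
        # embryos: focus -> edge (full radius); YOY: focus -> birthmark
        if row.cls == "embryo":
            return row.radius_mm * 1000.0
        birth_len = min(row.length_cm - 2.0,
                        float(_rng(seed, f"birth-{row.specimen_id}").uniform(44.0, 50.0)))
        return radius_from_length(birth_len, backcalc) * 1000.0

    # litter trajectories (shared by all embryos of the litter: the in utero
    # record is the mother's track); per-specimen trajectories for YOY
    embryo_rows = specimens[specimens.cls == "embryo"]
    litter_npts = {}
    for f in range(design.n_females):
        group = f"L{f + 1}"
        rows = embryo_rows[embryo_rows.group == group]
        if len(rows):
            litter_npts[group] = max(
                _scan_points(transect_length_um(r), config) for r in rows.itertuples())
            trajectories[group] = simulate_trajectory(
                1, litter_npts[group], traj_params, _rng(seed, f"traj-{group}"))
    for row in specimens[specimens.cls == "yoy"].itertuples():
        n_pts = _scan_points(transect_length_um(row), config)
        trajectories[row.specimen_id] = simulate_trajectory(
            int(row.pattern), n_pts, traj_params, _rng(seed, f"traj-{row.specimen_id}"))

    shift_map = {}
    for key, traj in trajectories.items():
        if traj.shift_fraction is not None:
            shift_map[key] = traj.shift_fraction
    specimens["shift_fraction"] = [
        shift_map.get(r.specimen_id, shift_map.get(r.group, np.nan))
        for r in specimens.itertuples()
    ]

    # --- acquisition schedule --------------------------------------------
    # (role, ppm, meta) tuples in order; blanks interleaved afterwards
    nist_ppm = np.array([config[m].nist612_ppm for m in labels])
    macs_ppm = np.array([config[m].macs3_ppm for m in labels])
    planned: list[tuple[str, object, dict]] = []

    def nist_bracket(tag: str) -> None:
        for rep in (1, 2):
            planned.append(("nist612", nist_ppm,
                            {"record_id": f"NIST-{tag}-r{rep}", "replicate": rep}))

    section_rows = list(specimens.itertuples())
    slide_of = {r.specimen_id: f"S{i // 5 + 1}" for i, r in enumerate(section_rows)}
    current_slide = None
    for i, row in enumerate(section_rows):
        slide = slide_of[row.specimen_id]
        if slide != current_slide:
            planned.append(("macs3", macs_ppm,
                            {"record_id": f"MACS-{slide}-open", "slide": slide}))
            current_slide = slide
        if i % 5 == 0:
            nist_bracket(f"sec{i}")
        sid, group = row.specimen_id, row.group
        key = group if row.cls in ("female", "embryo") else sid
        if row.cls == "embryo":
            traj = trajectories[group]
            for target in ("focus", "edge"):
                env = _spot_ppm_from_trajectory(
                    signatures[(group, target)], traj, target, config)
                signatures[(group, target)] = env  # the period environment vector
                for rep in (1, 2, 3):
                    rid = f"{sid}-{target}-r{rep}"
                    ppm = _replicate_ppm(env, config, noise.replicate_sigma,
                                         _rng(seed, rid + "-bio"))
                    planned.append(("spot", ppm, {
                        "record_id": rid, "specimen_id": sid,
                        "target": target, "replicate": rep, "slide": slide,
                        "spot_um": SPOT_DIAMETER_UM,
                    }))
            length_um = row.radius_mm * 1000.0
            n_pts = _scan_points(length_um, config)
            ppm_mat = _transect_ppm(
                replace(traj, n_points=n_pts,
                        srba_env=_resample(traj.srba_env, n_pts),
                        pb_env=_resample(traj.pb_env, n_pts)),
                signatures[(group, "focus")], signatures[(group, "edge")], config)
            planned.append(("transect", ppm_mat, {
                "record_id": f"{sid}-transect", "specimen_id": sid,
                "target": "transect", "slide": slide,
                "scan_speed_um_s": SCAN_SPEED_UM_S,
                "scan_length_um": (n_pts - 1) * SCAN_SPEED_UM_S / config.acquisition_rate_hz,
                "spot_um": SPOT_DIAMETER_UM,
            }))
        elif row.cls == "female":
            traj = trajectories.get(group)
            sig = signatures[(group, "edge")]
            env = (_spot_ppm_from_trajectory(sig, traj, "edge", config)
                   if traj is not None else sig)
            signatures[(group, "edge")] = env
            for rep in (1, 2, 3):
                rid = f"{sid}-edge-r{rep}"
                ppm = _replicate_ppm(env, config, noise.replicate_sigma,
                                     _rng(seed, rid + "-bio"))
                planned.append(("spot", ppm, {
                    "record_id": rid, "specimen_id": sid,
                    "target": "edge", "replicate": rep, "slide": slide,
                    "spot_um": SPOT_DIAMETER_UM,
                }))
        else:  # yoy
            traj = trajectories[sid]
            ppm_mat = _transect_ppm(traj, signatures[(sid, "focus")],
                                    signatures[(sid, "edge")], config)
            planned.append(("transect", ppm_mat, {
                "record_id": f"{sid}-transect", "specimen_id": sid,
                "target": "transect", "slide": slide,
                "scan_speed_um_s": SCAN_SPEED_UM_S,
                "scan_length_um": (traj.n_points - 1) * SCAN_SPEED_UM_S
                / config.acquisition_rate_hz,
                "spot_um": SPOT_DIAMETER_UM,
            }))
        if (i + 1) % 5 == 0 or i == len(section_rows) - 1:
            nist_bracket(f"sec{i}-close")
        last_of_slide = (i + 1 >= len(section_rows)
                         or slide_of[section_rows[i + 1].specimen_id] != slide)
        if last_of_slide:
            planned.append(("macs3", macs_ppm,
                            {"record_id": f"MACS-{slide}-close", "slide": slide}))

    # interleave gas blanks: one before every ablation plus one final
    records: list[AblationRecord] = []
    record_ppm: dict = {}
    order = 0
    max_order = 2 * len(planned)  # blanks double the schedule length
    for k, (role, ppm, meta) in enumerate(planned):
        blank_id = f"BLANK-{k:04d}"
        records.append(render_ablation(
            None, "gas_blank", order, config, drift_slopes, max_order,
            noise, _rng(seed, blank_id), record_id=blank_id))
        order += 1
        rec = render_ablation(
            ppm, role, order, config, drift_slopes, max_order,
            noise, _rng(seed, meta["record_id"]), **meta)
        records.append(rec)
        record_ppm[rec.record_id] = ppm
        order += 1
    final_blank = f"BLANK-{len(planned):04d}"
    records.append(render_ablation(
        None, "gas_blank", order, config, drift_slopes, max_order,
        noise, _rng(seed, final_blank), record_id=final_blank))

    run = RunSequence(records=records, masses=labels)
    truth = SyntheticTruth(
        specimens=specimens, signatures=signatures, trajectories=trajectories,
        record_ppm=record_ppm, drift_slopes=drift_slopes, masses=labels,
        design=design, noise=noise,
    )
    return run, specimens, truth


def _resample(values: np.ndarray, n: int) -> np.ndarray:
    old = np.linspace(0.0, 1.0, len(values))
    new = np.linspace(0.0, 1.0, n)
    return np.interp(new, old, values)
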