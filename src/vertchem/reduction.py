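"""Reduction of raw LA-ICP-MS cps records to calibrated element signatures.

The processing chain per spot sample is: signal-window selection on the
internal-standard plateau, background subtraction against the bracketing gas
blanks, iterative Grubbs despiking (alpha = 0.05), per-mass sensitivity-drift
correction by linear interpolation between calibration-standard brackets,
external calibration against NIST-612, internal standardization to Ca-43
(element:Ca molar ratios, umol/mol), limits of detection from 3*SD of the
pooled gas blanks, omission of elements with >= 10% of measurements below
LOD, and exclusion of replicate spot scans with multivariate outlyingness
above 10 before averaging. Transects go through the same chain pointwise and
are mapped to distance from the vertebral focus via the scan speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import t as t_dist

from .config import MassConfig, Thresholds
from .records import AblationRecord, RunSequence

__all__ = [
    "FailedAblationError",
    "CalibrationModel",
    "ElementSignature",
    "TransectProfile",
    "ReductionResult",
    "despike_grubbs",
    "grubbs_critical_value",
    "blank_statistics",
    "integrate_signal",
    "build_drift_model",
    "quantify_spot",
    "filter_by_lod",
    "detect_outlier_replicates",
    "reduce_transect",
    "resample_transects",
    "reduce_run",
]


class FailedAblationError(RuntimeError):
    """No usable plateau on the internal-standard mass."""


# ---------------------------------------------------------------------------
# despiking


@lru_cache(maxsize=65536)
def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution closed form."""
    if n < 3:
        return np.inf
    tv = t_dist.ppf(1 - alpha / (2 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(tv**2 / (n - 2 + tv**2)))


def despike_grubbs(series, alpha: float = 0.05) -> tuple[np.ndarray, list[int]]:
    """Iterative two-sided Grubbs despiking.

    The single most extreme point is tested against the critical value at
    the current sample size; detected spikes are removed from the test set
    and finally replaced by the mean of the non-spike points. Deterministic;
    series shorter than 3 points are returned unchanged with a warning.
    """
    x = np.asarray(series, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if x.size < 3:
        warnings.warn("series too short for Grubbs despiking; returned unchanged")
        return x.copy(), []
    out = x.copy()
    n = out.size
    keep = np.ones(n, dtype=bool)
    spikes: list[int] = []
    # fixed-point iteration: replace the most extreme point, then re-test the
    # modified series; the output is idempotent under re-application
    while keep.sum() >= 3 and len(spikes) < n - 2:
        sd = out.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(out - out.mean())
        i = int(np.argmax(dev))
        if dev[i] / sd <= grubbs_critical_value(n, alpha):
            break
        keep[i] = False
        spikes.append(i)
        out[i] = out[keep].mean()
    return out, sorted(spikes)


def _despike_trend(series: np.ndarray, alpha: float, window: int = 11,
                   rel_floor: float = 0.5) -> tuple[np.ndarray, list[int]]:
    """Spike removal for trending series (transects).

    Grubbs on raw values would flag genuine trajectory structure, so spikes
    are detected on residuals from a running-median baseline and must also
    exceed a relative-magnitude floor (|residual| > rel_floor * |baseline|),
    which smooth noiseless trajectories never do. Flagged points are replaced
    by the local median.
    """
    x = np.asarray(series, dtype=float)
    if x.size < window:
        return despike_grubbs(x, alpha)
    # mirror padding: edge spikes must not dominate their own local median
    base = median_filter(x, size=window, mode="mirror")
    resid = x - base
    _, candidates = despike_grubbs(resid, alpha)
    spikes = [i for i in candidates
              if np.abs(resid[i]) > rel_floor * max(np.abs(base[i]), 1e-12)]
    out = x.copy()
    out[spikes] = base[spikes]
    return out, sorted(spikes)


# ---------------------------------------------------------------------------
# blanks and signal windows


def blank_statistics(blanks: list[AblationRecord], alpha: float = 0.05):
    """Per-mass mean and SD of pooled, despiked gas-blank series."""
    if not blanks:
        raise ValueError("need at least one gas blank")
    n_mass = len(blanks[0].masses)
    pooled = [[] for _ in range(n_mass)]
    for rec in blanks:
        for j in range(n_mass):
            clean, _ = despike_grubbs(rec.cps[:, j], alpha)
            pooled[j].append(clean)
    mean = np.array([np.concatenate(p).mean() for p in pooled])
    sd = np.array([np.concatenate(p).std(ddof=1) for p in pooled])
    return mean, sd


def _acquisition_rate(rec: AblationRecord) -> float:
    return 1.0 / float(np.median(np.diff(rec.time_s)))


def _signal_window(rec: AblationRecord, blank_mean: np.ndarray, blank_sd: np.ndarray,
                   config: MassConfig, thr: Thresholds, trim: bool) -> slice:
    """Contiguous plateau on the internal standard, optionally trimmed."""
    j = config.index(config.internal_standard)
    above = rec.cps[:, j] > blank_mean[j] + thr.plateau_sd_multiplier * blank_sd[j]
    best_len, best_start, cur_start = 0, 0, None
    for i, flag in enumerate(np.append(above, False)):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_len:
                best_len, best_start = i - cur_start, cur_start
            cur_start = None
    if best_len == 0:
        raise FailedAblationError(
            f"{rec.record_id}: internal-standard signal never exceeds blank threshold")
    start, stop = best_start, best_start + best_len
    if trim:
        n_trim = int(round(thr.plateau_trim_s * _acquisition_rate(rec)))
        start, stop = start + n_trim, stop - n_trim
    if stop - start < 5:
        raise FailedAblationError(f"{rec.record_id}: usable signal window too short")
    return slice(start, stop)


@dataclass(frozen=True)
class Integration:
    record_id: str
    net_cps: np.ndarray          # per-mass net mean cps (may be negative)
    window: slice
    blank_mean: np.ndarray
    blank_sd: np.ndarray
    spike_counts: np.ndarray


def integrate_signal(rec: AblationRecord, blank_before: AblationRecord,
                     blank_after: AblationRecord, config: MassConfig,
                     thr: Thresholds = Thresholds()) -> Integration:
    """Windowed, despiked, background-subtracted mean cps per mass (spots)."""
    blank_mean, blank_sd = blank_statistics([blank_before, blank_after], thr.grubbs_alpha)
    win = _signal_window(rec, blank_mean, blank_sd, config, thr, trim=rec.role != "transect")
    net = np.empty(len(rec.masses))
    spikes = np.zeros(len(rec.masses), dtype=int)
    for j in range(len(rec.masses)):
        clean, idx = despike_grubbs(rec.cps[win, j], thr.grubbs_alpha)
        net[j] = clean.mean() - blank_mean[j]
        spikes[j] = len(idx)
    return Integration(rec.record_id, net, win, blank_mean, blank_sd, spikes)


# ---------------------------------------------------------------------------
# calibration / drift


@dataclass
class CalibrationModel:
    """Per-mass sensitivity, drift factors and LODs for one acquisition run."""

    masses: tuple[str, ...]
    sensitivity: np.ndarray        # cps per ppm at the first standard bracket
    bracket_orders: np.ndarray     # mean acquisition order per standard bracket
    bracket_factors: np.ndarray    # (n_brackets, n_masses) relative sensitivity
    blank_mean: np.ndarray         # pooled gas blanks, cps
    blank_sd: np.ndarray
    lod_multiplier: float
    uncalibratable: tuple[str, ...] = ()

    def drift_factor(self, order: float) -> np.ndarray:
        """Per-mass relative sensitivity at an acquisition order.

        Linear interpolation between bracketing standards; constant
        extrapolation outside the bracketed range.
        """
        return np.array([
            np.interp(order, self.bracket_orders, self.bracket_factors[:, j])
            for j in range(len(self.masses))
        ])

    def lod_ppm(self, order: float) -> np.ndarray:
        """LOD per mass: lod_multiplier * blank SD converted to ppm."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = self.lod_multiplier * self.blank_sd / (
                self.sensitivity * self.drift_factor(order))
        return np.where(np.isfinite(lod), lod, np.inf)


def _group_brackets(records: list[AblationRecord], max_gap: int = 4) -> list[list[AblationRecord]]:
    groups: list[list[AblationRecord]] = []
    for rec in sorted(records, key=lambda r: r.order):
        if groups and rec.order - groups[-1][-1].order <= max_gap:
            groups[-1].append(rec)
        else:
            groups.append([rec])
    return groups


def build_drift_model(run: RunSequence, config: MassConfig,
                      thr: Thresholds = Thresholds()) -> CalibrationModel:
    """Calibration model from the NIST-612 brackets and pooled gas blanks."""
    standards = run.of_role("nist612")
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration-standard ablations")
    std_ppm = np.array([config[m].nist612_ppm for m in run.masses])
    brackets = _group_brackets(standards)
    net_rows, orders = [], []
    for group in brackets:
        nets = []
        for rec in group:
            b0, b1 = run.bracketing_blanks(rec)
            nets.append(integrate_signal(rec, b0, b1, config, thr).net_cps)
        net_rows.append(np.mean(nets, axis=0))
        orders.append(np.mean([r.order for r in group]))
    net = np.vstack(net_rows)
    orders = np.array(orders)
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = net[0] / std_ppm
        factors = net / net[0]
    bad = [m for j, m in enumerate(run.masses) if not (net[:, j] > 0).all()]
    for j, m in enumerate(run.masses):
        if m in bad:
            sens[j] = np.nan
            factors[:, j] = 1.0
    blank_mean, blank_sd = blank_statistics(run.of_role("gas_blank"), thr.grubbs_alpha)
    return CalibrationModel(
        masses=run.masses, sensitivity=sens, bracket_orders=orders,
        bracket_factors=factors, blank_mean=blank_mean, blank_sd=blank_sd,
        lod_multiplier=thr.lod_sd_multiplier, uncalibratable=tuple(bad),
    )


# ---------------------------------------------------------------------------
# spot quantification


def _calibrate_net(net_cps: np.ndarray, order: float, model: CalibrationModel,
                   config: MassConfig):
    """Drift-corrected net cps -> (raw ppm, Ca-normalized ppm, element:Ca)."""
    corrected = net_cps / model.drift_factor(order)
    with np.errstate(divide="ignore", invalid="ignore"):
        ppm_raw = corrected / model.sensitivity
    j_ca = config.index(config.internal_standard)
    ca_scale = config.internal_standard_ppm / ppm_raw[j_ca]
    ppm = ppm_raw * ca_scale
    # element:Ca (umol/mol): sample cps ratio over reference-bracket standard
    # cps ratio, times the standard's molar element:Ca ratio
    masses_amu = np.array([config[m].atomic_mass for m in config.labels])
    std_ppm = np.array([config[m].nist612_ppm for m in config.labels])
    std_net_ref = model.sensitivity * std_ppm  # reference-bracket standard net cps
    sample_ratio = corrected / corrected[j_ca]
    std_ratio = std_net_ref / std_net_ref[j_ca]
    std_molar = (std_ppm / masses_amu) / (std_ppm[j_ca] / masses_amu[j_ca])
    ratio = sample_ratio / std_ratio * std_molar * 1e6
    return ppm, ratio


@dataclass
class ElementSignature:
    """Per-sample mean element:Ca signature with QC bookkeeping."""

    specimen_id: str
    target: str
    elements: tuple[str, ...]
    mean_ppm: np.ndarray
    ratio_umol_mol: np.ndarray
    below_lod: np.ndarray
    replicates_used: tuple[str, ...]
    replicates_excluded: tuple[tuple[str, float], ...] = ()
    missing: bool = False


def quantify_spot(records: list[AblationRecord], run: RunSequence,
                  model: CalibrationModel, config: MassConfig,
                  thr: Thresholds = Thresholds(),
                  exclude: dict | None = None) -> ElementSignature:
    """Average calibrated replicate spot scans into one element signature.

    ``exclude`` maps record id -> outlyingness for replicates already flagged
    by :func:`detect_outlier_replicates`; with all replicates excluded the
    signature is returned marked missing.
    """
    if not records:
        raise ValueError("no replicate records given")
    sid = {r.specimen_id for r in records}
    tgt = {r.target for r in records}
    if len(sid) != 1 or len(tgt) != 1:
        raise ValueError("replicates must share specimen and target")
    exclude = exclude or {}
    ppm_rows, ratio_rows, lod_rows, used, dropped = [], [], [], [], []
    for rec in records:
        if rec.record_id in exclude:
            dropped.append((rec.record_id, float(exclude[rec.record_id])))
            continue
        b0, b1 = run.bracketing_blanks(rec)
        integ = integrate_signal(rec, b0, b1, config, thr)
        ppm, ratio = _calibrate_net(integ.net_cps, rec.order, model, config)
        ppm_rows.append(ppm)
        ratio_rows.append(ratio)
        lod_rows.append(ppm < model.lod_ppm(rec.order))
        used.append(rec.record_id)
    if not ppm_rows:
        n = len(config.labels)
        return ElementSignature(
            specimen_id=sid.pop(), target=tgt.pop(), elements=config.labels,
            mean_ppm=np.full(n, np.nan), ratio_umol_mol=np.full(n, np.nan),
            below_lod=np.ones(n, dtype=bool), replicates_used=(),
            replicates_excluded=tuple(dropped), missing=True,
        )
    return ElementSignature(
        specimen_id=sid.pop(), target=tgt.pop(), elements=config.labels,
        mean_ppm=np.mean(ppm_rows, axis=0),
        ratio_umol_mol=np.mean(ratio_rows, axis=0),
        below_lod=np.mean(lod_rows, axis=0) >= 0.5,
        replicates_used=tuple(used), replicates_excluded=tuple(dropped),
    )


def filter_by_lod(below_lod: pd.DataFrame, threshold_fraction: float = 0.10,
                  protect: tuple[str, ...] = ()) -> tuple[list[str], pd.Series]:
    """Element retention by the below-LOD fraction rule.

    ``below_lod`` is a boolean table (one row per measurement, one column per
    element). Elements whose below-LOD fraction is >= ``threshold_fraction``
    (boundary inclusive) are dropped; ``protect`` lists elements never
    dropped (the internal standard). Returns the retained element list and
    the per-element fractions.
    """
    fractions = below_lod.mean(axis=0)
    retained = [el for el in below_lod.columns
                if el in protect or fractions[el] < threshold_fraction]
    if not retained:
        raise ValueError("all elements fall below the LOD retention rule")
    return retained, fractions


def detect_outlier_replicates(X, cutoff: float = 10.0, n_projections: int = 1000,
                              seed: int = 0) -> tuple[np.ndarray, list[int]]:
    """Stahel-Donoho outlyingness of replicate concentration vectors.

    Outlyingness of row i is the max over K seeded random unit projections u
    of |x_i.u - median(X.u)| / MAD(X.u) with the normalized MAD (x1.4826).
    Columns are robust-standardized (median/MAD) before projecting so the
    measure is not dominated by high-concentration elements; constant
    columns carry no information and are dropped, while a zero-MAD column
    with deviating points keeps those deviations at full weight. Rows above
    ``cutoff`` are flagged for exclusion. Projections with zero MAD are
    skipped; if every projection is degenerate the outlyingness is undefined
    and nothing is excluded (with a warning).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2-D replicate-by-element matrix")
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 pooled replicate vectors")
    col_med = np.median(X, axis=0)
    col_mad = 1.4826 * np.median(np.abs(X - col_med), axis=0)
    centered = X - col_med
    constant = np.ptp(X, axis=0) == 0
    scale = col_mad.copy()
    for j in np.where((col_mad == 0) & ~constant)[0]:
        nz = np.abs(centered[:, j])
        scale[j] = nz[nz > 0].min()  # MAD breakdown: keep deviations visible
    keep_cols = ~constant
    if not keep_cols.any():
        return np.zeros(n), []
    X = centered[:, keep_cols] / scale[keep_cols]
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((n_projections, p))
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    proj = X @ U.T                                    # (n, K)
    med = np.median(proj, axis=0)
    mad = 1.4826 * np.median(np.abs(proj - med), axis=0)
    ok = mad > 0
    if not ok.any():
        warnings.warn("all projections degenerate; outlyingness undefined")
        return np.full(n, np.nan), []
    scores = np.abs(proj[:, ok] - med[ok]) / mad[ok]
    out = scores.max(axis=1)
    return out, [int(i) for i in np.where(out > cutoff)[0]]


# ---------------------------------------------------------------------------
# transects


@dataclass
class TransectProfile:
    """Distance-resolved transect: net cps and calibrated ppm per mass."""

    specimen_id: str
    distance_um: np.ndarray       # 0 at the vertebral focus, strictly increasing
    masses: tuple[str, ...]
    net_cps: np.ndarray           # (n_points, n_masses), drift-corrected
    ppm: np.ndarray               # (n_points, n_masses), Ca-normalized
    resampled: bool = False

    @property
    def n_points(self) -> int:
        return len(self.distance_um)

    def column(self, mass: str, which: str = "ppm") -> np.ndarray:
        j = self.masses.index(mass)
        return (self.ppm if which == "ppm" else self.net_cps)[:, j]


def reduce_transect(rec: AblationRecord, run: RunSequence, model: CalibrationModel,
                    config: MassConfig, thr: Thresholds = Thresholds()) -> TransectProfile:
    """Reduce one transect record to a distance-resolved elemental profile."""
    if rec.role != "transect":
        raise ValueError(f"{rec.record_id}: not a transect record")
    if rec.scan_speed_um_s is None:
        raise ValueError(f"{rec.record_id}: transect lacks scan geometry")
    b0, b1 = run.bracketing_blanks(rec)
    blank_mean, blank_sd = blank_statistics([b0, b1], thr.grubbs_alpha)
    win = _signal_window(rec, blank_mean, blank_sd, config, thr, trim=False)
    # guard against stray baseline points joining the window (a spiked blank
    # point adjacent to the scan can pass the plateau threshold): trim edge
    # points whose ablation yield on the internal standard is well below par
    j_ca = config.index(config.internal_standard)
    ca_raw = rec.cps[win, j_ca] - blank_mean[j_ca]
    good = ca_raw > 0.5 * np.median(ca_raw)
    if not good.any():
        raise FailedAblationError(f"{rec.record_id}: no usable ablation yield")
    start = int(np.argmax(good))
    stop = len(ca_raw) - int(np.argmax(good[::-1]))
    win = slice(win.start + start, win.start + stop)
    n_pts = win.stop - win.start
    drift = model.drift_factor(rec.order)
    net = np.empty((n_pts, len(rec.masses)))
    for j in range(len(rec.masses)):
        clean, _ = _despike_trend(rec.cps[win, j], thr.grubbs_alpha,
                                  window=thr.smoothing_window)
        net[:, j] = (clean - blank_mean[j]) / drift[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        ppm_raw = net / model.sensitivity
    j_ca = config.index(config.internal_standard)
    ppm = ppm_raw * (config.internal_standard_ppm / ppm_raw[:, [j_ca]])
    t = rec.time_s[win]
    distance = rec.scan_speed_um_s * (t - t[0])
    if not rec.scan_from_focus:
        net, ppm = net[::-1], ppm[::-1]
        distance = distance[-1] - distance[::-1]
    return TransectProfile(
        specimen_id=rec.specimen_id or rec.record_id, distance_um=distance,
        masses=rec.masses, net_cps=net, ppm=ppm,
    )


def resample_transects(profiles: list[TransectProfile],
                       elements: list[str] | None = None):
    """Resample profiles onto the index grid of the longest one.

    Returns (resampled profiles, feature matrix, per-element means). The
    feature matrix concatenates, per retained element, the resampled ppm
    sequence of each profile (one row per specimen); the means table holds
    the per-element transect mean (the integrated alternative).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to resample")
    for p in profiles:
        if p.n_points < 2:
            raise ValueError(f"{p.specimen_id}: profile has fewer than 2 points")
    elements = list(elements or profiles[0].masses)
    n_max = max(p.n_points for p in profiles)
    grid = np.linspace(0.0, 1.0, n_max)
    out_profiles, feat_rows, mean_rows = [], [], []
    for p in profiles:
        x_rel = np.linspace(0.0, 1.0, p.n_points)
        net_r = np.column_stack([np.interp(grid, x_rel, p.net_cps[:, j])
                                 for j in range(len(p.masses))])
        ppm_r = np.column_stack([np.interp(grid, x_rel, p.ppm[:, j])
                                 for j in range(len(p.masses))])
        dist_r = np.interp(grid, x_rel, p.distance_um)
        out_profiles.append(TransectProfile(
            specimen_id=p.specimen_id, distance_um=dist_r, masses=p.masses,
            net_cps=net_r, ppm=ppm_r, resampled=True))
        feat_rows.append(np.concatenate([ppm_r[:, p.masses.index(el)] for el in elements]))
        mean_rows.append([ppm_r[:, p.masses.index(el)].mean() for el in elements])
    ids = [p.specimen_id for p in profiles]
    features = pd.DataFrame(np.vstack(feat_rows), index=ids)
    means = pd.DataFrame(mean_rows, index=ids, columns=elements)
    return out_profiles, features, means


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ReductionResult:
    signatures: list[ElementSignature]
    profiles: list[TransectProfile]
    retained_elements: list[str]
    model: CalibrationModel
    qc: dict = field(default_factory=dict)


def reduce_run(run: RunSequence, config: MassConfig,
               thr: Thresholds = Thresholds(), seed: int = 0) -> ReductionResult:
    """Full reduction of a run: calibration, spot signatures, transect profiles."""
    model = build_drift_model(run, config, thr)
    spots = run.of_role("spot")
    failed: list[str] = []

    # per-replicate calibrated vectors for LOD screening + outlyingness
    rep_ids, rep_ppm, rep_lod = [], [], []
    for rec in spots:
        b0, b1 = run.bracketing_blanks(rec)
        try:
            integ = integrate_signal(rec, b0, b1, config, thr)
        except FailedAblationError:
            failed.append(rec.record_id)
            continue
        ppm, _ = _calibrate_net(integ.net_cps, rec.order, model, config)
        rep_ids.append(rec.record_id)
        rep_ppm.append(ppm)
        rep_lod.append(ppm < model.lod_ppm(rec.order))

    retained = list(config.labels)
    fractions = pd.Series(dtype=float)
    exclude: dict[str, float] = {}
    if rep_ids:
        lod_table = pd.DataFrame(rep_lod, index=rep_ids, columns=config.labels)
        candidates = [m for m in config.labels if m not in model.uncalibratable]
        retained, fractions = filter_by_lod(
            lod_table[candidates], thr.lod_fraction, protect=(config.internal_standard,))
        # replicate screening pooled per analysis set (focus spots vs edge spots)
        cols = [config.index(el) for el in retained
                if el != config.internal_standard]
        target_of = {rec.record_id: rec.target for rec in spots}
        for target in sorted({t for t in target_of.values() if t}):
            sel = [i for i, rid in enumerate(rep_ids) if target_of[rid] == target]
            if len(sel) < 5:
                continue
            X = np.vstack([rep_ppm[i] for i in sel])[:, cols]
            out, flagged = detect_outlier_replicates(
                X, thr.outlyingness_cutoff, thr.outlyingness_projections, seed)
            exclude.update({rep_ids[sel[i]]: out[i] for i in flagged})

    signatures = []
    groups: dict[tuple[str, str], list[AblationRecord]] = {}
    for rec in spots:
        if rec.record_id in failed:
            continue
        groups.setdefault((rec.specimen_id, rec.target), []).append(rec)
    for (sid, target), recs in groups.items():
        signatures.append(quantify_spot(recs, run, model, config, thr, exclude))

    profiles = []
    for rec in run.of_role("transect"):
        try:
            profiles.append(reduce_transect(rec, run, model, config, thr))
        except FailedAblationError:
            failed.append(rec.record_id)

    qc = {
        "failed_records": failed,
        "excluded_replicates": exclude,
        "below_lod_fraction": fractions.to_dict() if len(fractions) else {},
        "uncalibratable": list(model.uncalibratable),
        "n_standard_brackets": len(model.bracket_orders),
    }
    return ReductionResult(signatures=signatures, profiles=profiles,
                           retained_elements=list(retained), model=model, qc=qc)
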