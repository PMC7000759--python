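"""Signal reduction: despiking, calibration, LOD, outlyingness, round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import t as t_dist

import vertchem as vc
from vertchem.records import AblationRecord
from vertchem.reduction import (_calibrate_net, despike_grubbs,
                                detect_outlier_replicates, filter_by_lod,
                                grubbs_critical_value, integrate_signal,
                                resample_transects)
from vertchem.synthetic import NoiseParams


# ---------------------------------------------------------------------------
# Grubbs despiking


def hand_grubbs_crit(n, alpha):
    """Independent closed-form oracle for the two-sided critical value."""
    tv = t_dist.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(tv**2 / (n - 2 + tv**2))


def test_grubbs_hand_case_rejects_spike():
    # [10,10,10,10,100]: G = (100-28)/sd; sd = sqrt(sum((x-28)^2)/4)
    x = np.array([10.0, 10, 10, 10, 100])
    sd = x.std(ddof=1)
    g = (100 - x.mean()) / sd
    assert g == pytest.approx(1.7889, abs=1e-4)
    assert hand_grubbs_crit(5, 0.05) == pytest.approx(1.715, abs=1e-3)
    clean, spikes = despike_grubbs(x, alpha=0.05)
    assert spikes == [4]
    assert np.allclose(clean, 10.0)


def test_grubbs_borderline_matches_closed_form_decision():
    x = np.array([10.0, 10, 10, 10, 40])
    g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
    should_reject = g > hand_grubbs_crit(5, 0.05)
    _, spikes = despike_grubbs(x, alpha=0.05)
    assert (len(spikes) > 0) == should_reject


def test_grubbs_constant_series_unchanged():
    x = np.full(5, 10.0)
    clean, spikes = despike_grubbs(x)
    assert spikes == []
    assert np.array_equal(clean, x)


def test_grubbs_short_series_warns():
    with pytest.warns(UserWarning):
        clean, spikes = despike_grubbs([1.0, 2.0])
    assert spikes == []


@given(st.integers(0, 500))
def test_grubbs_idempotent(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(100, 5, 50)
    x[rng.integers(0, 50, 2)] *= 10
    once, _ = despike_grubbs(x)
    twice, again = despike_grubbs(once)
    assert np.allclose(once, twice)


def test_grubbs_critical_value_decreasing_alpha():
    assert grubbs_critical_value(20, 0.01) > grubbs_critical_value(20, 0.05)


# ---------------------------------------------------------------------------
# integration / windows


def _flat_record(mass_config, level, record_id="r", role="spot", n=200, rate=5.0):
    """Record with constant cps = level per mass (level: scalar or vector)."""
    cps = np.broadcast_to(np.asarray(level, float),
                          (n, len(mass_config.labels))).copy()
    return AblationRecord(record_id=record_id, role=role,
                          time_s=np.arange(n) / rate, cps=cps,
                          masses=mass_config.labels, order=1)


def test_integrate_blank_equal_record_gives_zero_net(mass_config):
    blank_level = np.array([mass_config[m].blank_mean_cps for m in mass_config.labels])
    blank = _flat_record(mass_config, blank_level, "b", "gas_blank")
    # plateau detectable on the internal standard only
    level = blank_level.copy()
    level[mass_config.index("Ca43")] += 1e6
    rec = _flat_record(mass_config, level, "s", "spot")
    blank2 = _flat_record(mass_config, blank_level, "b2", "gas_blank")
    integ = integrate_signal(rec, blank, blank2, mass_config)
    for j, m in enumerate(mass_config.labels):
        if m != "Ca43":
            assert integ.net_cps[j] == pytest.approx(0.0, abs=1e-9)


def test_integrate_subtraction_oracle(mass_config):
    # blank 200 cps, plateau 1200 cps -> net 1000 on every mass
    blank = _flat_record(mass_config, 200.0, "b", "gas_blank")
    blank2 = _flat_record(mass_config, 200.0, "b2", "gas_blank")
    rec = _flat_record(mass_config, 1200.0, "s", "spot")
    integ = integrate_signal(rec, blank, blank2, mass_config)
    assert np.allclose(integ.net_cps, 1000.0)


def test_integrate_fails_without_plateau(mass_config):
    blank = _flat_record(mass_config, 200.0, "b", "gas_blank")
    blank2 = _flat_record(mass_config, 200.0, "b2", "gas_blank")
    rec = _flat_record(mass_config, 199.0, "s", "spot")  # never above the blank
    with pytest.raises(vc.FailedAblationError):
        integrate_signal(rec, blank, blank2, mass_config)


# ---------------------------------------------------------------------------
# drift model and LOD


def test_drift_model_flat_standards_unit_factors(mass_config):
    # identical standard cps at every bracket -> drift factor identically 1
    blank_level = np.array([mass_config[m].blank_mean_cps
                            for m in mass_config.labels])
    std_level = blank_level + 1000.0
    records = []
    order = 0
    for k in range(3):
        records.append(_flat_record(mass_config, blank_level, f"b{k}",
                                    "gas_blank"))
        records[-1].order = order
        order += 1
        records.append(_flat_record(mass_config, std_level, f"n{k}", "nist612"))
        records[-1].order = order
        order += 20  # separate brackets
    records.append(_flat_record(mass_config, blank_level, "bz", "gas_blank"))
    records[-1].order = order
    run = vc.RunSequence(records=records, masses=mass_config.labels)
    model = vc.build_drift_model(run, mass_config)
    assert np.allclose(model.bracket_factors, 1.0)
    assert np.allclose(model.drift_factor(order / 2), 1.0)


def test_drift_factor_linear_interpolation_oracle(mass_config):
    model = vc.CalibrationModel(
        masses=("A", "B"), sensitivity=np.array([10.0, 10.0]),
        bracket_orders=np.array([0.0, 10.0]),
        bracket_factors=np.array([[1.0, 1.0], [1.1, 1.2]]),
        blank_mean=np.zeros(2), blank_sd=np.ones(2), lod_multiplier=3.0)
    f = model.drift_factor(5.0)
    assert f[0] == pytest.approx(1.05, abs=1e-12)
    assert f[1] == pytest.approx(1.10, abs=1e-12)
    # constant extrapolation outside the bracketed range
    assert np.allclose(model.drift_factor(-5.0), [1.0, 1.0])
    assert np.allclose(model.drift_factor(99.0), [1.1, 1.2])


def test_lod_from_blank_sd_oracle():
    # blank SD 100 cps, sensitivity*drift 50 cps/ppm -> LOD = 3*100/50 = 6 ppm
    model = vc.CalibrationModel(
        masses=("A",), sensitivity=np.array([50.0]),
        bracket_orders=np.array([0.0, 1.0]),
        bracket_factors=np.array([[1.0], [1.0]]),
        blank_mean=np.zeros(1), blank_sd=np.array([100.0]), lod_multiplier=3.0)
    assert model.lod_ppm(0.5)[0] == pytest.approx(6.0, abs=1e-12)


def test_lod_monotone_in_blank_sd():
    def lod(sd):
        m = vc.CalibrationModel(
            masses=("A",), sensitivity=np.array([50.0]),
            bracket_orders=np.array([0.0, 1.0]),
            bracket_factors=np.array([[1.0], [1.0]]),
            blank_mean=np.zeros(1), blank_sd=np.array([sd]), lod_multiplier=3.0)
        return m.lod_ppm(0.5)[0]
    sds = [1.0, 10.0, 100.0, 1000.0]
    vals = [lod(s) for s in sds]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_drift_correction_undoes_synthetic_linear_drift(noiseless_study,
                                                        mass_config,
                                                        noiseless_reduction):
    # corrected per-bracket standard net cps is constant across the run
    from vertchem.reduction import _group_brackets
    run, _, truth = noiseless_study
    model = noiseless_reduction.model
    ref = model.sensitivity * np.array(
        [mass_config[m].nist612_ppm for m in mass_config.labels])
    for bracket in _group_brackets(run.of_role("nist612")):
        nets = []
        for rec in bracket:
            b0, b1 = run.bracketing_blanks(rec)
            nets.append(integrate_signal(rec, b0, b1, mass_config).net_cps)
        order = np.mean([r.order for r in bracket])
        corrected = np.mean(nets, axis=0) / model.drift_factor(order)
        assert np.allclose(corrected, ref, rtol=1e-9)


# ---------------------------------------------------------------------------
# quantification


def test_ratio_identity_when_sample_matches_standard(mass_config, noiseless_reduction):
    # a sample with the standard's cps ratios returns the standard's molar ratio
    model = noiseless_reduction.model
    std_net = model.sensitivity * np.array(
        [mass_config[m].nist612_ppm for m in mass_config.labels])
    _, ratio = _calibrate_net(std_net, float(model.bracket_orders[0]),
                              model, mass_config)
    for j, m in enumerate(mass_config.labels):
        iso, ca = mass_config[m], mass_config["Ca43"]
        expect = (iso.nist612_ppm / iso.atomic_mass) / (
            ca.nist612_ppm / ca.atomic_mass) * 1e6
        assert ratio[j] == pytest.approx(expect, rel=1e-9)


def test_ratio_closed_form_half_standard(mass_config, noiseless_reduction):
    # halving one element's cps ratio halves its element:Ca ratio
    model = noiseless_reduction.model
    std_net = model.sensitivity * np.array(
        [mass_config[m].nist612_ppm for m in mass_config.labels])
    halved = std_net.copy()
    j_sr = mass_config.index("Sr88")
    halved[j_sr] *= 0.5
    _, ratio_full = _calibrate_net(std_net, float(model.bracket_orders[0]),
                                   model, mass_config)
    _, ratio_half = _calibrate_net(halved, float(model.bracket_orders[0]),
                                   model, mass_config)
    assert ratio_half[j_sr] == pytest.approx(0.5 * ratio_full[j_sr], rel=1e-12)


def test_internal_standard_identity(noiseless_reduction, mass_config):
    j_ca = mass_config.index("Ca43")
    for sig in noiseless_reduction.signatures:
        if not sig.missing:
            assert sig.ratio_umol_mol[j_ca] == pytest.approx(1e6, rel=1e-9)


def test_full_chain_noiseless_recovery(noiseless_study, noiseless_reduction,
                                       mass_config):
    """Element:Ca ratios equal synthetic truth to 1e-6 relative (noiseless)."""
    _, _, truth = noiseless_study
    amu = np.array([mass_config[m].atomic_mass for m in mass_config.labels])
    j_ca = mass_config.index("Ca43")
    checked = 0
    for sig in noiseless_reduction.signatures:
        assert not sig.missing
        tp = truth.record_ppm[f"{sig.specimen_id}-{sig.target}-r1"]
        expect = (tp / amu) / (tp[j_ca] / amu[j_ca]) * 1e6
        assert np.allclose(sig.ratio_umol_mol, expect, rtol=1e-6)
        assert np.allclose(sig.mean_ppm, tp, rtol=1e-6)
        checked += 1
    assert checked == 32  # 14 embryos x 2 targets + 4 females


def test_full_chain_noisy_rmse_under_5_percent(noisy_study, noisy_reduction,
                                               mass_config):
    _, _, truth = noisy_study
    errs = []
    for sig in noisy_reduction.signatures:
        if sig.missing:
            continue
        reps = [truth.record_ppm[f"{sig.specimen_id}-{sig.target}-r{k}"]
                for k in (1, 2, 3)]
        tp = np.mean(reps, axis=0)
        for el in noisy_reduction.retained_elements:
            j = mass_config.index(el)
            errs.append(sig.mean_ppm[j] / tp[j] - 1)
    errs = np.asarray(errs)
    assert len(errs) >= 30 * len(noisy_reduction.retained_elements) * 0.9
    assert np.sqrt((errs**2).mean()) < 0.05


# ---------------------------------------------------------------------------
# LOD rule and outlyingness


def test_filter_by_lod_rule():
    def table(n_below, n_total):
        flags = [True] * n_below + [False] * (n_total - n_below)
        return pd.DataFrame({"El": flags})

    retained, _ = filter_by_lod(table(0, 28))
    assert retained == ["El"]
    retained, frac = filter_by_lod(pd.DataFrame({
        "Keep": [False] * 14, "Drop": [True] * 6 + [False] * 8}))
    assert retained == ["Keep"] and frac["Drop"] == pytest.approx(6 / 14)
    # boundary inclusive: exactly 10% below LOD is dropped
    with pytest.raises(ValueError):
        filter_by_lod(pd.DataFrame({"El": [True] + [False] * 9}))


def test_filter_by_lod_protects_internal_standard():
    tbl = pd.DataFrame({"Ca43": [True] * 5, "Sr88": [False] * 5})
    retained, _ = filter_by_lod(tbl, protect=("Ca43",))
    assert set(retained) == {"Ca43", "Sr88"}


def test_lod_rule_drops_trace_elements_in_noisy_run(noisy_reduction):
    # generator concentrations for these elements sit below the 3*SD LOD
    dropped = set(vc.default_mass_config().labels) - set(
        noisy_reduction.retained_elements)
    assert {"Sc45", "V51", "Cr53", "Ge72", "Au197", "Th232", "U238"} <= dropped
    assert {"Sr88", "Ba137", "Pb208", "Ca43"}.isdisjoint(dropped)


def test_outlyingness_identical_replicates_zero():
    X = np.ones((6, 4))
    out, excluded = detect_outlier_replicates(X)
    assert np.allclose(out, 0.0)
    assert excluded == []


def test_outlyingness_displaced_replicate_excluded():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (10, 5))
    mad = 1.4826 * np.median(np.abs(X[:, 2] - np.median(X[:, 2])))
    X[3, 2] += 50 * mad
    out, excluded = detect_outlier_replicates(X, cutoff=10)
    assert 3 in excluded
    assert out[3] > 10


def test_outlyingness_infinite_cutoff_excludes_nothing():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (8, 3))
    X[0] += 100
    _, excluded = detect_outlier_replicates(X, cutoff=np.inf)
    assert excluded == []


def test_outlyingness_needs_five_rows():
    with pytest.raises(ValueError):
        detect_outlier_replicates(np.ones((4, 3)))


# ---------------------------------------------------------------------------
# transects


def test_transect_distance_span(noiseless_study, noiseless_reduction):
    # scan at 10 um/s: distance = speed * time from scan start
    run, _, truth = noiseless_study
    for prof in noiseless_reduction.profiles:
        rec = run[f"{prof.specimen_id}-transect"]
        expected_span = rec.scan_length_um
        assert prof.distance_um[0] == 0.0
        assert prof.distance_um[-1] == pytest.approx(expected_span, abs=2.1)
        assert np.all(np.diff(prof.distance_um) > 0)


def test_transect_noiseless_roundtrip(noiseless_study, noiseless_reduction):
    _, _, truth = noiseless_study
    for prof in noiseless_reduction.profiles:
        tp = truth.record_ppm[f"{prof.specimen_id}-transect"]
        assert prof.ppm.shape == tp.shape
        assert np.allclose(prof.ppm, tp, rtol=1e-6)


def test_transect_reversal_restores_focus_origin(noiseless_study, mass_config,
                                                 noiseless_reduction):
    run, _, _ = noiseless_study
    rec = run["Y1-transect"]
    flipped = AblationRecord(
        record_id="Y1r", role="transect", time_s=rec.time_s,
        cps=rec.cps[::-1].copy(), masses=rec.masses, order=rec.order,
        specimen_id="Y1", target="transect",
        scan_speed_um_s=rec.scan_speed_um_s, scan_length_um=rec.scan_length_um,
        scan_from_focus=False)
    model = noiseless_reduction.model
    orig = [p for p in noiseless_reduction.profiles if p.specimen_id == "Y1"][0]
    rev = vc.reduce_transect(flipped, run, model, mass_config)
    assert np.allclose(rev.ppm, orig.ppm, rtol=1e-9)


def test_resample_linear_interpolation_oracle():
    def prof(sid, values):
        values = np.asarray(values, float)[:, None]
        return vc.TransectProfile(
            specimen_id=sid, distance_um=np.arange(len(values)) * 10.0,
            masses=("A",), net_cps=values, ppm=values)

    out, features, means = resample_transects(
        [prof("a", [0, 10, 20]), prof("b", [0, 1, 2, 3, 4])], ["A"])
    assert np.allclose(out[0].ppm[:, 0], [0, 5, 10, 15, 20])
    assert features.shape == (2, 5)
    assert means.loc["a", "A"] == pytest.approx(10.0)


def test_resample_equal_lengths_unchanged():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(2, 7))

    def prof(sid, v):
        v = v[:, None]
        return vc.TransectProfile(specimen_id=sid,
                                  distance_um=np.arange(7.0), masses=("A",),
                                  net_cps=v, ppm=v)

    out, _, _ = resample_transects([prof("a", vals[0]), prof("b", vals[1])])
    assert np.allclose(out[0].ppm[:, 0], vals[0])
    assert np.allclose(out[1].ppm[:, 0], vals[1])


def test_resample_feature_matrix_shape():
    rng = np.random.default_rng(3)
    profs = []
    for i, n in enumerate([120, 150, 200, 180]):
        v = rng.normal(size=(n, 12))
        profs.append(vc.TransectProfile(
            specimen_id=f"s{i}", distance_um=np.arange(n, dtype=float),
            masses=tuple(f"m{j}" for j in range(12)), net_cps=v, ppm=v))
    _, features, _ = resample_transects(profs, [f"m{j}" for j in range(12)])
    assert features.shape == (4, 12 * 200)


def test_resample_requires_two_profiles():
    with pytest.raises(ValueError):
        resample_transects([])
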