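"""GAW parameter families: hand-derived perturbation values, quotient
conventions, spectral noise measure, symmetry parameters, and the full
registry evaluation."""

import dataclasses

import numpy as np
import pytest

from phonovib.cycles import CycleSet, detect_cycles
from phonovib.features import (CycleSeries, compute_feature_vector,
                               cycle_series, perturbation_features,
                               quotients, snr_k, symmetry_features)
from phonovib.registry import REGISTRY, HSV2_PARAMETERS
from phonovib.synth import GlottalRecording, RecordingSpec, \
    generate_recording


def make_series(periods_s=None, amplitudes=None, n=14, **kw):
    """CycleSeries with directly specified period/amplitude series."""
    if periods_s is None:
        periods_s = np.full(n, 0.01)
    periods_s = np.asarray(periods_s, dtype=float)
    n = periods_s.size
    if amplitudes is None:
        amplitudes = np.ones(n)
    defaults = dict(
        fs=4000.0, period_s=periods_s, amplitude=np.asarray(amplitudes,
                                                            dtype=float),
        energy=np.ones(n), dyn_range=np.ones(n),
        opening=np.full(n, 10.0), plateau=np.full(n, 5.0),
        closing=np.full(n, 10.0), open_frac=np.full(n, 0.6),
        peak_instant=np.arange(n, dtype=float))
    defaults.update(kw)
    return CycleSeries(**defaults)


class TestPerturbationFeatures:
    def test_periodic_series_has_zero_perturbation(self):
        pf = perturbation_features(make_series())
        for key in ("Jit(%)", "PPQ3", "PPQ5", "PPQ11", "MShim", "APQ3",
                    "Shim(%)", "PPF"):
            assert pf[key] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_periods_give_hand_computed_jitter(self):
        # Periods alternate 40 and 42 frames at 4000 Hz:
        # Jit(%) = 100 * 2 / 41 = 4.878...
        periods = np.tile([40.0, 42.0], 7) / 4000.0
        pf = perturbation_features(make_series(periods_s=periods))
        assert pf["Jit(%)"] == pytest.approx(100.0 * 2.0 / 41.0, rel=1e-12)
        assert pf["RAP_K"] == pf["PPQ3"]

    def test_alternating_amplitudes_give_hand_computed_shimmer(self):
        amps = np.tile([1.0, 1.1], 7)
        pf = perturbation_features(make_series(amplitudes=amps))
        assert pf["MShim"] == pytest.approx(20.0 * np.log10(1.1), rel=1e-12)

    def test_eleven_point_quotients_need_twelve_cycles(self):
        with pytest.warns(UserWarning):
            pf = perturbation_features(make_series(n=8))
        assert np.isnan(pf["PPQ11"])
        assert np.isfinite(pf["PPQ5"])
        assert np.isfinite(pf["Jit(%)"])

    def test_relative_measures_are_scale_invariant(self, perturbed_recording):
        rec = perturbed_recording
        vec = compute_feature_vector(rec, include_pvg=False)
        scaled = GlottalRecording(
            disp_left=3.7 * rec.disp_left, disp_right=3.7 * rec.disp_right,
            gaw_left=3.7 * rec.gaw_left, gaw_right=3.7 * rec.gaw_right,
            gaw_total=3.7 * rec.gaw_total, fs=rec.fs, truth=rec.truth)
        vec_s = compute_feature_vector(scaled, include_pvg=False)
        for entry in REGISTRY.entries:
            if entry.family == "pvg" or not entry.scale_invariant:
                continue
            a, b = vec[entry.abbreviation], vec_s[entry.abbreviation]
            if np.isfinite(a):
                assert b == pytest.approx(a, rel=1e-9, abs=1e-9), \
                    entry.abbreviation

    def test_perturbation_measures_nonnegative(self, perturbed_recording):
        vec = compute_feature_vector(perturbed_recording, include_pvg=False)
        for key in ("Jit(%)", "PPQ3", "PPQ5", "PPQ11", "APQ3", "APQ5",
                    "APQ11", "MShim", "PhAI [Mean]"):
            assert vec[key] >= 0
        assert -0.5 < vec["PhA [Mean]"] <= 0.5
        assert 0 <= vec["AmSI [Mean]"] <= 1


class TestQuotients:
    def test_symmetric_pulses_have_unit_speed_quotient(self):
        q = quotients(make_series(opening=np.full(14, 12.0),
                                  closing=np.full(14, 12.0)))
        assert q["SQ [Mean]"] == pytest.approx(1.0)
        assert q["SQ [Std]"] == pytest.approx(0.0)

    def test_speed_quotient_is_closing_over_opening(self):
        q = quotients(make_series(opening=np.full(14, 30.0),
                                  closing=np.full(14, 10.0)))
        assert q["SQ [Mean]"] == pytest.approx(1.0 / 3.0)

    def test_square_pulses_peakier_than_triangles(self):
        def pq_for(plateau_fraction):
            spec = RecordingSpec(f0=150.0, seed=0,
                                 pulse=dataclasses.replace(
                                     RecordingSpec().pulse,
                                     plateau_fraction=plateau_fraction))
            rec = generate_recording(spec)
            cyc = detect_cycles(rec.gaw_total, rec.fs, "maximum")
            return quotients(cycle_series(rec.gaw_total, cyc))["PQ [Mean]"]

        assert pq_for(0.6) > pq_for(0.0)

    def test_generator_quotient_targets_recovered(self, plain_recording):
        rec = plain_recording
        cyc = detect_cycles(rec.gaw_total, rec.fs, "maximum")
        q = quotients(cycle_series(rec.gaw_total, cyc))
        assert q["SQ [Mean]"] == pytest.approx(
            rec.truth.pulse.speed_quotient_target, rel=0.02)
        assert q["PQ [Mean]"] == pytest.approx(
            rec.truth.pulse.plateau_fraction, rel=0.02)
        assert q["OQ [Mean]"] == pytest.approx(
            rec.truth.pulse.open_quotient, rel=0.02)


class TestSnr:
    def test_pure_sinusoid_hits_cap(self):
        t = np.arange(2000) / 4000.0
        x = np.sin(2 * np.pi * 100.0 * t)
        cyc = detect_cycles(x, 4000.0, "maximum")
        assert snr_k(x, cyc) == 60.0
        val, flagged = snr_k(x, cyc, return_flag=True)
        assert flagged

    def test_doubling_noise_power_drops_three_db(self):
        base = RecordingSpec(
            f0=150.0, n_frames=RecordingSpec.n_frames_for_cycles(150, 150.0))
        est = {}
        for target in (15.0, 12.0):
            vals = []
            for seed in range(6):
                rec = generate_recording(dataclasses.replace(
                    base, snr_db_target=target, seed=seed))
                cyc = detect_cycles(rec.gaw_total, rec.fs, "maximum")
                vals.append(snr_k(rec.gaw_total, cyc))
            est[target] = np.mean(vals)
        assert est[15.0] - est[12.0] == pytest.approx(3.0, abs=0.5)

    def test_too_few_cycles_is_not_a_value(self):
        t = np.arange(200) / 4000.0
        x = np.sin(2 * np.pi * 100.0 * t)
        cyc = detect_cycles(x, 4000.0, "maximum")
        with pytest.warns(UserWarning):
            assert np.isnan(snr_k(x, cyc))


def triangle_pair(lags, period=100):
    """Left/right pulse trains where the right pulse of cycle k is shifted
    by ``lags[k]`` cycle fractions.  Pulses sit at a 0.2-cycle offset so
    the shifted pulse stays wholly inside its cycle window."""
    n = len(lags)
    t = np.arange(n * period)
    k = t // period
    u = (t % period) / period
    def pulse(u):
        return np.clip(np.minimum(u / 0.25, (0.6 - u) / 0.35), 0.0, 1.0)
    left = pulse(u - 0.2)
    right = pulse(u - 0.2 - np.asarray(lags)[k])
    bounds = np.arange(n + 1) * period
    cs = CycleSet(mode="minimum", boundaries=bounds, fs=4000.0,
                  period_bounds=(0.0, np.inf))
    return left, right, cs


class TestSymmetryFeatures:
    def test_identical_sides_are_perfectly_symmetric(self, plain_recording):
        rec = plain_recording
        mx = detect_cycles(rec.gaw_total, rec.fs, "maximum")
        mn = detect_cycles(rec.gaw_total, rec.fs, "minimum")
        sym = symmetry_features(rec.gaw_left, rec.gaw_right, mx, mn)
        assert sym["PhA [Mean]"] == pytest.approx(0.0, abs=1e-9)
        assert sym["PhAI [Mean]"] == pytest.approx(0.0, abs=1e-9)
        assert sym["AmSI [Mean]"] == pytest.approx(1.0)
        assert sym["WaSI [Mean]"] == pytest.approx(1.0)

    def test_quarter_cycle_shift_recovered(self):
        spec = RecordingSpec(
            f0=150.0, phase_shift=0.25,
            n_frames=RecordingSpec.n_frames_for_cycles(40, 150.0), seed=0)
        rec = generate_recording(spec)
        vec = compute_feature_vector(rec, include_pvg=False)
        assert vec["PhA [Mean]"] == pytest.approx(0.25, abs=0.02)
        assert vec["PhAI [Mean]"] == pytest.approx(0.25, abs=0.02)

    def test_alternating_lags_cancel_in_pha_but_not_phai(self):
        lags = [0.1, -0.1] * 6
        left, right, cs = triangle_pair(lags)
        sym = symmetry_features(left, right, cs, cs)
        assert sym["PhA [Mean]"] == pytest.approx(0.0, abs=1e-6)
        assert sym["PhAI [Mean]"] == pytest.approx(0.1, abs=1e-6)

    def test_swapping_sides_negates_signed_measures(self,
                                                    perturbed_recording):
        rec = perturbed_recording
        mx = detect_cycles(rec.gaw_total, rec.fs, "maximum")
        mn = detect_cycles(rec.gaw_total, rec.fs, "minimum")
        fwd = symmetry_features(rec.gaw_left, rec.gaw_right, mx, mn)
        rev = symmetry_features(rec.gaw_right, rec.gaw_left, mx, mn)
        assert rev["PhA [Mean]"] == pytest.approx(-fwd["PhA [Mean]"],
                                                  abs=1e-9)
        assert rev["AmS [Mean]"] == pytest.approx(-fwd["AmS [Mean]"],
                                                  abs=1e-9)
        assert rev["PhAI [Mean]"] == pytest.approx(fwd["PhAI [Mean]"],
                                                   abs=1e-9)
        assert rev["AmSI [Mean]"] == pytest.approx(fwd["AmSI [Mean]"],
                                                   abs=1e-9)

    def test_amplitude_ratio_recovered(self):
        spec = RecordingSpec(
            f0=150.0, lr_amplitude_ratio=0.8,
            n_frames=RecordingSpec.n_frames_for_cycles(40, 150.0), seed=0)
        vec = compute_feature_vector(generate_recording(spec),
                                     include_pvg=False)
        assert vec["AmSI [Mean]"] == pytest.approx(0.8, rel=0.02)
        assert vec["AmS [Mean]"] == pytest.approx(-0.2, abs=0.01)


class TestRegistryEvaluation:
    def test_registry_has_ninety_one_unique_entries(self):
        assert len(REGISTRY) == 91
        assert len(REGISTRY.family("gaw_t")) == 41
        assert len(REGISTRY.family("symmetry")) == 18
        assert len(REGISTRY.family("pvg")) == 32
        min_based = [e.abbreviation for e in REGISTRY.entries
                     if e.cycle_mode == "minimum"]
        assert sorted(min_based) == ["PhA [Mean]", "PhA [Std]",
                                     "PhAI [Mean]", "PhAI [Std]"]
        assert all(p in REGISTRY for p in HSV2_PARAMETERS)

    def test_full_vector_covers_registry(self, perturbed_recording):
        vec = compute_feature_vector(perturbed_recording)
        assert list(vec) == REGISTRY.abbreviations
        finite = sum(np.isfinite(v) for v in vec.values())
        assert finite == 91

    def test_short_recording_degrades_gracefully(self):
        spec = RecordingSpec(
            f0=150.0, jitter_pct_target=1.0,
            n_frames=RecordingSpec.n_frames_for_cycles(6, 150.0), seed=1)
        vec = compute_feature_vector(generate_recording(spec),
                                     include_pvg=False)
        assert np.isnan(vec["PPQ11"]) and np.isnan(vec["APQ11"])
        assert np.isfinite(vec["Jit(%)"]) and np.isfinite(vec["PPQ5"])
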