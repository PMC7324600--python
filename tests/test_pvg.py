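"""Phonovibrogram construction, edge extraction and contour angles."""

import dataclasses

import numpy as np
import pytest

from phonovib.cycles import CycleSet
from phonovib.features import compute_feature_vector
from phonovib.pvg import (AngleSet, Phonovibrogram, angle_symmetry,
                          build_pvg, contour_angles, load_pvg_tiff,
                          opening_closing_edges, save_pvg_tiff)
from phonovib.synth import RecordingSpec, generate_recording


def rect_pvg(onsets, offsets, period=100, n_cycles=4, P=16,
             onsets_r=None, offsets_r=None):
    """PVG with rectangular pulses: position p displaced in
    [onsets[p], offsets[p]) within each cycle."""
    onsets_r = onsets if onsets_r is None else onsets_r
    offsets_r = offsets if offsets_r is None else offsets_r
    T = period
    t = np.arange(n_cycles * T) % T
    disp_l = ((t[None, :] >= np.asarray(onsets)[:, None])
              & (t[None, :] < np.asarray(offsets)[:, None])).astype(float)
    disp_r = ((t[None, :] >= np.asarray(onsets_r)[:, None])
              & (t[None, :] < np.asarray(offsets_r)[:, None])).astype(float)
    pvg = Phonovibrogram(disp_left=disp_l, disp_right=disp_r, fs=4000.0)
    cs = CycleSet(mode="minimum",
                  boundaries=np.arange(n_cycles + 1) * T, fs=4000.0,
                  period_bounds=(0.0, np.inf))
    return pvg, cs


class TestBuildPvg:
    def test_symmetric_recording_mirrors_in_image(self, plain_recording):
        pvg = build_pvg(plain_recording)
        img = pvg.to_image()
        P = pvg.n_positions
        assert np.array_equal(img[:P], img[P:][::-1])

    def test_zero_displacement_gives_zero_image(self):
        pvg = Phonovibrogram(disp_left=np.zeros((8, 50)),
                             disp_right=np.zeros((8, 50)), fs=4000.0)
        assert not pvg.to_image().any()

    def test_missing_displacement_rejected(self, plain_recording):
        broken = dataclasses.replace(plain_recording, disp_left=None)
        with pytest.raises(ValueError):
            build_pvg(broken)

    def test_tiff_round_trip_within_quantization(self, tmp_path,
                                                 perturbed_recording):
        pvg = build_pvg(perturbed_recording)
        path = tmp_path / "pvg.tif"
        scale = save_pvg_tiff(pvg, path)
        back = load_pvg_tiff(path, fs=pvg.fs, scale=scale)
        tol = 0.5 / scale
        assert np.allclose(back.disp_left, pvg.disp_left, atol=tol)
        assert np.allclose(back.disp_right, pvg.disp_right, atol=tol)


class TestEdges:
    def test_simultaneous_opening_gives_constant_onset(self):
        pvg, cs = rect_pvg(onsets=[10] * 16, offsets=[70] * 16)
        edges = opening_closing_edges(pvg, cs, eps_frac=0.05)
        for i, (s, _) in enumerate(edges.spans):
            assert np.all(edges.onset["L"][i] == s + 10)
            assert np.all(edges.offset["L"][i] == s + 69)

    def test_linear_delay_appears_linearly_in_onsets(self):
        # Onset sweeps linearly over positions with total spread 15 frames.
        onsets = np.round(np.linspace(10, 25, 16)).astype(int)
        pvg, cs = rect_pvg(onsets=onsets, offsets=[80] * 16)
        edges = opening_closing_edges(pvg, cs, eps_frac=0.05)
        got = edges.onset["L"][0] - edges.spans[0][0]
        assert np.array_equal(got, onsets.astype(float))

    def test_zero_eps_takes_first_nonzero_frame(self):
        pvg, cs = rect_pvg(onsets=[5] * 16, offsets=[50] * 16)
        edges = opening_closing_edges(pvg, cs, eps_frac=0.0)
        assert np.all(edges.onset["L"][0] == 5)

    def test_silent_positions_marked_absent(self):
        onsets = [10] * 16
        pvg, cs = rect_pvg(onsets=onsets, offsets=[70] * 16)
        pvg.disp_left[0] = 0.0              # posterior tip never opens
        edges = opening_closing_edges(pvg, cs)
        assert np.all(np.isnan(edges.onset["L"][:, 0]))
        assert np.isfinite(edges.onset["L"][:, 1]).all()


class TestContourAngles:
    def test_simultaneous_opening_is_exactly_ninety_degrees(self):
        pvg, cs = rect_pvg(onsets=[10] * 16, offsets=[70] * 16)
        edges = opening_closing_edges(pvg, cs)
        angles = contour_angles(edges, cs, pvg.n_positions)
        pars = angles.as_parameters()
        assert pars["CA^L,OA [Mean]"] == 90.0
        assert pars["CA^L,OP [Mean]"] == 90.0
        assert pars["CA^R,CA [Mean]"] == 90.0
        assert pars["CA^L,OA [Std]"] == 0.0

    def test_quarter_cycle_tip_lead_matches_closed_form(self):
        # The anterior tip opens first; the front reaches mid-fold a
        # quarter cycle later: angle = atan2(1, 0.25) = 75.96 deg.
        P, T = 16, 100
        mid = (P - 1) / 2.0
        u = np.abs(np.arange(P) - mid) / ((P - 1) / 2.0)
        onsets = 10 + 0.25 * T * (1.0 - u)
        span = [(k * T, (k + 1) * T) for k in range(4)]
        from phonovib.pvg import EdgeSet
        edges = EdgeSet(
            spans=span,
            onset={s: np.tile(onsets, (4, 1))
                   + np.array([sp[0] for sp in span])[:, None]
                   for s in ("L", "R")},
            offset={s: np.full((4, P), 90.0)
                    + np.array([sp[0] for sp in span])[:, None]
                    for s in ("L", "R")})
        cs = CycleSet(mode="minimum", boundaries=np.arange(5) * T,
                      fs=4000.0, period_bounds=(0.0, np.inf))
        angles = contour_angles(edges, cs, P)
        expected = np.degrees(np.arctan2(1.0, 0.25))
        pars = angles.as_parameters()
        assert pars["CA^L,OA [Mean]"] == pytest.approx(expected, abs=1e-9)
        assert pars["CA^L,OP [Mean]"] == pytest.approx(expected, abs=1e-9)
        assert pars["CA^L,CA [Mean]"] == 90.0   # simultaneous closing

    def test_identical_cycles_have_zero_angle_spread(self):
        pvg, cs = rect_pvg(onsets=np.linspace(10, 30, 16).round(),
                           offsets=[80] * 16)
        edges = opening_closing_edges(pvg, cs)
        angles = contour_angles(edges, cs, pvg.n_positions)
        for key, val in angles.as_parameters().items():
            if key.endswith("[Std]"):
                assert val == pytest.approx(0.0, abs=1e-9)

    def test_ap_delay_maps_monotonically_to_angle(self):
        means = []
        for tau in (-0.10, -0.05, 0.0, 0.05, 0.10):
            spec = RecordingSpec(f0=150.0, ap_delay_open=tau, seed=0)
            vec = compute_feature_vector(generate_recording(spec))
            means.append(vec["CA^L,OA [Mean]"])
        assert np.all(np.diff(means) > 0)
        assert means[2] == pytest.approx(90.0, abs=0.5)


class TestAngleSymmetry:
    def test_mirrored_folds_are_perfectly_symmetric(self):
        pvg, cs = rect_pvg(onsets=np.linspace(10, 25, 16).round(),
                           offsets=[80] * 16)
        edges = opening_closing_edges(pvg, cs)
        angles = contour_angles(edges, cs, pvg.n_positions)
        sym = angle_symmetry(angles)
        assert sym["CAS^OA [Mean]"] == pytest.approx(1.0)
        assert sym["CASI^OA [Mean]"] == pytest.approx(1.0)

    def test_hand_computed_ratio_and_index(self):
        angles = AngleSet()
        for pr in ("OA", "OP", "CA", "CP"):
            angles.angles[("L", pr)] = np.full(5, 100.0)
            angles.angles[("R", pr)] = np.full(5, 80.0)
        sym = angle_symmetry(angles)
        assert sym["CAS^OA [Mean]"] == pytest.approx(1.25)
        assert sym["CASI^OA [Mean]"] == pytest.approx(0.8)

    def test_swapping_folds_inverts_ratio_not_index(self):
        angles = AngleSet()
        swapped = AngleSet()
        rng = np.random.default_rng(0)
        for pr in ("OA", "OP", "CA", "CP"):
            a = 90 + rng.normal(0, 5, 6)
            b = 90 + rng.normal(0, 5, 6)
            angles.angles[("L", pr)], angles.angles[("R", pr)] = a, b
            swapped.angles[("L", pr)], swapped.angles[("R", pr)] = b, a
        s1, s2 = angle_symmetry(angles), angle_symmetry(swapped)
        for pr in ("OA", "CA"):
            assert s2[f"CASI^{pr} [Mean]"] == pytest.approx(
                s1[f"CASI^{pr} [Mean]"])
            assert s2[f"CAS^{pr} [Mean]"] != pytest.approx(
                s1[f"CAS^{pr} [Mean]"])

    def test_symmetry_index_bounded_by_one(self, extracted_table):
        for pr in ("OA", "OP", "CA", "CP"):
            col = extracted_table.data[f"CASI^{pr} [Mean]"]
            assert (col.dropna() <= 1.0 + 1e-12).all()
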