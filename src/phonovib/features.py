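"""Parameters computed from glottal area waveforms.

Implements the per-cycle series (periods, amplitudes, energies, open-phase
durations), the perturbation families (jitter, shimmer, energy perturbation
and their k-point quotients), the spectral harmonics-to-noise ratio, the
pulse-shape quotients, the left-right symmetry parameters, and the driver
that evaluates the full 91-entry registry for one recording.

Sub-frame landmarks
-------------------
At 4000 frames/s a vocal-fold cycle spans only 13-40 frames, so integer
frame indices quantize cycle landmarks coarsely enough to inflate
perturbation measures at clinical jitter/shimmer levels.  Period, duration
and peak-instant estimates therefore use linear interpolation of level
crossings on the pulse edges:

* the pulse onset is extrapolated from the 20%- and 60%-of-peak crossings of
  the rising edge down to the baseline (exact for a piecewise-linear pulse);
  periods are differences of successive onsets;
* opening/plateau/closing durations are measured between the baseline and
  the interpolated 90%-of-peak crossings;
* the peak instant is the midpoint of the >=90% span (robust for
  plateau-topped pulses, where the sample argmax is arbitrary).

``refine=False`` in :func:`cycle_series` falls back to the literal
boundary-spacing periods (integer frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.fft import rfft

from .cycles import CycleSet, NoCyclesError, detect_cycles, transfer_cycles
from .registry import REGISTRY, ParameterRegistry

__all__ = [
    "CycleSeries",
    "PulseLandmarks",
    "cycle_series",
    "perturbation_features",
    "snr_k",
    "quotients",
    "symmetry_features",
    "compute_feature_vector",
    "extract_feature_table",
]


# --------------------------------------------------------------------------
# Pulse landmarks with sub-frame interpolation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseLandmarks:
    """Interpolated landmark times (in frames) of one glottal pulse."""

    onset: float        # open-phase start (baseline extrapolation)
    t90_up: float       # 90%-of-peak crossing, rising edge
    t90_down: float     # 90%-of-peak crossing, falling edge
    offset: float       # open-phase end (baseline extrapolation)
    peak: float         # peak amplitude
    base: float         # baseline level

    @property
    def peak_instant(self) -> float:
        return 0.5 * (self.t90_up + self.t90_down)

    @property
    def opening(self) -> float:
        return self.t90_up - self.onset

    @property
    def plateau(self) -> float:
        return self.t90_down - self.t90_up

    @property
    def closing(self) -> float:
        return self.offset - self.t90_down

    @property
    def open_duration(self) -> float:
        return self.offset - self.onset


def _cross_before(x, lo, pk, level):
    """Interpolated time of the last upward crossing of ``level`` in
    ``x[lo:pk+1]`` (None if the edge never drops below the level)."""
    seg = x[lo:pk + 1]
    below = np.flatnonzero(seg < level)
    if below.size == 0 or below[-1] == seg.size - 1:
        return None
    i = int(below[-1])
    x0, x1 = seg[i], seg[i + 1]
    return lo + i + (level - x0) / (x1 - x0)


def _cross_after(x, pk, hi, level):
    """Interpolated time of the first downward crossing of ``level`` in
    ``x[pk:hi]``."""
    seg = x[pk:hi]
    below = np.flatnonzero(seg < level)
    if below.size == 0 or below[0] == 0:
        return None
    i = int(below[0])
    x0, x1 = seg[i - 1], seg[i]
    return pk + i - 1 + (x0 - level) / (x0 - x1)


def pulse_landmarks(x, pk: int, lo: int, hi: int) -> Optional[PulseLandmarks]:
    """Landmarks of the pulse peaking at index ``pk``, searched within
    ``[lo, hi)``.  Returns None when an edge cannot be resolved."""
    if not (lo <= pk < hi):
        return None
    base_l = float(np.min(x[lo:pk + 1]))
    base_r = float(np.min(x[pk:hi]))
    peak = float(x[pk])
    if peak - base_l <= 0 or peak - base_r <= 0:
        return None

    def lev_l(f):
        return base_l + f * (peak - base_l)

    def lev_r(f):
        return base_r + f * (peak - base_r)

    t20 = _cross_before(x, lo, pk, lev_l(0.2))
    t60 = _cross_before(x, lo, pk, lev_l(0.6))
    t90u = _cross_before(x, lo, pk, lev_l(0.9))
    t90d = _cross_after(x, pk, hi, lev_r(0.9))
    t20d = _cross_after(x, pk, hi, lev_r(0.2))
    t60d = _cross_after(x, pk, hi, lev_r(0.6))
    if None in (t20, t60, t90u, t90d, t20d, t60d):
        return None
    # Extrapolate the linear edge to the baseline: the 20% and 60% crossings
    # fix the edge slope, so onset = t20 - (t60 - t20)/2 lands exactly at
    # level 0 for a linear edge.
    onset = t20 - 0.5 * (t60 - t20)
    offset = t20d + 0.5 * (t20d - t60d)
    return PulseLandmarks(onset=onset, t90_up=t90u, t90_down=t90d,
                          offset=offset, peak=peak, base=base_l)


# --------------------------------------------------------------------------
# Per-cycle series
# --------------------------------------------------------------------------

@dataclass
class CycleSeries:
    """Per-cycle quantities extracted from one GAW under one cycle set."""

    fs: float
    period_s: np.ndarray       # seconds
    amplitude: np.ndarray      # value at the cycle's peak, area units
    energy: np.ndarray         # sum of squared samples per cycle
    dyn_range: np.ndarray      # cycle max - cycle min
    opening: np.ndarray        # frames (float, interpolated)
    plateau: np.ndarray
    closing: np.ndarray
    open_frac: np.ndarray      # open duration / period
    peak_instant: np.ndarray   # frames (float), one per boundary pulse

    @property
    def n_cycles(self) -> int:
        return int(self.amplitude.size)


def cycle_series(gaw, cycles: CycleSet, refine: bool = True) -> CycleSeries:
    """Extract the per-cycle series from a GAW and maximum-based cycles.

    Each boundary of a maximum-based cycle set is a pulse peak; durations
    and the period sequence are derived from the landmarks of those pulses.
    Requires at least 3 cycles.
    """
    x = np.asarray(gaw, dtype=float)
    spans = cycles.cycles()
    if len(spans) < 3:
        raise ValueError("need at least 3 cycles")
    b = cycles.boundaries
    n = x.size

    # Amplitude = value at the cycle's defining peak.  The window max of a
    # peak-to-peak cycle also sees the rise toward the *next* peak, which
    # correlates consecutive amplitudes and dilutes shimmer estimates.
    amplitude, energy, dyn = [], [], []
    for s, e in spans:
        seg = x[s:e]
        amplitude.append(float(x[s]))
        energy.append(float(np.sum(seg ** 2)))
        dyn.append(float(seg.max() - seg.min()))
    amplitude = np.array(amplitude)
    energy = np.array(energy)
    dyn = np.array(dyn)

    # Landmarks of the pulse at each boundary; the search window extends to
    # the neighboring boundaries (or a typical period at the edges).
    typ = int(np.median(np.diff(b)))
    lm: List[Optional[PulseLandmarks]] = []
    for k, pk in enumerate(b):
        lo = int(b[k - 1]) if k > 0 else max(0, int(pk) - typ)
        hi = int(b[k + 1]) if k + 1 < b.size else min(n, int(pk) + typ)
        lm.append(pulse_landmarks(x, int(pk), lo, hi))

    onsets = np.array([m.onset if m is not None else np.nan for m in lm])
    peak_instant = np.array([m.peak_instant if m is not None else np.nan
                             for m in lm])

    if refine:
        period_frames = np.diff(onsets)
    else:
        period_frames = np.diff(b).astype(float)
    period_s = period_frames / cycles.fs
    period_s = period_s[np.isfinite(period_s)]

    # Durations attributed to the pulse at the cycle's starting boundary.
    m_cyc = lm[:len(spans)]
    opening = np.array([m.opening if m is not None else np.nan for m in m_cyc])
    plateau = np.array([m.plateau if m is not None else np.nan for m in m_cyc])
    closing = np.array([m.closing if m is not None else np.nan for m in m_cyc])
    open_dur = np.array([m.open_duration if m is not None else np.nan
                         for m in m_cyc])
    with np.errstate(invalid="ignore"):
        open_frac = open_dur / (np.diff(b)[:len(spans)].astype(float))

    return CycleSeries(fs=cycles.fs, period_s=period_s, amplitude=amplitude,
                       energy=energy, dyn_range=dyn, opening=opening,
                       plateau=plateau, closing=closing, open_frac=open_frac,
                       peak_instant=peak_instant)


# --------------------------------------------------------------------------
# Perturbation families
# --------------------------------------------------------------------------

def _kpoint_quotient(x: np.ndarray, k: int) -> float:
    """100 * mean|x_i - MA_k(x)_i| / mean(x), centered k-point window."""
    if x.size < k + 1:
        warnings.warn(f"{k}-point quotient needs {k + 1} cycles, got "
                      f"{x.size}; returning not-a-value", stacklevel=2)
        return np.nan
    ma = np.convolve(x, np.ones(k) / k, mode="valid")
    center = x[k // 2: k // 2 + ma.size]
    return 100.0 * float(np.mean(np.abs(center - ma))) / float(np.mean(x))


def _abs_diff(x):
    return np.abs(np.diff(x))


def perturbation_features(series: CycleSeries) -> Dict[str, float]:
    """Perturbation parameters of the period/amplitude/energy series.

    Members needing more cycles than available are not-a-value (NaN) with a
    warning.  Sample statistics use ddof=1.
    """
    out: Dict[str, float] = {}
    T = series.period_s[series.period_s > 0]
    A = series.amplitude
    E = series.energy

    def moments(prefix, x):
        d = _abs_diff(x)
        out[f"{prefix} [Mean]"] = float(np.mean(d)) if d.size else np.nan
        out[f"{prefix} [Std]"] = float(np.std(d, ddof=1)) if d.size > 1 \
            else np.nan

    if T.size >= 2:
        f0 = 1.0 / T
        out["F0 [Mean]"] = float(np.mean(f0))
        out["F0 [Std]"] = float(np.std(f0, ddof=1))
        out["vF0"] = 100.0 * out["F0 [Std]"] / out["F0 [Mean]"]
        moments("TP", T)
        out["Jit(%)"] = 100.0 * float(np.mean(_abs_diff(T))) / float(np.mean(T))
        out["PPF"] = 100.0 * float(np.mean(_abs_diff(T) / T[:-1]))
    else:
        for k in ("F0 [Mean]", "F0 [Std]", "vF0", "TP [Mean]", "TP [Std]",
                  "Jit(%)", "PPF"):
            out[k] = np.nan
    for k, name in ((3, "PPQ3"), (5, "PPQ5"), (11, "PPQ11")):
        out[name] = _kpoint_quotient(T, k)
    out["RAP_K"] = out["PPQ3"]

    if A.size >= 2 and np.all(A > 0):
        moments("AP", A)
        out["MShim"] = float(np.mean(np.abs(20.0 * np.log10(A[1:] / A[:-1]))))
        out["Shim(%)"] = 100.0 * float(np.mean(_abs_diff(A))) / float(np.mean(A))
        out["APF"] = 100.0 * float(np.mean(_abs_diff(A) / A[:-1]))
    else:
        for k in ("AP [Mean]", "AP [Std]", "MShim", "Shim(%)", "APF"):
            out[k] = np.nan
    for k, name in ((3, "APQ3"), (5, "APQ5"), (11, "APQ11")):
        out[name] = _kpoint_quotient(A, k)

    if E.size >= 2 and np.all(E > 0):
        moments("EP", E)
        out["EPF"] = 100.0 * float(np.mean(_abs_diff(E) / E[:-1]))
    else:
        for k in ("EP [Mean]", "EP [Std]", "EPF"):
            out[k] = np.nan
    for k, name in ((3, "EPQ3"), (5, "EPQ5"), (11, "EPQ11")):
        out[name] = _kpoint_quotient(E, k)

    def stats(prefix, x):
        out[f"{prefix} [Mean]"] = float(np.mean(x)) if x.size else np.nan
        out[f"{prefix} [Std]"] = float(np.std(x, ddof=1)) if x.size > 1 \
            else np.nan

    stats("A", A)
    stats("E", E)
    stats("DyR", series.dyn_range)
    return out


# --------------------------------------------------------------------------
# Spectral harmonics-to-noise ratio
# --------------------------------------------------------------------------

SNR_CAP_DB = 60.0


def snr_k(gaw, cycles: CycleSet, max_harmonics: int = 8,
          cap: float = SNR_CAP_DB, return_flag: bool = False):
    """Harmonics-to-noise energy ratio of the GAW spectrum, in dB.

    The signal is truncated to the span of the detected cycle boundaries
    (approximately an integer number of periods), mean-removed, Hann
    windowed, and transformed.  Harmonic energy is summed over main-lobe
    (+/-2 bin) bands around multiples of the fundamental (k = 1..K, K =
    harmonics below Nyquist, at most ``max_harmonics``), with the broadband
    noise floor under the bands estimated from the non-harmonic bins and
    subtracted.  The fundamental is located by the spectral maximum in the
    plausible-period range with parabolic sub-bin refinement.  Returns
    ``10 log10(E_harm / (E_total - E_harm))``, capped at ``cap`` dB; a
    (near-)zero residual returns the cap (flagged when
    ``return_flag=True``).
    """
    x = np.asarray(gaw, dtype=float)
    b = cycles.boundaries
    n_cyc = b.size - 1
    if n_cyc < 10:
        warnings.warn("snr_k: fewer than 10 cycles; returning not-a-value")
        return (np.nan, False) if return_flag else np.nan
    seg = x[b[0]:b[-1]].astype(float)
    seg = seg - seg.mean()
    # Hann window: confines each harmonic's leakage to its main lobe even
    # when the segment is not an exact number of periods (boundary
    # detection is only frame-accurate, noisier still with noise).
    spec = np.abs(rfft(seg * np.hanning(seg.size))) ** 2
    n_bins = spec.size
    # Fundamental bin from the spectral maximum within the plausible
    # period range (cycle boundaries are unreliable under heavy noise).
    p_lo, p_hi = cycles.period_bounds
    lo = max(1, int(np.floor(seg.size / p_hi)) if np.isfinite(p_hi)
             else int(seg.size // 80))
    hi = min(n_bins - 2, int(np.ceil(seg.size / max(p_lo, 2.0))))
    if hi <= lo:
        return (cap, True) if return_flag else cap
    c1 = lo + int(np.argmax(spec[lo:hi + 1]))
    # Guard against landing on the second harmonic: prefer the subharmonic
    # if it carries substantial energy.
    half = c1 // 2
    if half >= lo and spec[half - 2:half + 3].sum() >= 0.25 * \
            spec[c1 - 2:c1 + 3].sum():
        c1 = half
    # Parabolic refinement of the fundamental to sub-bin accuracy so the
    # higher-harmonic band centers stay on target.
    if 1 <= c1 < n_bins - 1:
        d1, d0, d2 = spec[c1 - 1], spec[c1], spec[c1 + 1]
        denom = d1 - 2 * d0 + d2
        c1f = c1 + (0.5 * (d1 - d2) / denom if denom < 0 else 0.0)
    else:
        c1f = float(c1)
    k_max = min(max_harmonics, int((n_bins - 3) // c1f))
    if k_max < 1:
        return (cap, True) if return_flag else cap
    band = np.zeros(n_bins, dtype=bool)
    for k in range(1, k_max + 1):
        c = int(round(k * c1f))
        band[c - 2:c + 3] = True
    band[0] = False
    e_total = float(spec[1:].sum())
    e_band = float(spec[band].sum())
    n_band = int(band.sum())
    n_free = (n_bins - 1) - n_band
    density = (e_total - e_band) / n_free if n_free > 0 else 0.0
    e_harm = max(e_band - n_band * density, 0.0)
    e_noise = e_total - e_harm
    flagged = False
    if e_noise <= 0 or e_harm / max(e_noise, 1e-300) >= 10 ** (cap / 10.0):
        val, flagged = cap, True
    elif e_harm <= 0:
        val, flagged = -cap, True
    else:
        val = 10.0 * np.log10(e_harm / e_noise)
    return (val, flagged) if return_flag else val


def _snr_block_std(gaw, cycles: CycleSet, block_cycles: int = 16):
    """Std of the harmonics-to-noise ratio over consecutive cycle blocks."""
    b = cycles.boundaries
    n_cyc = b.size - 1
    n_blocks = n_cyc // block_cycles
    if n_blocks < 2:
        return np.nan
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_blocks):
            sub = CycleSet(mode=cycles.mode,
                           boundaries=b[i * block_cycles:(i + 1) * block_cycles + 1],
                           fs=cycles.fs, period_bounds=cycles.period_bounds)
            v = snr_k(gaw, sub)
            if np.isfinite(v):
                vals.append(v)
    if len(vals) < 2:
        return np.nan
    return float(np.std(vals, ddof=1))


# --------------------------------------------------------------------------
# Pulse-shape quotients
# --------------------------------------------------------------------------

def quotients(series: CycleSeries) -> Dict[str, float]:
    """Speed, plateau and open quotients (means and stds across cycles).

    ``SQ_k = closing/opening`` (note: much of the literature uses the
    inverse convention); ``PQ_k = plateau / open duration``.  Cycles with
    zero or unresolved opening are skipped with a warning.
    """
    opening, plateau, closing = series.opening, series.plateau, series.closing
    open_dur = opening + plateau + closing
    ok = np.isfinite(opening) & np.isfinite(closing) & np.isfinite(plateau) \
        & (opening > 0) & (open_dur > 0)
    n_skipped = int(np.sum(~ok))
    if n_skipped:
        warnings.warn(f"quotients: skipped {n_skipped} cycles with "
                      "degenerate opening phase")
    out: Dict[str, float] = {}

    def stats(name, x):
        x = x[np.isfinite(x)]
        out[f"{name} [Mean]"] = float(np.mean(x)) if x.size else np.nan
        out[f"{name} [Std]"] = float(np.std(x, ddof=1)) if x.size > 1 \
            else np.nan

    sq = np.where(ok, closing / np.where(ok, opening, 1.0), np.nan)
    pq = np.where(ok, plateau / np.where(ok, open_dur, 1.0), np.nan)
    stats("SQ", sq)
    stats("PQ", pq)
    stats("OQ", series.open_frac[ok] if ok.any() else
          np.array([]))
    return out


# --------------------------------------------------------------------------
# Left-right symmetry parameters
# --------------------------------------------------------------------------

def _wrap_lag(x: float) -> float:
    w = ((x + 0.5) % 1.0) - 0.5
    return 0.5 if w == -0.5 else w


def symmetry_features(gaw_l, gaw_r, max_cycles: CycleSet,
                      min_cycles: Optional[CycleSet]) -> Dict[str, float]:
    """The 18 left-right symmetry parameters.

    Phase shifts (PhA/PhAI) use minimum-based cycles so that each window
    contains a whole pulse; the lag is the difference of interpolated peak
    instants in cycle fractions, wrapped to (-0.5, 0.5].  All other members
    compare per-cycle amplitude, dynamic range, energy, and waveform shape
    on maximum-based cycles.  Flat cycles on either side are skipped.
    """
    xl = np.asarray(gaw_l, dtype=float)
    xr = np.asarray(gaw_r, dtype=float)
    out: Dict[str, float] = {}

    ams, amsi, dyrs, dyrsi, spa, spai, wasi = ([] for _ in range(7))
    for s, e in max_cycles.cycles():
        l_seg, r_seg = xl[s:e], xr[s:e]
        a_l, a_r = l_seg.max(), r_seg.max()
        d_l, d_r = a_l - l_seg.min(), a_r - r_seg.min()
        e_l, e_r = float(np.sum(l_seg ** 2)), float(np.sum(r_seg ** 2))
        if d_l <= 0 or d_r <= 0 or max(a_l, a_r) <= 0 or max(e_l, e_r) <= 0:
            continue
        ams.append((a_r - a_l) / max(a_r, a_l))
        amsi.append(min(a_l, a_r) / max(a_l, a_r))
        dyrs.append((d_r - d_l) / max(d_r, d_l))
        dyrsi.append(min(d_l, d_r) / max(d_l, d_r))
        spa.append((e_r - e_l) / max(e_r, e_l))
        spai.append(min(e_l, e_r) / max(e_l, e_r))
        lc = l_seg - l_seg.mean()
        rc = r_seg - r_seg.mean()
        denom = np.sqrt(np.sum(lc ** 2) * np.sum(rc ** 2))
        if denom > 0:
            wasi.append(float(np.sum(lc * rc)) / denom)

    def stats(name, vals):
        v = np.asarray(vals, dtype=float)
        out[f"{name} [Mean]"] = float(np.mean(v)) if v.size else np.nan
        out[f"{name} [Std]"] = float(np.std(v, ddof=1)) if v.size > 1 \
            else np.nan

    stats("AmS", ams)
    stats("AmSI", amsi)
    stats("DyRS", dyrs)
    stats("DyRSI", dyrsi)
    stats("SpA", spa)
    stats("SpAI", spai)
    stats("WaSI", wasi)

    lags = []
    if min_cycles is not None:
        for s, e in min_cycles.cycles():
            inst = []
            for x in (xl, xr):
                seg = x[s:e]
                if seg.max() - seg.min() <= 0:
                    inst.append(None)
                    continue
                pk = s + int(np.argmax(seg))
                m = pulse_landmarks(x, pk, s, e)
                inst.append(m.peak_instant if m is not None else float(pk))
            if None in inst:
                continue
            lags.append(_wrap_lag((inst[1] - inst[0]) / (e - s)))
    lags = np.asarray(lags, dtype=float)
    stats("PhA", lags)
    stats("PhAI", np.abs(lags))
    return out


# --------------------------------------------------------------------------
# Full registry evaluation
# --------------------------------------------------------------------------

def compute_feature_vector(recording, registry: ParameterRegistry = REGISTRY,
                           prominence_frac: float = 0.10,
                           f0_bounds=(50.0, 1000.0),
                           include_pvg: bool = True) -> Dict[str, float]:
    """Evaluate every registry entry for one recording.

    Runs cycle detection in both modes on the total GAW, transfers the
    boundaries to the partial GAWs and the phonovibrogram, and assembles the
    91-entry parameter vector (undefined members are NaN).  Raises
    :class:`phonovib.cycles.NoCyclesError` only when no cycles can be
    detected at all.
    """
    gaw_t = recording.gaw_total
    fs = recording.fs
    max_cycles = detect_cycles(gaw_t, fs, "maximum", prominence_frac,
                               f0_bounds)
    try:
        min_cycles = detect_cycles(gaw_t, fs, "minimum", prominence_frac,
                                   f0_bounds)
    except NoCyclesError:
        min_cycles = None

    transfer_cycles(max_cycles, recording.gaw_left.size)

    out: Dict[str, float] = {a: np.nan for a in registry.abbreviations}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            series = cycle_series(gaw_t, max_cycles)
            out.update({k: v for k, v in perturbation_features(series).items()
                        if k in out})
            out.update({k: v for k, v in quotients(series).items()
                        if k in out})
        except ValueError:
            pass
        if "SNR_K [Mean]" in out:
            out["SNR_K [Mean]"] = snr_k(gaw_t, max_cycles)
            out["SNR_K [Std]"] = _snr_block_std(gaw_t, max_cycles)
        if "GA [Mean]" in out:
            out["GA [Mean]"] = float(np.mean(gaw_t))
            out["GA [Std]"] = float(np.std(gaw_t, ddof=1))
        out.update({k: v for k, v in symmetry_features(
            recording.gaw_left, recording.gaw_right, max_cycles,
            min_cycles).items() if k in out})
        if include_pvg and min_cycles is not None:
            from .pvg import (build_pvg, opening_closing_edges,
                              contour_angles, angle_symmetry)
            pvg = build_pvg(recording)
            try:
                edges = opening_closing_edges(pvg, min_cycles)
                angles = contour_angles(edges, min_cycles, pvg.n_positions)
                out.update({k: v for k, v in angles.as_parameters().items()
                            if k in out})
                out.update({k: v for k, v in
                            angle_symmetry(angles).items() if k in out})
            except ValueError:
                pass
    return out


def extract_feature_table(recordings, groups: Sequence[str],
                          registry: ParameterRegistry = REGISTRY,
                          ages: Optional[Sequence[float]] = None,
                          sexes: Optional[Sequence[str]] = None,
                          include_pvg: bool = True):
    """Compute feature vectors for a cohort and assemble a feature table.

    ``recordings`` may be any iterable of :class:`GlottalRecording` (a
    generator keeps memory flat for large cohorts).
    """
    import pandas as pd
    from .tables import FeatureTable

    rows = []
    groups = list(groups)
    for i, rec in enumerate(recordings):
        vec = compute_feature_vector(rec, registry, include_pvg=include_pvg)
        row = {"subject_id": f"S{i:04d}", "group": groups[i],
               "sex": sexes[i] if sexes is not None else "",
               "age": float(ages[i]) if ages is not None else np.nan}
        row.update(vec)
        rows.append(row)
    data = pd.DataFrame(rows)
    return FeatureTable(data=data, parameters=list(registry.abbreviations))
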