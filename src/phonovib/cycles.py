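"""Extremum-based oscillation cycle detection on glottal area waveforms.

Cycles are detected on the total GAW and the resulting boundary indices are
transferred unchanged to the partial GAWs and the phonovibrogram, which share
the same frame clock.  A maximum-based cycle starts at a sufficiently
distinct local maximum and ends just before the next one; minimum-based
cycles are analogous on local minima and are needed for the phase-shift
parameters (peaks must lie in the interior of the window).

"Sufficiently distinct" is operationalized as peak prominence of at least
``prominence_frac`` times the signal range (default 0.10); extrema closer
than the period of ``f0_bounds[1]`` are thinned by keeping the more
prominent one.  Detection is invariant to affine rescaling y -> a*y + b
(a > 0) because prominence is measured relative to the range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.signal import find_peaks

__all__ = ["CycleSet", "NoCyclesError", "detect_cycles", "transfer_cycles"]


class NoCyclesError(ValueError):
    """Raised when fewer than two qualifying extrema are found."""


def _spectral_f0(x: np.ndarray, fs: float, f0_min: float,
                 f0_max: float):
    """Coarse fundamental-frequency estimate from the spectral maximum in
    the plausible range (with a subharmonic check), or None."""
    from scipy.fft import rfft
    n = x.size
    spec = np.abs(rfft(x - x.mean())) ** 2
    lo = max(1, int(np.floor(f0_min * n / fs)))
    hi = min(spec.size - 1, int(np.ceil(f0_max * n / fs)))
    if hi <= lo or not np.any(spec[lo:hi] > 0):
        return None
    c = lo + int(np.argmax(spec[lo:hi]))
    half = c // 2
    if half >= lo and spec[max(half - 1, 1):half + 2].sum() >= \
            0.25 * spec[c - 1:c + 2].sum():
        c = half
    return c * fs / n


@dataclass(frozen=True)
class CycleSet:
    """Cycle boundaries shared by all signals of one recording.

    ``boundaries`` are strictly increasing frame indices (0-based); cycle k
    spans the half-open interval ``[boundaries[k], boundaries[k+1])``.  The
    trailing partial cycle past the last boundary is discarded by
    construction.  ``period_bounds`` are the plausible per-cycle lengths in
    frames; :meth:`cycles` skips spans outside them.
    """

    mode: str                      # 'maximum' | 'minimum'
    boundaries: np.ndarray         # int frame indices
    fs: float
    period_bounds: Tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=int)
        object.__setattr__(self, "boundaries", b)
        if self.mode not in ("maximum", "minimum"):
            raise ValueError("mode must be 'maximum' or 'minimum'")
        if b.size < 2:
            raise NoCyclesError("need at least 2 boundaries (1 cycle)")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if b[0] < 0:
            raise ValueError("boundaries must be nonnegative frame indices")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles())

    def cycles(self) -> List[Tuple[int, int]]:
        """(start, end) frame pairs for plausible cycles."""
        lo, hi = self.period_bounds
        out = []
        b = self.boundaries
        for s, e in zip(b[:-1], b[1:]):
            if lo <= e - s <= hi:
                out.append((int(s), int(e)))
        return out

    def to_json(self) -> str:
        return json.dumps({"mode": self.mode, "fs": self.fs,
                           "boundaries": self.boundaries.tolist(),
                           "period_bounds": list(self.period_bounds)})

    @classmethod
    def from_json(cls, s: str) -> "CycleSet":
        d = json.loads(s)
        return cls(mode=d["mode"], boundaries=np.array(d["boundaries"]),
                   fs=d["fs"], period_bounds=tuple(d["period_bounds"]))


def detect_cycles(gaw, fs: float, mode: str = "maximum",
                  prominence_frac: float = 0.10,
                  f0_bounds: Tuple[float, float] = (50.0, 1000.0)) -> CycleSet:
    """Detect extremum-based cycles on a GAW signal.

    Parameters
    ----------
    gaw : array-like
        Finite signal, length >= 3.
    fs : float
        Sampling rate in Hz.
    mode : {'maximum', 'minimum'}
        Kind of extremum that starts each cycle.
    prominence_frac : float
        Minimum peak prominence as a fraction of the signal range.
    f0_bounds : (f0_min, f0_max)
        Plausible fundamental-frequency range; extrema spaced closer than
        one period of ``f0_max`` are thinned (weaker dropped), spans longer
        than one period of ``f0_min`` are not counted as cycles.

    Raises
    ------
    NoCyclesError
        If fewer than two qualifying extrema exist (e.g. constant signal).
    """
    x = np.asarray(gaw, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("gaw must be a 1-D signal of length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("gaw must be finite")
    if mode not in ("maximum", "minimum"):
        raise ValueError("mode must be 'maximum' or 'minimum'")
    f0_min, f0_max = f0_bounds
    if not (0 < f0_min < f0_max):
        raise ValueError("f0_bounds must satisfy 0 < f0_min < f0_max")

    rng = float(np.ptp(x))
    if rng <= 0:
        raise NoCyclesError("no cycles detected: constant signal")
    y = x if mode == "maximum" else -x
    # Spacing constraint from a spectral period estimate: broadband noise
    # creates spurious prominent extrema between the true ones, so the
    # plausible-f0 floor alone is not a safe minimum distance.
    f0_est = _spectral_f0(x, fs, f0_min, f0_max)
    min_dist = max(1, int(np.floor(fs / f0_max)))
    if f0_est is not None:
        min_dist = max(min_dist, int(np.floor(0.7 * fs / f0_est)))
    peaks, _ = find_peaks(y, prominence=prominence_frac * rng,
                          distance=min_dist)
    if peaks.size < 2:
        raise NoCyclesError(
            f"no cycles detected: {peaks.size} qualifying extrema")
    return CycleSet(mode=mode, boundaries=peaks, fs=fs,
                    period_bounds=(fs / f0_max, fs / f0_min))


def transfer_cycles(cycles: CycleSet, target_length: int) -> CycleSet:
    """Apply a cycle set to another signal on the same frame clock.

    The boundary indices are kept identical; they are only validated against
    the target signal length.  Transferring twice is a no-op.
    """
    if cycles.boundaries[-1] >= target_length:
        raise ValueError(
            f"cycle boundary {int(cycles.boundaries[-1])} beyond target "
            f"length {target_length}")
    return CycleSet(mode=cycles.mode, boundaries=cycles.boundaries.copy(),
                    fs=cycles.fs, period_bounds=cycles.period_bounds)
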