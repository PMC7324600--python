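"""Phonovibrogram construction and contour-angle parameters.

A phonovibrogram (PVG) maps the displacement of each vocal-fold contour
position over time into one image: one row per contour position, one column
per frame, the left fold flipped above the right so the glottal midline runs
through the image center.  The *contour angles* quantify how the opening
(or closing) front sweeps along each fold half within a cycle: 90 degrees
means the half opens (closes) simultaneously; deviations from 90 measure
the anterior-posterior "zipper" delay, with the sign indicating whether the
tip leads or trails the mid-fold.

Angle normalization: position is measured in half-fold units
(``u = |p - mid| / (P/2)``, 0 at mid-fold, 1 at the tip) and time in cycle
fractions.  The edge front is fit by least squares (edge frame vs ``u``)
over the valid positions of the region, and

    angle = atan2(du, dt_tip_to_mid)  [degrees]

where ``dt_tip_to_mid`` is the fitted time the front takes from tip to
mid-fold in cycle fractions.  A front with zero time spread gives exactly
90 degrees; a tip leading by a quarter cycle gives atan2(1, 0.25) = 75.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .cycles import CycleSet

__all__ = [
    "Phonovibrogram",
    "EdgeSet",
    "AngleSet",
    "build_pvg",
    "opening_closing_edges",
    "contour_angles",
    "angle_symmetry",
    "save_pvg_tiff",
    "load_pvg_tiff",
]

PHASE_REGIONS = ("OA", "OP", "CA", "CP")   # phase O/C x region A(nterior)/P(osterior)


@dataclass
class Phonovibrogram:
    """Per-fold displacement image [n_positions x n_frames].

    Position index 0 is posterior, index P-1 anterior; values are
    nonnegative midline distances.
    """

    disp_left: np.ndarray
    disp_right: np.ndarray
    fs: float

    def __post_init__(self):
        if self.disp_left.shape != self.disp_right.shape:
            raise ValueError("left/right displacement shapes differ")
        if np.any(self.disp_left < 0) or np.any(self.disp_right < 0):
            raise ValueError("displacements must be nonnegative")

    @property
    def n_positions(self) -> int:
        return self.disp_left.shape[0]

    @property
    def n_frames(self) -> int:
        return self.disp_left.shape[1]

    def to_image(self) -> np.ndarray:
        """2P x n_frames image, left fold flipped above the right fold."""
        return np.vstack([self.disp_left[::-1], self.disp_right])


def build_pvg(recording) -> Phonovibrogram:
    """Map a recording's displacement matrices into PVG coordinates."""
    if recording.disp_left is None or recording.disp_right is None:
        raise ValueError("recording has no displacement data")
    return Phonovibrogram(disp_left=recording.disp_left,
                          disp_right=recording.disp_right,
                          fs=recording.fs)


@dataclass
class EdgeSet:
    """Per-cycle opening/closing edge frames per position per fold.

    ``onset[side]`` and ``offset[side]`` are (n_cycles, n_positions) float
    arrays of absolute frame indices; NaN marks positions that never exceed
    the threshold within a cycle.
    """

    spans: List[tuple]
    onset: Dict[str, np.ndarray]
    offset: Dict[str, np.ndarray]


def _edges_one_cycle(window: np.ndarray, thr: np.ndarray):
    """Onset/offset per position within one cycle window.

    ``thr`` is a per-position threshold.  Onset is the first of three
    consecutive suprathreshold frames (robust against isolated noise
    spikes; identical to the first suprathreshold frame for clean data),
    offset the last of three.
    """
    P, w = window.shape
    above = window > thr[:, None]
    if w >= 3:
        run = above[:, :-2] & above[:, 1:-1] & above[:, 2:]
    else:
        run = above[:, :1]
    has = run.any(axis=1)
    onset = np.where(has, np.argmax(run, axis=1).astype(float), np.nan)
    rev = run[:, ::-1]
    last_start = run.shape[1] - 1 - np.argmax(rev, axis=1)
    off = last_start + (2 if w >= 3 else 0)
    offset = np.where(has, off.astype(float), np.nan)
    return onset, offset


def opening_closing_edges(pvg: Phonovibrogram, cycles: CycleSet,
                          eps_frac: float = 0.05,
                          floor_frac: float = 0.02) -> EdgeSet:
    """Opening onset and closing offset frames per position and fold.

    For each cycle and position: onset is the first frame with displacement
    above ``eps_frac`` times that position's maximum displacement, offset
    the last such frame (both with a 3-consecutive-frame robustness rule).
    The threshold is relative to each position's own amplitude so that a
    front that opens simultaneously along the fold crosses it
    simultaneously regardless of the spatial amplitude envelope (the 90-deg
    anchor is exact).  Positions whose amplitude stays below ``floor_frac``
    of the fold maximum are marked absent.  Cycle windows must contain a
    whole pulse (minimum-based cycles).  Cycles where every position stays
    below threshold are skipped with a warning.
    """
    spans = cycles.cycles()
    if len(spans) < 1:
        raise ValueError("need at least 1 full cycle")
    onset = {}
    offset = {}
    keep = None
    for side, disp in (("L", pvg.disp_left), ("R", pvg.disp_right)):
        row_max = disp.max(axis=1)
        thr = eps_frac * row_max
        thr[row_max < floor_frac * float(disp.max())] = np.inf
        ons = np.full((len(spans), pvg.n_positions), np.nan)
        offs = np.full_like(ons, np.nan)
        for i, (s, e) in enumerate(spans):
            o, f = _edges_one_cycle(disp[:, s:e], thr)
            ons[i] = o + s
            offs[i] = f + s
        onset[side] = ons
        offset[side] = offs
        k = ~np.all(np.isnan(ons), axis=1)
        keep = k if keep is None else (keep & k)
    if not np.all(keep):
        warnings.warn(f"opening_closing_edges: skipped "
                      f"{int(np.sum(~keep))} cycles with no suprathreshold "
                      "positions")
    idx = np.flatnonzero(keep)
    return EdgeSet(spans=[spans[i] for i in idx],
                   onset={s: onset[s][idx] for s in onset},
                   offset={s: offset[s][idx] for s in offset})


@dataclass
class AngleSet:
    """Per-cycle contour angles for each fold/phase-region combination.

    ``angles[(side, pr)]`` is an array of per-cycle angles in degrees
    (NaN for cycles where the region could not be fit).
    """

    angles: Dict[tuple, np.ndarray] = field(default_factory=dict)

    def mean_std(self, side: str, pr: str):
        a = self.angles[(side, pr)]
        a = a[np.isfinite(a)]
        mean = float(np.mean(a)) if a.size else np.nan
        std = float(np.std(a, ddof=1)) if a.size > 1 else np.nan
        return mean, std

    def as_parameters(self) -> Dict[str, float]:
        out = {}
        for side in ("L", "R"):
            for pr in PHASE_REGIONS:
                m, s = self.mean_std(side, pr)
                out[f"CA^{side},{pr} [Mean]"] = m
                out[f"CA^{side},{pr} [Std]"] = s
        return out


def _region_angle(edge: np.ndarray, u: np.ndarray, cycle_len: float) -> float:
    """Least-squares contour angle for one region of one cycle.

    ``edge`` are edge frames over the region's positions (NaN = absent),
    ``u`` the normalized distance from mid-fold.  Needs >= 3 valid
    positions spanning distinct ``u``.
    """
    ok = np.isfinite(edge)
    if ok.sum() < 3:
        return np.nan
    uu, tt = u[ok], edge[ok]
    du = uu - uu.mean()
    denom = float(np.sum(du ** 2))
    if denom <= 0:
        return np.nan
    beta = float(np.sum(du * (tt - tt.mean()))) / denom  # frames per unit u
    # Time from tip (u=1) to mid (u=0) in cycle fractions: -beta / cycle_len.
    dt = -beta / cycle_len
    return float(np.degrees(np.arctan2(1.0, dt)))


def contour_angles(edges: EdgeSet, cycles: CycleSet,
                   n_positions: int) -> AngleSet:
    """Contour angles per cycle for every fold/phase/region combination.

    Requires edges from at least 3 cycles.
    """
    if len(edges.spans) < 3:
        raise ValueError("need edges from at least 3 cycles")
    P = n_positions
    mid = (P - 1) / 2.0
    u = np.abs(np.arange(P) - mid) / ((P - 1) / 2.0)
    anterior = np.arange(P) >= P // 2      # midpoint goes to the anterior half
    posterior = ~anterior
    out = AngleSet()
    for side in ("L", "R"):
        for phase, table in (("O", edges.onset[side]),
                             ("C", edges.offset[side])):
            for reg, mask in (("A", anterior), ("P", posterior)):
                vals = []
                for i, (s, e) in enumerate(edges.spans):
                    vals.append(_region_angle(table[i][mask], u[mask],
                                              float(e - s)))
                out.angles[(side, f"{phase}{reg}")] = np.asarray(vals)
    return out


def angle_symmetry(angles: AngleSet) -> Dict[str, float]:
    """Left-right contour-angle symmetry: signed ratio CAS = CA_L/CA_R and
    bounded index CASI = min/max, per phase-region, with means and stds
    across cycles.  Cycles missing either member of a pair are excluded."""
    out: Dict[str, float] = {}
    for pr in PHASE_REGIONS:
        a_l = angles.angles[("L", pr)]
        a_r = angles.angles[("R", pr)]
        ok = np.isfinite(a_l) & np.isfinite(a_r) & (a_r > 0) & (a_l > 0)
        cas = a_l[ok] / a_r[ok]
        casi = np.minimum(a_l[ok], a_r[ok]) / np.maximum(a_l[ok], a_r[ok])
        for name, v in ((f"CAS^{pr}", cas), (f"CASI^{pr}", casi)):
            out[f"{name} [Mean]"] = float(np.mean(v)) if v.size else np.nan
            out[f"{name} [Std]"] = float(np.std(v, ddof=1)) if v.size > 1 \
                else np.nan
    return out


# --------------------------------------------------------------------------
# Image export
# --------------------------------------------------------------------------

def save_pvg_tiff(pvg: Phonovibrogram, path, scale: Optional[float] = None):
    """Export the PVG as 16-bit grayscale TIFF.

    Returns the scale factor used (grey levels per displacement unit), which
    :func:`load_pvg_tiff` needs to undo the quantization.
    """
    import tifffile
    img = pvg.to_image()
    if scale is None:
        m = float(img.max())
        scale = 65535.0 / m if m > 0 else 1.0
    tifffile.imwrite(path, np.round(img * scale).astype(np.uint16))
    return scale


def load_pvg_tiff(path, fs: float, scale: float) -> Phonovibrogram:
    import tifffile
    img = tifffile.imread(path).astype(float) / scale
    P = img.shape[0] // 2
    return Phonovibrogram(disp_left=img[:P][::-1], disp_right=img[P:], fs=fs)
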