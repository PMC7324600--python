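"""Synthetic vocal-fold oscillation generator.

Produces per-fold displacement matrices and the derived glottal area
waveforms (GAW) with *known* ground-truth parameter values, so that every
downstream estimator can be validated by recovery.

Model
-----
The lateral displacement of fold ``s`` at contour position ``p`` and time
``t`` is

    D_s(p, t) = A_{s,k} * g(p) * f(phi(t) - tau_s; edges_s(p))

where ``phi`` is a continuous cycle coordinate advancing by 1 per cycle,
``k = floor(phi - tau_s)`` indexes cycles, ``g(p)`` is a half-sine amplitude
envelope along the fold (maximum at mid-fold), ``tau_s`` is the left-right
phase shift (right fold only), and ``f`` is a trapezoidal pulse: closed
phase, linear rise, plateau, linear fall.  The pulse's open-phase onset and
offset shift linearly with normalized distance from mid-fold
(``h(p) = |p - mid| / (P/2)``), which produces the anterior-posterior
"zipper" opening/closing visible in a phonovibrogram and controls the
contour angles.

Cycle-to-cycle perturbation: periods are ``T_k = T0 (1 + eta_k)`` with
``eta_k`` i.i.d. Gaussian; amplitudes are ``A_k = exp(eps_k)`` with
``eps_k`` i.i.d. Gaussian (common to both folds; the right fold is
additionally scaled by a constant amplitude ratio).  The Gaussian scales are
computed from the jitter/shimmer targets via ``E|X_k - X_{k-1}| =
2 sigma / sqrt(pi)`` for i.i.d. N(0, sigma^2), so the population-expected
Jit(%) and MShim equal the requested targets; the lognormal amplitude form
makes the dB shimmer relation exact rather than first-order.

Pulses start at the cycle boundary (onset at phase 0), so intervals between
successive pulse onsets equal the generated period sequence exactly; this is
what makes sub-frame onset-based period estimation unbiased.

Broadband noise, when requested, is added to the 1-D partial GAWs (not to
the displacement matrices): the harmonics-to-noise ratio is a property of
the GAW spectrum, and segmentation noise in real recordings manifests in the
GAW.  The noise standard deviation is calibrated so that the expected
AC-energy ratio of the clean total GAW to the injected noise equals the
target in dB.  Noisy GAWs may dip slightly below zero; clipping is
deliberately avoided because rectification would bias the calibrated ratio.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .registry import REGISTRY, HSV2_PARAMETERS

__all__ = [
    "PulseShapeSpec",
    "RecordingSpec",
    "GlottalRecording",
    "CohortSpec",
    "GroupFeatureStats",
    "TABLE_GROUP_STATS",
    "generate_recording",
    "generate_cohort",
    "iter_cohort",
    "sample_feature_table",
    "save_recording",
    "load_recording",
]


class SpecValidationError(ValueError):
    """Raised when a generator spec violates an invariant; names the field."""


@dataclass(frozen=True)
class PulseShapeSpec:
    """Shape of one glottal pulse.

    Parameters
    ----------
    open_quotient : float in (0, 1]
        Fraction of the cycle during which the fold is displaced (open).
    speed_quotient_target : float > 0
        Target ratio of closing to opening duration (measured between the
        open-phase edge and the 90%-of-peak crossings).
    plateau_fraction : float in [0, 1)
        Target fraction of the open phase at >= 90% of the peak.  A linear
        rise/fall alone already spends 10% of its ramps above the 90% level,
        so values below 0.1 degenerate to a triangular pulse with measured
        plateau quotient 0.1.
    amplitude : float > 0
        Peak displacement amplitude (area units after integration).
    """

    open_quotient: float = 0.6
    speed_quotient_target: float = 1.2
    plateau_fraction: float = 0.25
    amplitude: float = 1.0

    def validate(self):
        if not (0 < self.open_quotient <= 1):
            raise SpecValidationError("open_quotient must be in (0, 1]")
        if not (self.speed_quotient_target > 0):
            raise SpecValidationError("speed_quotient_target must be > 0")
        if not (0 <= self.plateau_fraction < 1):
            raise SpecValidationError("plateau_fraction must be in [0, 1)")
        if not (self.amplitude > 0):
            raise SpecValidationError("amplitude must be > 0")

    def segment_fractions(self) -> Tuple[float, float, float]:
        """(rise, flat, fall) durations as fractions of the open phase.

        Solved so that the measured 90%-crossing landmarks reproduce the
        speed-quotient and plateau-fraction targets:
        ``0.9 F / 0.9 R = SQ`` and ``0.1 R + L + 0.1 F = PQ * O``.
        """
        s = self.speed_quotient_target
        pf = max(self.plateau_fraction, 0.1)
        rise = (1.0 - pf) / (0.9 * (1.0 + s))
        fall = s * rise
        flat = 1.0 - rise - fall
        return rise, flat, fall


def _as_pulse(p) -> PulseShapeSpec:
    if p is None:
        return PulseShapeSpec()
    if isinstance(p, PulseShapeSpec):
        return p
    return PulseShapeSpec(**p)


@dataclass(frozen=True)
class RecordingSpec:
    """Full specification of one synthetic recording.

    ``jitter_pct_target``, ``shimmer_db_target`` and ``snr_db_target`` are
    the ground-truth values of Jit(%), MShim and SNR_K that a consistent
    estimator should recover in expectation.  ``phase_shift`` is the
    left-right phase shift in cycle fractions (right minus left, signed);
    ``lr_amplitude_ratio`` is the right/left peak amplitude ratio.
    ``ap_delay_open``/``ap_delay_close`` delay the open-phase onset/offset at
    the fold tips relative to mid-fold, in cycle fractions (signed; 0 means
    simultaneous along the fold).
    """

    f0: float = 150.0
    fs: float = 4000.0
    n_frames: int = 1000
    jitter_pct_target: float = 0.0
    shimmer_db_target: float = 0.0
    snr_db_target: Optional[float] = None
    phase_shift: float = 0.0
    lr_amplitude_ratio: float = 1.0
    ap_delay_open: float = 0.0
    ap_delay_close: float = 0.0
    n_positions: int = 64
    pulse: PulseShapeSpec = field(default_factory=PulseShapeSpec)
    pulse_right: Optional[PulseShapeSpec] = None
    seed: int = 0

    def validate(self):
        if not (self.f0 > 0):
            raise SpecValidationError("f0 must be > 0")
        if not (self.fs > 2 * self.f0):
            raise SpecValidationError("fs must exceed 2*f0")
        if self.n_frames < 3 * self.fs / self.f0:
            raise SpecValidationError("n_frames must cover at least 3 cycles")
        if self.n_positions < 8 or self.n_positions % 2:
            raise SpecValidationError("n_positions must be even and >= 8")
        if self.jitter_pct_target < 0:
            raise SpecValidationError("jitter_pct_target must be >= 0")
        if self.shimmer_db_target < 0:
            raise SpecValidationError("shimmer_db_target must be >= 0")
        if self.lr_amplitude_ratio <= 0:
            raise SpecValidationError("lr_amplitude_ratio must be > 0")
        if abs(self.phase_shift) > 0.5:
            raise SpecValidationError("phase_shift must be in [-0.5, 0.5]")
        for name in ("ap_delay_open", "ap_delay_close"):
            if abs(getattr(self, name)) > 0.25:
                raise SpecValidationError(f"{name} must be in [-0.25, 0.25]")
        _as_pulse(self.pulse).validate()
        if self.pulse_right is not None:
            _as_pulse(self.pulse_right).validate()
        oq = _as_pulse(self.pulse).open_quotient
        if oq + abs(self.ap_delay_close) + abs(self.ap_delay_open) > 0.98:
            raise SpecValidationError(
                "open_quotient plus anterior-posterior delays must leave a "
                "closed phase (sum <= 0.98)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "RecordingSpec":
        d = json.loads(s)
        d["pulse"] = PulseShapeSpec(**d["pulse"])
        if d.get("pulse_right") is not None:
            d["pulse_right"] = PulseShapeSpec(**d["pulse_right"])
        return cls(**d)

    @staticmethod
    def n_frames_for_cycles(n_cycles: int, f0: float,
                            fs: float = 4000.0) -> int:
        """Frame count covering ``n_cycles`` full cycles with margin."""
        return int(math.ceil((n_cycles + 2.5) * fs / f0))


@dataclass
class GlottalRecording:
    """A generated recording: displacement matrices plus derived GAWs.

    ``gaw_total == gaw_left + gaw_right`` exactly, and each partial GAW is
    the trapezoidal integration of the corresponding displacement matrix
    over the position axis (plus injected noise, if any).
    """

    disp_left: np.ndarray    # (n_positions, n_frames)
    disp_right: np.ndarray
    gaw_left: np.ndarray     # (n_frames,)
    gaw_right: np.ndarray
    gaw_total: np.ndarray
    fs: float
    truth: RecordingSpec

    @property
    def n_frames(self) -> int:
        return self.disp_left.shape[1]

    @property
    def n_positions(self) -> int:
        return self.disp_left.shape[0]


def integrate_displacement(disp: np.ndarray) -> np.ndarray:
    """Partial GAW: trapezoidal integration of midline distances over
    position (unit spacing)."""
    return np.trapezoid(disp, axis=0)


# Conversion constants: E|X_k - X_{k-1}| = 2 sigma / sqrt(pi) for iid
# N(0, sigma^2) values.
_JIT_TO_SIGMA = math.sqrt(math.pi) / 2.0 / 100.0
_MSHIM_TO_SIGMA = math.sqrt(math.pi) * math.log(10.0) / 40.0


def _pulse_matrix(u: np.ndarray, amp_row: np.ndarray, pulse: PulseShapeSpec,
                  h: np.ndarray, tau_open: float, tau_close: float,
                  g: np.ndarray) -> np.ndarray:
    """Evaluate the trapezoidal pulse on the (position, frame) grid.

    ``u`` is the within-cycle phase per frame, ``amp_row`` the per-frame
    cycle amplitude, ``h`` the normalized distance from mid-fold per
    position, ``g`` the spatial envelope.
    """
    onset = (tau_open * h)[:, None]                       # (P, 1)
    offset = (pulse.open_quotient + tau_close * h)[:, None]
    open_len = offset - onset
    if np.any(open_len <= 0):
        raise SpecValidationError(
            "ap_delay_open/ap_delay_close close the open phase at some "
            "positions")
    rf, _, ff = pulse.segment_fractions()
    rise = rf * open_len
    fall = ff * open_len

    out = np.zeros((h.size, u.size))
    # The pulse may straddle the cycle boundary when delays shift the onset
    # below 0; evaluate the phase at u and u +/- 1 and take the maximum.
    for shift in (-1.0, 0.0, 1.0):
        uu = u[None, :] + shift
        up = (uu - onset) / rise
        down = (offset - uu) / fall
        val = np.minimum(up, down)
        np.clip(val, 0.0, 1.0, out=val)
        np.maximum(out, val, out=out)
    out *= g[:, None]
    out *= amp_row[None, :]
    return out


def generate_recording(spec: RecordingSpec) -> GlottalRecording:
    """Generate one synthetic recording from its spec.

    Deterministic under ``spec.seed``.  Raises
    :class:`SpecValidationError` naming the offending field for an invalid
    spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    P = spec.n_positions
    T0 = 1.0 / spec.f0

    # Cycle sequence with one spare cycle before t=0 (for negative phase
    # shifts) and margin after the last frame.
    n_cycles = int(math.ceil(spec.n_frames / spec.fs / T0)) + 4
    sigma_t = spec.jitter_pct_target * _JIT_TO_SIGMA
    if sigma_t > 0:
        eta = rng.normal(0.0, sigma_t, n_cycles)
        np.clip(eta, -0.8, 0.8, out=eta)
    else:
        eta = np.zeros(n_cycles)
    periods = T0 * (1.0 + eta)
    bounds = np.concatenate([[0.0], np.cumsum(periods)])

    sigma_a = spec.shimmer_db_target * _MSHIM_TO_SIGMA
    if sigma_a > 0:
        amps = np.exp(rng.normal(0.0, sigma_a, n_cycles))
    else:
        amps = np.ones(n_cycles)

    # Continuous cycle coordinate; time origin one full cycle in so that
    # phi - phase_shift stays within the generated range.
    t = np.arange(spec.n_frames) / spec.fs + bounds[1]
    phi = np.interp(t, bounds, np.arange(n_cycles + 1))

    mid = (P - 1) / 2.0
    pos = np.arange(P)
    h = np.abs(pos - mid) / ((P - 1) / 2.0)
    g = np.sin(np.pi * (pos + 0.5) / P)

    pulse_l = _as_pulse(spec.pulse)
    pulse_r = _as_pulse(spec.pulse_right) if spec.pulse_right is not None \
        else pulse_l

    def side(pulse, shift, scale):
        v = phi - shift
        k = np.floor(v).astype(int)
        np.clip(k, 0, n_cycles - 1, out=k)
        u = v - k
        amp_row = amps[k] * pulse.amplitude * scale
        return _pulse_matrix(u, amp_row, pulse, h, spec.ap_delay_open,
                             spec.ap_delay_close, g)

    disp_left = side(pulse_l, 0.0, 1.0)
    disp_right = side(pulse_r, spec.phase_shift, spec.lr_amplitude_ratio)

    gaw_left = integrate_displacement(disp_left)
    gaw_right = integrate_displacement(disp_right)

    if spec.snr_db_target is not None:
        total = gaw_left + gaw_right
        e_ac = float(np.sum((total - total.mean()) ** 2))
        e_noise = e_ac / (10.0 ** (spec.snr_db_target / 10.0))
        sigma_n = math.sqrt(e_noise / spec.n_frames)
        # Independent noise on each partial GAW; variances add on the total.
        gaw_left = gaw_left + rng.normal(0.0, sigma_n / math.sqrt(2),
                                         spec.n_frames)
        gaw_right = gaw_right + rng.normal(0.0, sigma_n / math.sqrt(2),
                                           spec.n_frames)

    gaw_total = gaw_left + gaw_right
    return GlottalRecording(disp_left=disp_left, disp_right=disp_right,
                            gaw_left=gaw_left, gaw_right=gaw_right,
                            gaw_total=gaw_total, fs=spec.fs, truth=spec)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

#: distribution spec: ("uniform", lo, hi) | ("normal", mu, sd) | ("const", v)
Distribution = Tuple


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a group-structured cohort of recordings.

    ``distributions`` maps each group label to a mapping of
    :class:`RecordingSpec` field names to distributions over that field.
    ``n_cycles`` (optional) sizes each recording to cover that many cycles of
    its drawn f0 instead of using a fixed ``n_frames``.
    """

    n_per_group: Dict[str, int]
    distributions: Dict[str, Dict[str, Distribution]]
    base: RecordingSpec = field(default_factory=RecordingSpec)
    n_cycles: Optional[int] = None
    seed: int = 0

    def validate(self):
        if not self.n_per_group:
            raise SpecValidationError("n_per_group must not be empty")
        for grp, n in self.n_per_group.items():
            if n <= 0:
                raise SpecValidationError(f"n_per_group[{grp!r}] must be > 0")
            if grp not in self.distributions:
                raise SpecValidationError(
                    f"distributions missing group {grp!r}")


def _draw(dist: Distribution, rng) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "normal":
        return float(rng.normal(dist[1], dist[2]))
    if kind == "const":
        return float(dist[1])
    raise SpecValidationError(f"unknown distribution kind {kind!r}")


def iter_cohort(spec: CohortSpec):
    """Yield ``(GlottalRecording, group_label)`` lazily (constant memory)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    for grp in spec.n_per_group:                    # insertion order: stable
        dists = spec.distributions[grp]
        for _ in range(spec.n_per_group[grp]):
            fields = {k: _draw(d, rng) for k, d in dists.items()}
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            rec_spec = dataclasses.replace(spec.base, seed=sub_seed, **fields)
            if spec.n_cycles is not None:
                nf = RecordingSpec.n_frames_for_cycles(
                    spec.n_cycles, rec_spec.f0, rec_spec.fs)
                rec_spec = dataclasses.replace(rec_spec, n_frames=nf)
            yield generate_recording(rec_spec), grp


def generate_cohort(spec: CohortSpec) -> List[Tuple[GlottalRecording, str]]:
    """Materialize the whole cohort as a list (see :func:`iter_cohort`)."""
    return list(iter_cohort(spec))


# --------------------------------------------------------------------------
# Feature-table sampler calibrated to printed per-group statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupFeatureStats:
    """Per-group mean/std for the 12 final-subset parameters.

    ``stats[group][parameter] = (mean, std)``.
    """

    stats: Dict[str, Dict[str, Tuple[float, float]]]

    def validate(self):
        want = set(HSV2_PARAMETERS)
        for grp, pars in self.stats.items():
            if set(pars) != want:
                raise SpecValidationError(
                    f"group {grp!r} must provide exactly the 12 final-subset "
                    "parameters")
            for p, (_, sd) in pars.items():
                if sd < 0:
                    raise SpecValidationError(f"std of {p!r} in {grp!r} < 0")


# Published per-group means/stds of the 12 final-subset parameters for
# healthy/functionally-dysphonic female/male cohorts (N_F, FD_F, N_M, FD_M).
_TBL = {
    "CA^L,OP [Mean]":  ((100.8, 12.9), (99.9, 15.8), (96.9, 17.2), (80.9, 16.3)),
    "CA^R,CA [Mean]":  ((87.6, 5.9),   (87.7, 9.4),  (83.1, 9.1),  (78.5, 8.6)),
    "CAS^OA [Mean]":   ((0.976, 0.141), (1.001, 0.154), (0.995, 0.084), (1.020, 0.103)),
    "CASI^OA [Mean]":  ((0.883, 0.070), (0.880, 0.073), (0.933, 0.045), (0.923, 0.049)),
    "CASI^CA [Mean]":  ((0.934, 0.035), (0.904, 0.061), (0.921, 0.044), (0.902, 0.048)),
    "CA^L,CA [Std]":   ((3.4, 1.7),    (4.3, 3.0),   (2.9, 1.6),   (4.0, 1.7)),
    "CA^R,CA [Std]":   ((3.4, 1.8),    (4.4, 2.1),   (3.1, 1.5),   (3.3, 1.0)),
    "CA^R,CP [Std]":   ((6.6, 4.3),    (6.5, 5.1),   (5.3, 6.5),   (2.9, 2.1)),
    "SNR_K [Mean]":    ((11.2, 1.4),   (10.5, 1.6),  (11.1, 1.3),  (11.0, 1.4)),
    "PhA [Mean]":      ((-0.031, 0.080), (0.001, 0.113), (-0.001, 0.078), (-0.011, 0.092)),
    "SQ [Std]":        ((0.151, 0.065), (0.174, 0.085), (0.155, 0.057), (0.165, 0.100)),
    "PQ [Std]":        ((0.047, 0.011), (0.052, 0.014), (0.043, 0.013), (0.051, 0.018)),
}
_GROUPS = ("N_F", "FD_F", "N_M", "FD_M")

#: Default :class:`GroupFeatureStats` with the published group statistics.
TABLE_GROUP_STATS = GroupFeatureStats(
    {g: {p: _TBL[p][i] for p in _TBL} for i, g in enumerate(_GROUPS)})

#: Synthetic age ranges per group (years).  The clinical age structure is not
#: modeled; healthy groups skew younger, disordered older, as in typical
#: clinical cohorts.
_AGE_RANGES = {"N_F": (20, 40), "FD_F": (25, 65),
               "N_M": (20, 40), "FD_M": (25, 65)}


def sample_feature_table(stats: GroupFeatureStats = TABLE_GROUP_STATS,
                         n_per_group=None, seed: int = 0):
    """Draw a subject-level feature table from per-group Gaussian marginals.

    Each parameter is drawn independently per group from
    ``N(mean, std^2)`` and clipped to its registry domain (angles
    unconstrained, symmetry indices to [0, 1.5], Std-type parameters at 0).
    The marginal statistics are the only published calibration; correlations
    between parameters are not modeled (independence is a documented
    limitation).

    Returns a :class:`phonovib.tables.FeatureTable`.
    """
    from .tables import FeatureTable
    import pandas as pd

    stats.validate()
    if n_per_group is None:
        n_per_group = {g: 30 for g in stats.stats}
    rng = np.random.default_rng(seed)
    rows = []
    params = [p for p in REGISTRY.abbreviations
              if p in next(iter(stats.stats.values()))]
    sid = 0
    for grp, n in n_per_group.items():
        if n <= 0:
            raise SpecValidationError(f"n_per_group[{grp!r}] must be > 0")
        if grp not in stats.stats:
            raise SpecValidationError(f"no stats for group {grp!r}")
        sex = "F" if grp.endswith("_F") else "M"
        lo, hi = _AGE_RANGES.get(grp, (20, 65))
        ages = rng.uniform(lo, hi, n)
        cols = {}
        for p in params:
            mu, sd = stats.stats[grp][p]
            cols[p] = REGISTRY.clip_to_domain(p, rng.normal(mu, sd, n))
        for i in range(n):
            row = {"subject_id": f"S{sid:04d}", "group": grp, "sex": sex,
                   "age": float(ages[i])}
            row.update({p: float(cols[p][i]) for p in params})
            rows.append(row)
            sid += 1
    data = pd.DataFrame(rows)
    return FeatureTable(data=data, parameters=params)


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def save_recording(rec: GlottalRecording, path):
    """Persist a recording as an NPZ bundle (truth spec embedded as JSON)."""
    np.savez_compressed(
        path, disp_left=rec.disp_left, disp_right=rec.disp_right,
        gaw_left=rec.gaw_left, gaw_right=rec.gaw_right,
        gaw_total=rec.gaw_total, fs=rec.fs,
        truth=np.frombuffer(rec.truth.to_json().encode(), dtype=np.uint8))


def load_recording(path) -> GlottalRecording:
    with np.load(path) as z:
        truth = RecordingSpec.from_json(bytes(z["truth"].tobytes()).decode())
        return GlottalRecording(
            disp_left=z["disp_left"], disp_right=z["disp_right"],
            gaw_left=z["gaw_left"], gaw_right=z["gaw_right"],
            gaw_total=z["gaw_total"], fs=float(z["fs"]), truth=truth)
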