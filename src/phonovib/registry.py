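"""Registry of the 91 vibration parameters extracted from high-speed recordings.

The registry is the single source of truth for parameter names, families,
cycle conventions, units and valid domains.  Downstream code (feature
extraction, pruning, the selection pipeline, the cohort sampler) looks
parameters up here rather than hard-coding definitions, so a definition can
be corrected in one place.

Families
--------
``gaw_t``
    41 parameters computed from the total glottal area waveform: fundamental
    frequency statistics, period/amplitude/energy perturbation families
    (jitter, shimmer and their k-point quotients), spectral harmonics-to-noise
    ratio, pulse-shape quotients and plain waveform statistics.
``symmetry``
    18 left-right symmetry parameters computed from the two partial waveforms
    (phase shift, amplitude/dynamic-range/energy asymmetries, waveform
    similarity), each as signed and index (bounded) variants.
``pvg``
    32 phonovibrogram contour-angle parameters: per-fold opening/closing
    angles on the anterior and posterior halves, and their left-right
    symmetry ratios/indices.

Cycle convention: all parameters use maximum-based cycles except the four
phase-shift entries (PhA/PhAI mean and std), which need minimum-based cycles
so that the waveform peaks lie in the interior of each analysis window.

Several exact per-parameter definitions are not fixed by any published
formula table and are reconstructed from the standard voice-perturbation
literature; those entries carry ``source='reconstruction'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "ParameterEntry",
    "ParameterRegistry",
    "REGISTRY",
    "HSV2_PARAMETERS",
]


@dataclass(frozen=True)
class ParameterEntry:
    """One row of the parameter registry."""

    abbreviation: str
    family: str              # 'gaw_t' | 'symmetry' | 'pvg'
    statistic: str           # 'mean' | 'std' | 'scalar'
    cycle_mode: str          # 'maximum' | 'minimum'
    units: str
    description: str
    source: str              # 'standard' | 'reconstruction'
    # Valid domain used when sampling synthetic feature tables; None = unbounded.
    domain: Tuple[Optional[float], Optional[float]] = (None, None)
    # True if the parameter is invariant under uniform amplitude scaling.
    scale_invariant: bool = False


def _e(abbr, family, statistic, units, desc, source="standard",
       cycle_mode="maximum", domain=(None, None), scale_invariant=False):
    return ParameterEntry(abbr, family, statistic, cycle_mode, units, desc,
                          source, domain, scale_invariant)


def _build_entries():
    E = []

    # ------------------------------------------------------------------ GAW_T
    E += [
        _e("F0 [Mean]", "gaw_t", "mean", "Hz",
           "Mean fundamental frequency, 1/T_k averaged over cycles.",
           scale_invariant=True),
        _e("F0 [Std]", "gaw_t", "std", "Hz",
           "Standard deviation of per-cycle fundamental frequency.",
           scale_invariant=True),
        _e("TP [Mean]", "gaw_t", "mean", "s",
           "Time perturbation: mean absolute consecutive period difference "
           "|T_k - T_{k-1}|.", scale_invariant=True),
        _e("TP [Std]", "gaw_t", "std", "s",
           "Standard deviation of absolute consecutive period differences.",
           scale_invariant=True),
        _e("AP [Mean]", "gaw_t", "mean", "a.u.",
           "Amplitude perturbation: mean absolute consecutive cycle-peak "
           "difference |A_k - A_{k-1}| (amplitude units, not scale "
           "invariant)."),
        _e("AP [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of absolute consecutive amplitude "
           "differences."),
        _e("EP [Mean]", "gaw_t", "mean", "a.u.",
           "Energy perturbation: mean absolute consecutive cycle-energy "
           "difference |E_k - E_{k-1}|."),
        _e("EP [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of absolute consecutive energy differences."),
        _e("Jit(%)", "gaw_t", "scalar", "%",
           "Relative jitter: 100 * mean|T_k - T_{k-1}| / mean T.",
           domain=(0.0, None), scale_invariant=True),
        _e("RAP_K", "gaw_t", "scalar", "%",
           "Three-point relative average perturbation of the period "
           "(numerically identical to PPQ3, kept as a separate registry "
           "entry by convention).", domain=(0.0, None), scale_invariant=True),
        _e("PPQ3", "gaw_t", "scalar", "%",
           "3-point period perturbation quotient: 100 * mean|T_k - MA3(T)_k| "
           "/ mean T.", domain=(0.0, None), scale_invariant=True),
        _e("PPQ5", "gaw_t", "scalar", "%",
           "5-point period perturbation quotient.", domain=(0.0, None),
           scale_invariant=True),
        _e("PPQ11", "gaw_t", "scalar", "%",
           "11-point period perturbation quotient.", domain=(0.0, None),
           scale_invariant=True),
        _e("PPF", "gaw_t", "scalar", "%",
           "Period perturbation factor: 100 * mean(|T_k - T_{k-1}| / "
           "T_{k-1}).", source="reconstruction", domain=(0.0, None),
           scale_invariant=True),
        _e("vF0", "gaw_t", "scalar", "%",
           "Fundamental frequency variation: 100 * std(F0_k) / mean(F0_k).",
           source="reconstruction", domain=(0.0, None), scale_invariant=True),
        _e("APQ3", "gaw_t", "scalar", "%",
           "3-point amplitude perturbation quotient: 100 * mean|A_k - "
           "MA3(A)_k| / mean A.", domain=(0.0, None), scale_invariant=True),
        _e("APQ5", "gaw_t", "scalar", "%",
           "5-point amplitude perturbation quotient.", domain=(0.0, None),
           scale_invariant=True),
        _e("APQ11", "gaw_t", "scalar", "%",
           "11-point amplitude perturbation quotient.", domain=(0.0, None),
           scale_invariant=True),
        _e("MShim", "gaw_t", "scalar", "dB",
           "Mean shimmer in dB: mean |20 log10(A_{k+1}/A_k)|.",
           domain=(0.0, None), scale_invariant=True),
        _e("Shim(%)", "gaw_t", "scalar", "%",
           "Relative shimmer: 100 * mean|A_k - A_{k-1}| / mean A.",
           domain=(0.0, None), scale_invariant=True),
        _e("APF", "gaw_t", "scalar", "%",
           "Amplitude perturbation factor: 100 * mean(|A_k - A_{k-1}| / "
           "A_{k-1}).", source="reconstruction", domain=(0.0, None),
           scale_invariant=True),
        _e("EPQ3", "gaw_t", "scalar", "%",
           "3-point energy perturbation quotient.", source="reconstruction",
           domain=(0.0, None), scale_invariant=True),
        _e("EPQ5", "gaw_t", "scalar", "%",
           "5-point energy perturbation quotient.", source="reconstruction",
           domain=(0.0, None), scale_invariant=True),
        _e("EPQ11", "gaw_t", "scalar", "%",
           "11-point energy perturbation quotient.", source="reconstruction",
           domain=(0.0, None), scale_invariant=True),
        _e("EPF", "gaw_t", "scalar", "%",
           "Energy perturbation factor: 100 * mean(|E_k - E_{k-1}| / "
           "E_{k-1}).", source="reconstruction", domain=(0.0, None),
           scale_invariant=True),
        _e("SNR_K [Mean]", "gaw_t", "mean", "dB",
           "Harmonics-to-noise energy ratio of the waveform spectrum over "
           "the full cycle-aligned segment.", scale_invariant=True),
        _e("SNR_K [Std]", "gaw_t", "std", "dB",
           "Standard deviation of the harmonics-to-noise ratio over "
           "consecutive 16-cycle blocks.", source="reconstruction",
           domain=(0.0, None), scale_invariant=True),
        _e("SQ [Mean]", "gaw_t", "mean", "a.u.",
           "Speed quotient: per-cycle closing/opening duration ratio, "
           "averaged. Note much literature uses the inverse "
           "(opening/closing).", domain=(0.0, None), scale_invariant=True),
        _e("SQ [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of the per-cycle speed quotient.",
           domain=(0.0, None), scale_invariant=True),
        _e("PQ [Mean]", "gaw_t", "mean", "a.u.",
           "Plateau quotient ('peakiness'): fraction of the open phase at "
           ">= 90% of the cycle peak, averaged.", domain=(0.0, 1.0),
           scale_invariant=True),
        _e("PQ [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of the per-cycle plateau quotient.",
           domain=(0.0, None), scale_invariant=True),
        _e("OQ [Mean]", "gaw_t", "mean", "a.u.",
           "Open quotient: open-phase duration / cycle duration, averaged.",
           domain=(0.0, 1.0), scale_invariant=True),
        _e("OQ [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of the per-cycle open quotient.",
           domain=(0.0, None), scale_invariant=True),
        _e("GA [Mean]", "gaw_t", "mean", "a.u.",
           "Mean glottal area over all frames.", source="reconstruction"),
        _e("GA [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of the glottal area over all frames.",
           source="reconstruction"),
        _e("A [Mean]", "gaw_t", "mean", "a.u.",
           "Mean per-cycle peak amplitude.", source="reconstruction"),
        _e("A [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of per-cycle peak amplitudes.",
           source="reconstruction"),
        _e("DyR [Mean]", "gaw_t", "mean", "a.u.",
           "Mean per-cycle dynamic range (max - min).",
           source="reconstruction"),
        _e("DyR [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of per-cycle dynamic ranges.",
           source="reconstruction"),
        _e("E [Mean]", "gaw_t", "mean", "a.u.",
           "Mean per-cycle energy (sum of squared samples).",
           source="reconstruction"),
        _e("E [Std]", "gaw_t", "std", "a.u.",
           "Standard deviation of per-cycle energies.",
           source="reconstruction"),
    ]

    # --------------------------------------------------------------- symmetry
    sym = [
        ("PhA", "Signed left-right phase shift of the waveform peaks in "
         "cycle fractions, wrapped to (-0.5, 0.5].", "minimum",
         (-0.5, 0.5)),
        ("PhAI", "Absolute left-right phase shift |lag_k| in cycle "
         "fractions.", "minimum", (0.0, 0.5)),
        ("AmS", "Signed amplitude asymmetry (A_R - A_L)/max(A_R, A_L).",
         "maximum", (-1.0, 1.0)),
        ("AmSI", "Amplitude symmetry index min(A_L, A_R)/max(A_L, A_R).",
         "maximum", (0.0, 1.5)),
        ("DyRS", "Signed dynamic-range asymmetry of the two folds.",
         "maximum", (-1.0, 1.0)),
        ("DyRSI", "Dynamic-range symmetry index (min/max).", "maximum",
         (0.0, 1.5)),
        ("SpA", "Signed per-cycle energy asymmetry of the two folds.",
         "maximum", (-1.0, 1.0)),
        ("SpAI", "Per-cycle energy symmetry index (min/max).", "maximum",
         (0.0, 1.5)),
        ("WaSI", "Waveform similarity: per-cycle normalized zero-lag "
         "cross-correlation of the mean-removed partial waveforms.",
         "maximum", (-1.0, 1.0)),
    ]
    for abbr, desc, mode, dom in sym:
        for stat in ("Mean", "Std"):
            d = dom if stat == "Mean" else (0.0, None)
            E.append(_e(f"{abbr} [{stat}]", "symmetry", stat.lower(), "a.u.",
                        desc + (f" ({stat} over cycles.)"),
                        source="reconstruction", cycle_mode=mode, domain=d,
                        scale_invariant=True))

    # -------------------------------------------------------------------- PVG
    phase_region = ("OA", "OP", "CA", "CP")
    pr_desc = {"OA": "opening phase, anterior half",
               "OP": "opening phase, posterior half",
               "CA": "closing phase, anterior half",
               "CP": "closing phase, posterior half"}
    for side in ("L", "R"):
        for pr in phase_region:
            for stat in ("Mean", "Std"):
                dom = (0.0, 180.0) if stat == "Mean" else (0.0, None)
                E.append(_e(
                    f"CA^{side},{pr} [{stat}]", "pvg", stat.lower(), "deg",
                    f"Contour angle of the {'left' if side == 'L' else 'right'} "
                    f"fold, {pr_desc[pr]}; 90 deg = simultaneous "
                    f"opening/closing along the fold half. {stat} over "
                    "cycles.", source="reconstruction", domain=dom,
                    scale_invariant=True))
    for pr in phase_region:
        for stat in ("Mean", "Std"):
            dom = (0.0, 1.5) if stat == "Mean" else (0.0, None)
            E.append(_e(
                f"CAS^{pr} [{stat}]", "pvg", stat.lower(), "a.u.",
                f"Signed contour-angle symmetry CA^L/CA^R for {pr_desc[pr]}; "
                f"{stat} over cycles.", source="reconstruction", domain=dom,
                scale_invariant=True))
            E.append(_e(
                f"CASI^{pr} [{stat}]", "pvg", stat.lower(), "a.u.",
                f"Contour-angle symmetry index min/max of the L/R pair for "
                f"{pr_desc[pr]}; {stat} over cycles.",
                source="reconstruction", domain=dom, scale_invariant=True))
    return E


class ParameterRegistry:
    """Ordered, validated collection of :class:`ParameterEntry` rows."""

    def __init__(self, entries=None):
        self.entries = list(entries if entries is not None else _build_entries())
        self._by_abbr = {e.abbreviation: e for e in self.entries}
        if len(self._by_abbr) != len(self.entries):
            raise ValueError("duplicate abbreviations in registry")
        self._validate()

    def _validate(self):
        counts = {"gaw_t": 0, "symmetry": 0, "pvg": 0}
        for e in self.entries:
            counts[e.family] += 1
        expected = {"gaw_t": 41, "symmetry": 18, "pvg": 32}
        if counts != expected:
            raise ValueError(f"registry family counts {counts} != {expected}")
        min_based = {e.abbreviation for e in self.entries
                     if e.cycle_mode == "minimum"}
        if min_based != {"PhA [Mean]", "PhA [Std]", "PhAI [Mean]",
                         "PhAI [Std]"}:
            raise ValueError("only the four PhA/PhAI entries may be "
                             "minimum-based")

    def __len__(self):
        return len(self.entries)

    def __contains__(self, abbr):
        return abbr in self._by_abbr

    def __getitem__(self, abbr) -> ParameterEntry:
        try:
            return self._by_abbr[abbr]
        except KeyError:
            raise KeyError(f"unknown parameter {abbr!r}") from None

    @property
    def abbreviations(self):
        return [e.abbreviation for e in self.entries]

    def family(self, name):
        """All abbreviations of one family, in registry order."""
        return [e.abbreviation for e in self.entries if e.family == name]

    def clip_to_domain(self, abbr, values):
        """Clip an array of sampled values to the parameter's valid domain."""
        import numpy as np
        lo, hi = self[abbr].domain
        return np.clip(values, -np.inf if lo is None else lo,
                       np.inf if hi is None else hi)


#: The default 91-parameter registry.
REGISTRY = ParameterRegistry()

#: The 12-parameter final subset whose per-group statistics are tabulated for
#: healthy/dysphonic female/male cohorts (used by the cohort feature sampler).
HSV2_PARAMETERS = [
    "CA^L,OP [Mean]",
    "CA^R,CA [Mean]",
    "CAS^OA [Mean]",
    "CASI^OA [Mean]",
    "CASI^CA [Mean]",
    "CA^L,CA [Std]",
    "CA^R,CA [Std]",
    "CA^R,CP [Std]",
    "SNR_K [Mean]",
    "PhA [Mean]",
    "SQ [Std]",
    "PQ [Std]",
]
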