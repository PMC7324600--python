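"""Shared fixtures: synthetic recordings and cohort feature tables.

Session-scoped cohorts are generated once and reused across modules to keep
the suite fast; everything is seeded and deterministic.
"""

import numpy as np
import pytest

from phonovib.cycles import detect_cycles
from phonovib.features import (cycle_series, perturbation_features,
                               extract_feature_table)
from phonovib.synth import (CohortSpec, RecordingSpec, generate_recording,
                            iter_cohort)


@pytest.fixture(scope="session")
def plain_recording():
    """Unperturbed, symmetric recording (1000 frames, f0=150)."""
    return generate_recording(RecordingSpec(f0=150.0, seed=0))


@pytest.fixture(scope="session")
def perturbed_recording():
    """Recording with jitter, shimmer and left-right asymmetry."""
    spec = RecordingSpec(
        f0=150.0, jitter_pct_target=2.0, shimmer_db_target=0.4,
        phase_shift=0.08, lr_amplitude_ratio=0.85, ap_delay_open=0.06,
        ap_delay_close=-0.04,
        n_frames=RecordingSpec.n_frames_for_cycles(60, 150.0), seed=42)
    return generate_recording(spec)


def _perturbation_cohort_spec(seed):
    """100 recordings, 200 cycles each, with varied jitter/shimmer/f0."""
    return CohortSpec(
        n_per_group={"A": 100},
        distributions={"A": {
            "jitter_pct_target": ("uniform", 0.5, 5.0),
            "shimmer_db_target": ("uniform", 0.1, 1.0),
            "f0": ("uniform", 100.0, 300.0)}},
        n_cycles=200, seed=seed)


PERTURBATION_PARAMS = ["Jit(%)", "PPQ3", "PPQ5", "PPQ11",
                       "APQ3", "APQ5", "APQ11", "MShim"]


@pytest.fixture(scope="session")
def perturbation_cohort():
    """Perturbation-family features plus generator truth for 100
    recordings (the redundancy-analysis cohort)."""
    rows, truth = [], []
    for rec, _ in iter_cohort(_perturbation_cohort_spec(seed=1)):
        cyc = detect_cycles(rec.gaw_total, rec.fs, "maximum")
        pf = perturbation_features(cycle_series(rec.gaw_total, cyc))
        rows.append([pf[k] for k in PERTURBATION_PARAMS])
        truth.append((rec.truth.jitter_pct_target,
                      rec.truth.shimmer_db_target, rec.truth.f0))
    return np.asarray(rows), np.asarray(truth)


@pytest.fixture(scope="session")
def extracted_table():
    """Full 91-parameter feature table extracted from a varied 30-recording
    cohort (two nominal groups)."""
    spec = CohortSpec(
        n_per_group={"N_F": 15, "FD_F": 15},
        distributions={
            "N_F": {"jitter_pct_target": ("uniform", 0.3, 1.5),
                    "shimmer_db_target": ("uniform", 0.1, 0.4),
                    "f0": ("uniform", 160.0, 280.0),
                    "phase_shift": ("normal", 0.0, 0.02),
                    "ap_delay_open": ("normal", 0.03, 0.02)},
            "FD_F": {"jitter_pct_target": ("uniform", 1.0, 4.0),
                     "shimmer_db_target": ("uniform", 0.3, 1.0),
                     "f0": ("uniform", 140.0, 260.0),
                     "phase_shift": ("normal", 0.0, 0.06),
                     "lr_amplitude_ratio": ("uniform", 0.75, 1.0),
                     "ap_delay_open": ("normal", 0.06, 0.04)}},
        n_cycles=60, seed=11)
    recs, groups = [], []
    for rec, grp in iter_cohort(spec):
        recs.append(rec)
        groups.append(grp)
    ages = np.random.default_rng(3).uniform(20, 60, len(recs))
    return extract_feature_table(recs, groups, ages=ages,
                                 sexes=["F"] * len(recs))
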