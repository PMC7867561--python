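"""Synthetic cohorts with the statistical structure the analysis assumes.

The raw fMRI behind the study is not deposited, so end-to-end validation
runs on simulated cohorts instead: clinical covariates drawn within the
observed PANSS-8 item ranges, ground-truth connectivity that varies linearly
with a symptom covariate across subjects, band-limited endogenous
fluctuations driving the two-state neural model, hemodynamic filtering, and
additive white observation noise.  The default ground truth mirrors the
qualitative published pattern — positive-symptom load increases within-region
inhibitory (GABAergic) tone and decreases between-region excitatory
(glutamatergic) influence — so that recovery tests exercise exactly the
effect structure the analysis is meant to detect.  All output is synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft
import scipy.linalg
import scipy.signal

from .clinical import PANSSRecord, build_design_matrix
from .model import (
    ConnectionParams,
    FixedNeuralParams,
    HRFParams,
    NoiseParams,
    system_jacobian,
)
from .preprocess import TimeSeriesData

__all__ = [
    "SyntheticTruth",
    "generate_clinical",
    "generate_subject_series",
    "generate_cohort",
    "perturb_csd",
]

# Observed per-item score ranges of the study's printed clinical table.
_ITEM_RANGES = {
    "p1": (4, 7), "p2": (1, 6), "p3": (1, 6),
    "n1": (1, 5), "n4": (1, 5), "n6": (1, 4),
    "g5": (1, 4), "g9": (2, 6),
}
_NO_MEDICATION_FRACTION = 0.4
_DUP_RANGE_MONTHS = (1, 72)
_DUP_MISSING_FRACTION = 0.1

#: Default second-level effects (log-units per centred covariate point), in
#: connection order (IE within DLPFC, EE STR->DLPFC, EE DLPFC->STR, IE
#: within STR): symptoms raise inhibition, lower between-region excitation.
_DEFAULT_COVARIATE_EFFECT = np.array([0.1, -0.1, -0.1, 0.1])


def _default_beta() -> np.ndarray:
    beta = np.zeros((4, 4))
    beta[1] = _DEFAULT_COVARIATE_EFFECT
    return beta


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating second-level parameters for a synthetic cohort.

    ``beta`` has one row per design regressor of ``model_name``'s design
    (constant, covariate, medication, DUP) and one column per connection.
    """

    beta: np.ndarray = field(default_factory=_default_beta)
    subject_sd: float = 0.1
    noise_scale: float = 1.0
    seed: int = 0
    model_name: str = "total positive"

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if b.ndim != 2 or b.shape[1] != 4:
            raise ValueError("beta must be (n_regressors, 4)")
        if self.subject_sd < 0 or self.noise_scale < 0:
            raise ValueError("dispersions must be non-negative")
        object.__setattr__(self, "beta", b)


def generate_clinical(n: int, seed: int) -> list[PANSSRecord]:
    """Sample a synthetic clinical table within the observed item ranges."""
    if n < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        items = {k: int(rng.integers(lo, hi + 1))
                 for k, (lo, hi) in _ITEM_RANGES.items()}
        medicated = int(rng.random() >= _NO_MEDICATION_FRACTION)
        dup = None if rng.random() < _DUP_MISSING_FRACTION else \
            float(rng.integers(*_DUP_RANGE_MONTHS))
        records.append(PANSSRecord(subject_id=str(i + 1), **items,
                                   medication=medicated, dup_months=dup))
    return records


def generate_subject_series(theta: ConnectionParams,
                            noise_scale: float = 1.0,
                            n_timepoints: int = 360,
                            tr: float = 1.0,
                            seed: int = 0,
                            fixed: FixedNeuralParams = FixedNeuralParams(),
                            noise: NoiseParams = NoiseParams(),
                            hrf: HRFParams = HRFParams(),
                            dt: float = 0.1,
                            band: tuple[float, float] = (0.0078, 0.1),
                            burn_in_s: float = 64.0) -> TimeSeriesData:
    """Simulate one subject's two-region BOLD series.

    Band-limited power-law fluctuations are synthesized in the frequency
    domain (band padded by 0.004 Hz on each side so band-edge power is not
    attenuated by leakage), integrated through the linearized neural system
    with an Euler scheme at step ``dt``, convolved with the hemodynamic
    kernel, decimated to the repetition time, and corrupted with white
    observation noise of one-sided density ``noise.alpha_obs *
    noise_scale**2``.
    """
    A = system_jacobian(theta, fixed)  # raises UnstableModelError if needed
    rng = np.random.default_rng(seed)
    total_s = n_timepoints * tr + burn_in_s
    n_sim = scipy.fft.next_fast_len(int(np.ceil(total_s / dt)), real=True)
    n_sim += n_sim % 2

    # frequency-domain synthesis of the endogenous fluctuations
    f = np.fft.rfftfreq(n_sim, dt)
    pad = 0.004
    lo = max(band[0] - pad, 1e-4)
    hi = band[1] + pad
    in_band = (f >= lo) & (f <= hi)
    S_one = np.zeros_like(f)
    S_one[in_band] = noise.neural_density(f[in_band])
    # E|X_k|^2 must equal S_one * n / (2 dt) for a one-sided density S_one;
    # the complex deviate below has E|z|^2 = 2, hence the factor 4.
    amp = np.sqrt(S_one * n_sim / (4.0 * dt))
    u = np.empty((n_sim, 2))
    for ch in range(2):
        spec = amp * (rng.standard_normal(f.size)
                      + 1j * rng.standard_normal(f.size))
        spec[0] = 0.0
        u[:, ch] = np.fft.irfft(spec, n=n_sim)

    # exact zero-order-hold discretization of dx/dt = A x + B u:
    # x[t+1] = expm(A dt) x[t] + A^-1 (expm(A dt) - I) B u[t],
    # integrated mode-by-mode with first-order IIR filters.
    M = scipy.linalg.expm(A * dt)
    N = np.linalg.solve(A, M - np.eye(4))
    lam, V = np.linalg.eig(M)
    T = np.linalg.solve(V, N)[:, [0, 2]]     # input coupling, E states only
    w = u @ T.T.real + 1j * (u @ T.T.imag)   # modal inputs, (n_sim, 4)
    z = np.empty_like(w)
    for k in range(4):
        z[:, k] = scipy.signal.lfilter([1.0], [1.0, -lam[k]], w[:, k])
    e_states = (z @ V[[0, 2], :].T).real

    # hemodynamic convolution on the HRF's dense grid resampled to dt
    t_h, h = hrf.kernel()
    h_dt = np.interp(np.arange(0.0, hrf.duration_s, dt), t_h, h)
    bold = np.empty_like(e_states)
    for ch in range(2):
        bold[:, ch] = scipy.signal.fftconvolve(e_states[:, ch], h_dt)[:n_sim] * dt

    step = int(round(tr / dt))
    start = int(round(burn_in_s / dt))
    sampled = bold[start:start + n_timepoints * step:step]
    if sampled.shape[0] < n_timepoints:
        raise RuntimeError("simulation shorter than requested output")

    obs_sd = noise_scale * np.sqrt(noise.alpha_obs / (2.0 * tr))
    sampled = sampled + obs_sd * rng.standard_normal(sampled.shape)
    return TimeSeriesData(sampled, tr_seconds=tr)


def perturb_csd(csd, rel_sd: float, seed: int = 0):
    """Add Hermitian sampling-style noise to a cross-spectral density.

    Every entry is perturbed with independent Gaussian noise of standard
    deviation ``rel_sd * sqrt(S11(f) S22(f))`` — the scale of a spectral
    estimate's sampling error with ``1/rel_sd**2`` averaged segments — and
    each matrix is floored back to positive semidefiniteness.  Used to
    validate the inverter at a controlled data-feature noise level,
    independent of record length.
    """
    from .model import CrossSpectralData

    rng = np.random.default_rng(seed)
    S = csd.csd.copy()
    scale = rel_sd * np.sqrt(S[:, 0, 0].real * S[:, 1, 1].real)
    S[:, 0, 0] += scale * rng.standard_normal(scale.size)
    S[:, 1, 1] += scale * rng.standard_normal(scale.size)
    S[:, 0, 1] += scale * (rng.standard_normal(scale.size)
                           + 1j * rng.standard_normal(scale.size)) / np.sqrt(2)
    S[:, 1, 0] = np.conj(S[:, 0, 1])
    for i in range(S.shape[0]):
        w, V = np.linalg.eigh(S[i])
        S[i] = (V * np.maximum(w, 1e-10)) @ V.conj().T
    return CrossSpectralData(csd.freqs, S, region_names=csd.region_names)


def generate_cohort(truth: SyntheticTruth, n: int = 19,
                    n_timepoints: int = 360, tr: float = 1.0,
                    fixed: FixedNeuralParams = FixedNeuralParams(),
                    noise: NoiseParams = NoiseParams(),
                    hrf: HRFParams = HRFParams()):
    """Generate a full synthetic study.

    Returns ``(records, series_list, true_thetas)`` where ``true_thetas``
    has shape (n, 4): each subject's connectivity parameters are the design
    row (built exactly as the analysis builds it, centred covariates and
    imputed DUP) times ``truth.beta`` plus N(0, subject_sd^2) dispersion.
    """
    seeds = np.random.SeedSequence(truth.seed).generate_state(2 * n + 1) % (2 ** 31)
    records = generate_clinical(n, int(seeds[0]))
    design = build_design_matrix(records, truth.model_name)
    X = design.values
    if truth.beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"truth.beta has {truth.beta.shape[0]} rows but the "
            f"{truth.model_name!r} design has {X.shape[1]} columns")
    thetas = np.empty((n, 4))
    series = []
    for i in range(n):
        rng_i = np.random.default_rng(int(seeds[1 + 2 * i]))
        thetas[i] = X[i] @ truth.beta + truth.subject_sd * rng_i.standard_normal(4)
        series.append(generate_subject_series(
            ConnectionParams.from_array(thetas[i]),
            noise_scale=truth.noise_scale,
            n_timepoints=n_timepoints, tr=tr,
            seed=int(seeds[2 + 2 * i]),
            fixed=fixed, noise=noise, hrf=hrf))
    return records, series, thetas
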