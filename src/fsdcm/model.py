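"""Two-region, two-state neural generative model and its BOLD cross-spectra.

Each region (left DLPFC "f", left striatum "s") contains one excitatory (E)
and one inhibitory (I) population.  Four connectivity parameters are free and
are estimated as log scale factors on fixed default strengths:

* between-region excitatory (glutamatergic) influences E_f -> E_s and
  E_s -> E_f, default strength +1/8 Hz;
* within-region inhibitory (GABAergic) influences I -> E, default strength
  -1/8 Hz.

A log-scaling parameterization ``strength = +/- (1/8) exp(theta)`` enforces
the sign of every connection: between-region connections stay excitatory and
within-region connections stay inhibitory for any finite theta.  The E -> I
gain and both self-decays are fixed (never estimated).

Linearizing around the fixed point gives a 4x4 Jacobian A with state order
(E_f, I_f, E_s, I_s).  Endogenous fluctuations u (power-law spectrum
``alpha f^-beta``) drive the excitatory states; measured BOLD is the
hemodynamically filtered excitatory activity plus white observation noise.
The model therefore predicts, per frequency f on the analysis band,

    S(f) = |H(f)|^2 M(f) G_u(f) M(f)* + g_obs(f) I,
    M(f) = C (2 pi i f I - A)^{-1} B,

with B injecting fluctuations into E states, C reading E states out, and
H(f) the transfer of a canonical double-gamma hemodynamic response.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

__all__ = [
    "ConnectionParams",
    "FixedNeuralParams",
    "NoiseParams",
    "HRFParams",
    "CrossSpectralData",
    "UnstableModelError",
    "CONNECTION_NAMES",
    "DEFAULT_BAND",
    "default_frequencies",
    "effective_strength",
    "system_jacobian",
    "hemodynamic_gain",
    "predicted_csd",
    "save_csd",
    "load_csd",
]

#: Analysis band of endogenous BOLD fluctuations, Hz.
DEFAULT_BAND = (0.0078, 0.1)

#: Reporting order of the four free connections (Table-5-style labels):
#: within-DLPFC I->E, STR->DLPFC E->E, DLPFC->STR E->E, within-STR I->E.
CONNECTION_NAMES = (
    "LDLPFC -> LDLPFC",
    "LSTR -> LDLPFC",
    "LDLPFC -> LSTR",
    "LSTR -> LSTR",
)

_DEFAULT_STRENGTH_HZ = 0.125


class UnstableModelError(RuntimeError):
    """Raised when the neural system has a non-decaying mode."""


@dataclass(frozen=True)
class ConnectionParams:
    """The four free log scale factors (prior mean 0 = default strength).

    Field order matches :data:`CONNECTION_NAMES`:
    ``ie_dlpfc`` (within-DLPFC I->E), ``ee_str_to_dlpfc``,
    ``ee_dlpfc_to_str``, ``ie_str`` (within-STR I->E).
    """

    ie_dlpfc: float = 0.0
    ee_str_to_dlpfc: float = 0.0
    ee_dlpfc_to_str: float = 0.0
    ie_str: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.ie_dlpfc, self.ee_str_to_dlpfc,
                         self.ee_dlpfc_to_str, self.ie_str], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ConnectionParams":
        t = np.asarray(theta, dtype=float)
        if t.shape != (4,):
            raise ValueError("expected a length-4 parameter vector")
        return cls(*t)


@dataclass(frozen=True)
class FixedNeuralParams:
    """Fixed (never estimated) rate constants, Hz.

    Self-decays are negative (leaky populations); the E->I gain is positive.
    Defaults give a well-damped oscillatory system at the prior mean.
    """

    se_decay: float = -0.5
    si_decay: float = -0.5
    ei_gain: float = 0.5

    def __post_init__(self) -> None:
        if self.se_decay >= 0 or self.si_decay >= 0:
            raise ValueError("self-decays must be negative")
        if self.ei_gain <= 0:
            raise ValueError("E->I gain must be positive")


def _band_unit_amplitude(band: tuple[float, float] = DEFAULT_BAND,
                         beta: float = 0.5) -> float:
    """Amplitude alpha making int_band alpha f^-beta df = 1 (unit power)."""
    lo, hi = band
    if beta == 1.0:
        return 1.0 / np.log(hi / lo)
    return (1.0 - beta) / (hi ** (1 - beta) - lo ** (1 - beta))


@dataclass(frozen=True)
class NoiseParams:
    """Spectral parameters of fluctuations and observation noise.

    ``g(f) = alpha * f**-beta`` (one-sided density); the neural amplitude
    default integrates to unit power over the analysis band, the observation
    noise is white with density ``alpha_obs``.
    """

    alpha_neural: float = field(default_factory=_band_unit_amplitude)
    beta_neural: float = 0.5
    alpha_obs: float = 1.0
    beta_obs: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_neural <= 0 or self.alpha_obs <= 0:
            raise ValueError("noise amplitudes must be positive")

    def neural_density(self, freqs: np.ndarray) -> np.ndarray:
        return self.alpha_neural * np.asarray(freqs, float) ** (-self.beta_neural)

    def obs_density(self, freqs: np.ndarray) -> np.ndarray:
        return self.alpha_obs * np.asarray(freqs, float) ** (-self.beta_obs)


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response (SPM-like shape).

    peak_delay/undershoot_delay are gamma shape parameters (time constants of
    1 s), undershoot_ratio the relative amplitude of the undershoot.  The
    kernel is normalized to unit integral (unit DC gain).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0
    dt_s: float = 0.05

    def kernel(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, h(t)) on a dense grid, unit integral."""
        t = np.arange(0.0, self.duration_s, self.dt_s)
        h = (t ** (self.peak_delay - 1) * np.exp(-t) / gamma_fn(self.peak_delay)
             - self.undershoot_ratio * t ** (self.undershoot_delay - 1)
             * np.exp(-t) / gamma_fn(self.undershoot_delay))
        h /= np.trapezoid(h, t)
        return t, h


@dataclass(frozen=True)
class CrossSpectralData:
    """Per-frequency 2x2 complex Hermitian PSD cross-spectral matrices.

    ``feature_sd``, when present, holds the sampling standard deviation of
    each real data feature (S11, S22, Re S12, Im S12 per frequency, raveled)
    as propagated from the spectral estimator; inversion uses it to weight
    residuals.
    """

    freqs: np.ndarray
    csd: np.ndarray
    region_names: tuple[str, ...] = ("LDLPFC", "LSTR")
    feature_sd: np.ndarray | None = None
    feature_cov: np.ndarray | None = None
    #: number of free parameters of the spectral estimator behind these
    #: features (bounds the information the features can carry)
    effective_dof: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        S = np.asarray(self.csd, dtype=complex)
        if S.shape != (f.size, 2, 2):
            raise ValueError("csd must have shape (n_freqs, 2, 2)")
        if not np.allclose(S, np.conj(np.swapaxes(S, 1, 2)), atol=1e-8 * max(1.0, float(np.abs(S).max()))):
            raise ValueError("cross-spectral matrices must be Hermitian")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "csd", S)
        if self.feature_sd is not None:
            sd = np.asarray(self.feature_sd, dtype=float)
            if sd.shape != (4 * f.size,):
                raise ValueError("feature_sd must have length 4 * n_freqs")
            object.__setattr__(self, "feature_sd", sd)
        if self.feature_cov is not None:
            C = np.asarray(self.feature_cov, dtype=float)
            if C.shape != (4 * f.size, 4 * f.size):
                raise ValueError("feature_cov must be (4 n_freqs)^2")
            object.__setattr__(self, "feature_cov", C)

    def is_psd(self, tol: float = 1e-10) -> bool:
        w = np.linalg.eigvalsh(0.5 * (self.csd + np.conj(np.swapaxes(self.csd, 1, 2))))
        return bool((w >= -tol * max(1.0, float(np.abs(self.csd).max()))).all())

    def feature_vector(self) -> np.ndarray:
        """Real features per frequency: S11, S22, Re S12, Im S12."""
        return np.column_stack([
            self.csd[:, 0, 0].real,
            self.csd[:, 1, 1].real,
            self.csd[:, 0, 1].real,
            self.csd[:, 0, 1].imag,
        ]).ravel()


def default_frequencies(n: int = 32,
                        band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    return np.linspace(band[0], band[1], n)


def effective_strength(theta: float, kind: str) -> float:
    """Connection strength in Hz from a log scale factor.

    ``between`` connections are excitatory, +(1/8) exp(theta); ``within``
    connections are inhibitory, -(1/8) exp(theta).
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    if kind == "between":
        return _DEFAULT_STRENGTH_HZ * float(np.exp(theta))
    if kind == "within":
        return -_DEFAULT_STRENGTH_HZ * float(np.exp(theta))
    raise ValueError("kind must be 'between' or 'within'")


def system_jacobian(params: ConnectionParams,
                    fixed: FixedNeuralParams = FixedNeuralParams(),
                    check_stability: bool = True) -> np.ndarray:
    """Linearized neural dynamics, state order (E_f, I_f, E_s, I_s).

    Raises :class:`UnstableModelError` if any eigenvalue has a non-negative
    real part (the resting-state model requires decaying fluctuations).
    """
    A = np.zeros((4, 4))
    A[0, 0] = fixed.se_decay
    A[0, 1] = effective_strength(params.ie_dlpfc, "within")
    A[0, 2] = effective_strength(params.ee_str_to_dlpfc, "between")
    A[1, 0] = fixed.ei_gain
    A[1, 1] = fixed.si_decay
    A[2, 0] = effective_strength(params.ee_dlpfc_to_str, "between")
    A[2, 2] = fixed.se_decay
    A[2, 3] = effective_strength(params.ie_str, "within")
    A[3, 2] = fixed.ei_gain
    A[3, 3] = fixed.si_decay
    if check_stability:
        lam = np.linalg.eigvals(A)
        if lam.real.max() >= 0:
            raise UnstableModelError(
                f"unstable neural system: max Re(eig) = {lam.real.max():.4f}"
            )
    return A


@functools.lru_cache(maxsize=64)
def _hrf_transfer_cached(freqs_key: tuple[float, ...],
                         hrf: HRFParams) -> np.ndarray:
    t, h = hrf.kernel()
    f = np.asarray(freqs_key, dtype=float)
    phase = np.exp(-2j * np.pi * np.outer(f, t))
    return (phase * h).sum(axis=1) * hrf.dt_s


def hemodynamic_gain(freqs: np.ndarray,
                     hrf: HRFParams = HRFParams()) -> np.ndarray:
    """Complex transfer of the hemodynamic kernel at the given frequencies.

    DC magnitude equals the kernel's integral; the magnitude decreases over
    the analysis band (the HRF is a sluggish low-pass filter).
    """
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        return np.zeros(0, dtype=complex)
    return _hrf_transfer_cached(tuple(f.tolist()), hrf)


# Fluctuations drive E states; BOLD reads E states.
_B_INPUT = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
_C_OUTPUT = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])


def neural_transfer(A: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """M(f) = C (2 pi i f I - A)^{-1} B, shape (n_freqs, 2, 2)."""
    f = np.asarray(freqs, dtype=float)
    iw = 2j * np.pi * f
    lhs = iw[:, None, None] * np.eye(4) - A[None, :, :]
    sol = np.linalg.solve(lhs, np.broadcast_to(_B_INPUT, (f.size, 4, 2)))
    return _C_OUTPUT @ sol


def predicted_csd(params: ConnectionParams,
                  fixed: FixedNeuralParams = FixedNeuralParams(),
                  noise: NoiseParams = NoiseParams(),
                  freqs: np.ndarray | None = None,
                  hrf: HRFParams = HRFParams()) -> CrossSpectralData:
    """Model-predicted BOLD cross-spectral density on the analysis band.

    One-sided densities throughout: integrating a diagonal entry over the
    (positive-frequency) band gives that region's band-limited variance.
    """
    if freqs is None:
        freqs = default_frequencies()
    f = np.asarray(freqs, dtype=float)
    A = system_jacobian(params, fixed)  # raises if unstable
    M = neural_transfer(A, f)
    g_u = noise.neural_density(f)
    H2 = np.abs(hemodynamic_gain(f, hrf)) ** 2
    S = (M * g_u[:, None, None]) @ np.conj(np.swapaxes(M, 1, 2))
    S *= H2[:, None, None]
    S += noise.obs_density(f)[:, None, None] * np.eye(2)
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))  # kill Hermitian round-off
    return CrossSpectralData(f, S)


_CSD_COLUMNS = ["freq_hz", "re_S11", "im_S11", "re_S12", "im_S12",
                "re_S21", "im_S21", "re_S22", "im_S22"]


def save_csd(data: CrossSpectralData, path) -> None:
    """Serialize to the columnar text format (one row per frequency)."""
    S = data.csd
    df = pd.DataFrame({
        "freq_hz": data.freqs,
        "re_S11": S[:, 0, 0].real, "im_S11": S[:, 0, 0].imag,
        "re_S12": S[:, 0, 1].real, "im_S12": S[:, 0, 1].imag,
        "re_S21": S[:, 1, 0].real, "im_S21": S[:, 1, 0].imag,
        "re_S22": S[:, 1, 1].real, "im_S22": S[:, 1, 1].imag,
    })
    if data.feature_sd is not None:
        sd = data.feature_sd.reshape(-1, 4)
        df["sd_S11"], df["sd_S22"] = sd[:, 0], sd[:, 1]
        df["sd_reS12"], df["sd_imS12"] = sd[:, 2], sd[:, 3]
    df.to_csv(path, index=False)


def load_csd(path) -> CrossSpectralData:
    df = pd.read_csv(path)
    missing = set(_CSD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CSD file missing columns {sorted(missing)}")
    n = len(df)
    S = np.empty((n, 2, 2), dtype=complex)
    S[:, 0, 0] = df.re_S11 + 1j * df.im_S11
    S[:, 0, 1] = df.re_S12 + 1j * df.im_S12
    S[:, 1, 0] = df.re_S21 + 1j * df.im_S21
    S[:, 1, 1] = df.re_S22 + 1j * df.im_S22
    feature_sd = None
    if "sd_S11" in df.columns:
        feature_sd = np.column_stack(
            [df.sd_S11, df.sd_S22, df.sd_reS12, df.sd_imS12]).ravel()
    return CrossSpectralData(df.freq_hz.to_numpy(), S, feature_sd=feature_sd)
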