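"""BOLD time-series preparation: confound regression, drift removal, and
voxel-to-region summarization.

The study design is 360 volumes at TR = 1 s per subject for two regions
(left DLPFC, left striatum).  Analysis is restricted to endogenous
fluctuations between 0.0078 and 0.1 Hz; slower drifts are projected out with
a discrete-cosine basis, and nuisance signals (head motion, white matter,
CSF) are removed by least-squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

__all__ = [
    "TimeSeriesData",
    "ConfoundSet",
    "SpectralConfig",
    "regress_confounds",
    "highpass_cosine",
    "summarize_region",
]


@dataclass(frozen=True)
class TimeSeriesData:
    """time x region matrix with its repetition time (seconds)."""

    values: np.ndarray
    tr_seconds: float
    region_names: tuple[str, ...] = ("LDLPFC", "LSTR")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be a 2-D time x region matrix")
        if not np.isfinite(v).all():
            raise ValueError("time series contains missing/non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.region_names) != v.shape[1]:
            raise ValueError("one region name per column required")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds


@dataclass(frozen=True)
class ConfoundSet:
    """Nuisance regressors (e.g. six motion parameters, WM and CSF series)."""

    values: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[0] == 1 and v.shape[1] > 1 and len(self.names) == 1:
            v = v.T
        names = self.names or tuple(f"confound_{i}" for i in range(v.shape[1]))
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", names)


@dataclass(frozen=True)
class SpectralConfig:
    """Analysis band in Hz (defaults: 0.0078-0.1 Hz)."""

    f_min: float = 0.0078
    f_max: float = 0.1
    n_freqs: int = 32

    def __post_init__(self) -> None:
        if not 0.0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")

    def validate_against(self, tr_seconds: float) -> None:
        nyq = 0.5 / tr_seconds
        if self.f_min >= nyq:
            raise ValueError(f"f_min {self.f_min} >= Nyquist {nyq}")
        if self.f_max > nyq:
            raise ValueError(f"f_max {self.f_max} exceeds Nyquist {nyq}")

    def frequencies(self) -> np.ndarray:
        return np.linspace(self.f_min, self.f_max, self.n_freqs)


def regress_confounds(series: TimeSeriesData, confounds: ConfoundSet) -> TimeSeriesData:
    """Residualize each region on [intercept | confounds] by least squares."""
    C = confounds.values
    if C.shape[0] != series.n_timepoints:
        raise ValueError(
            f"confound rows ({C.shape[0]}) != series rows ({series.n_timepoints})"
        )
    X = np.column_stack([np.ones(series.n_timepoints), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR diagonal
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = piv[rank:]
        names = ["intercept", *confounds.names]
        raise ValueError(
            "rank-deficient confound matrix; collinear columns: "
            f"{[names[i] for i in sorted(bad)]} (rank {rank} of {X.shape[1]}, "
            f"min |R_ii| {diag.min():.2e})"
        )
    beta, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    return replace(series, values=series.values - X @ beta)


def _dct_drift_basis(n: int, tr: float, f_min: float) -> np.ndarray:
    """Constant plus DCT-II components with frequency below ``f_min``.

    Component k of the basis has frequency k / (2 n tr) Hz.
    """
    k_max = int(np.floor(2 * n * tr * f_min))
    t = np.arange(n)
    cols = [np.ones(n)]
    for k in range(1, k_max + 1):
        if k / (2 * n * tr) >= f_min:
            break
        cols.append(np.cos(np.pi * k * (2 * t + 1) / (2 * n)))
    return np.column_stack(cols)


def highpass_cosine(series: TimeSeriesData, config: SpectralConfig) -> TimeSeriesData:
    """Project out the discrete-cosine drift subspace below ``config.f_min``.

    Removes the constant and all cosine components slower than the analysis
    band; in-band frequencies pass essentially unattenuated.
    """
    config.validate_against(series.tr_seconds)
    X = _dct_drift_basis(series.n_timepoints, series.tr_seconds, config.f_min)
    beta, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    return replace(series, values=series.values - X @ beta)


def summarize_region(voxel_series: np.ndarray) -> np.ndarray:
    """Principal eigenvariate of a time x voxel matrix.

    The summary is the first principal component of the column-centred
    matrix, sign-aligned so its correlation with the mean voxel series is
    non-negative, and scaled to unit (sample) variance.  With a single voxel
    this reduces to standardization.
    """
    V = np.atleast_2d(np.asarray(voxel_series, dtype=float))
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("need a time x voxel matrix with >= 2 timepoints")
    centred = V - V.mean(axis=0)
    if not centred.any():
        raise ValueError("zero-variance voxel data")
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    score = U[:, 0] * s[0]
    mean_series = centred.mean(axis=1)
    if mean_series.any() and (score @ mean_series) < 0:
        score = -score
    sd = score.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate principal component")
    return score / sd
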