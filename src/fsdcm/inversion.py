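"""Per-subject Bayesian inversion of the spectral model.

The data feature is the observed cross-spectral density (CSD) of the
two-region BOLD series on the analysis band, estimated with a multivariate
autoregressive model (order 8 by default).  A Gauss-Newton variational
Laplace scheme then maximizes the free energy

    F = accuracy - complexity
      = E_q[ln p(y | phi)] - KL[q(phi) || p(phi)]   (Laplace approximation)

over phi = (theta_1..4, log alpha_neural, log alpha_obs, lambda) where the
thetas are the free log-scaling connectivity parameters, the alphas are the
fluctuation/observation noise amplitudes (log scale, Gaussian hyperpriors)
and lambda is the log precision of the residual CSD features.  The posterior
is Gaussian with covariance given by the negative inverse curvature at the
optimum; accepted Gauss-Newton steps never decrease F (step-halving on a
proposed decrease).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.tsa.api import VAR

from .model import (
    ConnectionParams,
    CrossSpectralData,
    FixedNeuralParams,
    HRFParams,
    NoiseParams,
    predicted_csd,
)
from .preprocess import SpectralConfig, TimeSeriesData

__all__ = [
    "PriorSpec",
    "SubjectPosterior",
    "CohortDiagnostics",
    "estimate_csd",
    "invert_subject",
    "explained_variance",
    "cohort_diagnostics",
    "summarize_explained_variance",
]

log = logging.getLogger(__name__)

#: Subjects whose model explains less than this share of CSD variance are
#: flagged in diagnostics (they are still carried forward: the group level
#: down-weights them through their posterior precision).
ACCEPTABLE_EV_PCT = 10.0


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors for the connectivity parameters and hyperparameters.

    The connectivity prior is deliberately mild: zero mean (i.e. the default
    +/- 1/8 Hz strengths) with variance 1/16 per log scale factor.  The
    log-precision prior for the residual features is data-adaptive when left
    unset (centred on a residual SD of ~30% of the feature SD).
    """

    theta_mean: np.ndarray = field(default_factory=lambda: np.zeros(4))
    theta_cov: np.ndarray = field(default_factory=lambda: np.eye(4) / 16.0)
    log_alpha_neural: tuple[float, float] = (float(np.log(NoiseParams().alpha_neural)), 0.25)
    log_alpha_obs: tuple[float, float] = (float(np.log(NoiseParams().alpha_obs)), 0.25)
    log_data_precision: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        C = np.asarray(self.theta_cov, dtype=float)
        if C.shape != (4, 4) or not np.allclose(C, C.T):
            raise ValueError("theta_cov must be symmetric 4x4")
        if np.linalg.eigvalsh(C).min() < 0:
            raise ValueError("theta_cov must be positive semidefinite")
        object.__setattr__(self, "theta_mean",
                           np.asarray(self.theta_mean, dtype=float))
        object.__setattr__(self, "theta_cov", C)


@dataclass
class SubjectPosterior:
    """Gaussian posterior over the four connectivity parameters."""

    subject_id: str
    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    explained_variance_pct: float
    hyper_mean: np.ndarray | None = None
    f_trajectory: tuple[float, ...] = ()
    converged: bool = True
    improved: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (4,) or self.covariance.shape != (4, 4):
            raise ValueError("posterior must cover the 4 connection parameters")

    @property
    def scale_factors(self) -> np.ndarray:
        """exp(posterior mean): >1 means stronger than the default strength."""
        return np.exp(self.mean)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "free_energy": self.free_energy,
            "explained_variance_pct": self.explained_variance_pct,
            "converged": self.converged,
            "improved": self.improved,
            "n_iterations": self.n_iterations,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectPosterior":
        return cls(d["subject_id"], np.asarray(d["mean"]),
                   np.asarray(d["covariance"]), d["free_energy"],
                   d["explained_variance_pct"],
                   converged=d.get("converged", True),
                   improved=d.get("improved", True),
                   n_iterations=d.get("n_iterations", 0))


def _var_spectrum(coefs: np.ndarray, sigma: np.ndarray, freqs: np.ndarray,
                  dt: float) -> np.ndarray:
    """One-sided VAR spectral matrices, shape (n_freqs, k, k)."""
    order, k, _ = coefs.shape
    phase = np.exp(-2j * np.pi * np.outer(freqs, dt * np.arange(1, order + 1)))
    Aw = np.eye(k)[None] - np.einsum("fl,lij->fij", phase, coefs)
    Hw = np.linalg.solve(Aw, np.broadcast_to(np.eye(k, dtype=complex),
                                             (freqs.size, k, k)))
    S = 2.0 * dt * Hw @ sigma @ np.conj(np.swapaxes(Hw, 1, 2))
    return 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))


def _csd_features(S: np.ndarray) -> np.ndarray:
    return np.column_stack([S[:, 0, 0].real, S[:, 1, 1].real,
                            S[:, 0, 1].real, S[:, 0, 1].imag]).ravel()


def _feature_sampling_cov(x: np.ndarray, coefs: np.ndarray, sigma: np.ndarray,
                          freqs: np.ndarray, dt: float) -> np.ndarray:
    """Delta-method sampling covariance of the VAR CSD features.

    The VAR coefficient estimates have covariance kron over Sigma_u and the
    lagged-regressor Gram inverse; the innovation covariance is Wishart with
    T - order degrees of freedom.  Both are propagated through the spectrum
    with a central-difference Jacobian.  The result is rank-deficient by
    construction (the features are a smooth transform of the ~order*k^2 + 3
    VAR parameters) — that rank structure is exactly what downstream
    whitening exploits.
    """
    order, k, _ = coefs.shape
    T = x.shape[0]
    Z = np.hstack([x[order - lag: T - lag] for lag in range(1, order + 1)])
    G = np.linalg.inv(Z.T @ Z)
    c0 = coefs.ravel()
    s0 = sigma[np.triu_indices(k)]           # (s11, s12, s22) for k=2

    def feats(c_flat, s_flat):
        sig = np.empty((k, k))
        sig[np.triu_indices(k)] = s_flat
        sig.T[np.triu_indices(k)] = s_flat
        return _csd_features(_var_spectrum(c_flat.reshape(order, k, k),
                                           sig, freqs, dt))

    n_c, n_s = c0.size, s0.size
    J = np.empty((4 * freqs.size, n_c + n_s))
    h = 1e-5
    for j in range(n_c):
        d = np.zeros(n_c); d[j] = h
        J[:, j] = (feats(c0 + d, s0) - feats(c0 - d, s0)) / (2 * h)
    for j in range(n_s):
        d = np.zeros(n_s); d[j] = h
        J[:, n_c + j] = (feats(c0, s0 + d) - feats(c0, s0 - d)) / (2 * h)

    # cov of coefficient (lag l, eq j, lag-var m) pairs
    Cc = np.zeros((n_c, n_c))
    lag_m = [(l, m) for l in range(order) for m in range(k)]
    for j in range(k):
        for j2 in range(k):
            block = sigma[j, j2] * G
            for a, (l, m) in enumerate(lag_m):
                for b, (l2, m2) in enumerate(lag_m):
                    Cc[l * k * k + j * k + m, l2 * k * k + j2 * k + m2] = \
                        block[l * k + m, l2 * k + m2]
    dof = max(T - order, 1)
    iu = np.stack(np.triu_indices(k), axis=1)
    Cs = np.empty((n_s, n_s))
    for a, (i1, j1) in enumerate(iu):
        for b, (i2, j2) in enumerate(iu):
            Cs[a, b] = (sigma[i1, i2] * sigma[j1, j2]
                        + sigma[i1, j2] * sigma[j1, i2]) / dof
    Cov = np.zeros((n_c + n_s, n_c + n_s))
    Cov[:n_c, :n_c] = Cc
    Cov[n_c:, n_c:] = Cs
    return J @ Cov @ J.T


def estimate_csd(series: TimeSeriesData,
                 config: SpectralConfig = SpectralConfig(),
                 order: int = 8,
                 with_uncertainty: bool = False) -> CrossSpectralData:
    """Multivariate autoregressive CSD estimate on the analysis grid.

    A VAR(order) model is fit to the demeaned series; its one-sided spectral
    density ``S(f) = 2 dt A(w)^-1 Sigma A(w)^-H`` (w = 2 pi f dt) is
    evaluated on the configured frequency grid (Hermitian PSD per frequency
    by construction).  The estimator's free-parameter count is attached as
    ``effective_dof`` (it bounds the information the smooth spectrum can
    carry); ``with_uncertainty`` additionally propagates the full sampling
    covariance of the features from the VAR coefficient covariance, for the
    measurement-error weighting modes of the inverter.
    """
    if series.n_timepoints < 4 * order:
        raise ValueError(
            f"series length {series.n_timepoints} < 4 x AR order {order}"
        )
    config.validate_against(series.tr_seconds)
    x = series.values - series.values.mean(axis=0)
    res = VAR(x).fit(maxlags=order, ic=None, trend="n")
    coefs = res.coefs  # (order, k, k)
    sigma = np.asarray(res.sigma_u)
    dt = series.tr_seconds
    freqs = config.frequencies()
    S = _var_spectrum(coefs, sigma, freqs, dt)
    sd = cov = None
    if with_uncertainty:
        cov = _feature_sampling_cov(x, coefs, sigma, freqs, dt)
        sd = np.sqrt(np.maximum(np.diag(cov), 1e-20))
    k = x.shape[1]
    dof = order * k * k + k * (k + 1) // 2
    return CrossSpectralData(freqs, S, region_names=series.region_names,
                             feature_sd=sd, feature_cov=cov,
                             effective_dof=float(dof))


def explained_variance(observed: CrossSpectralData,
                       predicted: CrossSpectralData) -> float:
    """Percent CSD variance explained, over stacked real and imaginary parts.

    ``100 * (1 - ||obs - pred||^2 / ||obs - mean(obs)||^2)`` over the unique
    real components per frequency (S11, S22, Re S12, Im S12); can be
    negative for fits worse than a constant.
    """
    if observed.freqs.shape != predicted.freqs.shape or \
            not np.allclose(observed.freqs, predicted.freqs):
        raise ValueError("observed and predicted must share a frequency grid")
    vo = observed.feature_vector()
    vp = predicted.feature_vector()
    denom = float(np.sum((vo - vo.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("observed CSD has zero variance")
    return float(100.0 * (1.0 - np.sum((vo - vp) ** 2) / denom))


def _predicted_features(theta: np.ndarray, log_alphas: np.ndarray,
                        freqs: np.ndarray, fixed: FixedNeuralParams,
                        base_noise: NoiseParams, hrf: HRFParams) -> np.ndarray:
    noise = NoiseParams(alpha_neural=float(np.exp(log_alphas[0])),
                        beta_neural=base_noise.beta_neural,
                        alpha_obs=float(np.exp(log_alphas[1])),
                        beta_obs=base_noise.beta_obs)
    pred = predicted_csd(ConnectionParams.from_array(theta), fixed, noise,
                        freqs, hrf)
    return pred.feature_vector()


class _Objective:
    """Free-energy objective with Gauss-Newton curvature.

    Residuals are whitened before entering the Gaussian likelihood.  When
    the observed CSD carries its full sampling covariance the whitener is
    the (pseudo-)inverse square root of that covariance restricted to its
    numerical rank — the spectral features of a fitted VAR are a smooth
    transform of a few dozen coefficients, so this is what turns "128
    features" into the correct effective number of observations.  Otherwise
    a per-frequency sqrt(S11 * S22) scale (Wishart statistics) is used, so
    the single log-precision hyperparameter lambda applies homogeneously
    across the band instead of letting low frequencies dominate.
    """

    def __init__(self, y, freqs, whiten, prior_mean, prior_prec,
                 weight, fixed, base_noise, hrf):
        self.whiten = whiten
        self.y = whiten @ y
        self.freqs = freqs
        self.mu0 = prior_mean
        self.P0 = prior_prec
        self.w = weight
        self.fixed = fixed
        self.base_noise = base_noise
        self.hrf = hrf
        self.n = self.y.size
        self.p = prior_mean.size

    def g(self, phi: np.ndarray) -> np.ndarray:
        return self.whiten @ _predicted_features(
            phi[:4], phi[4:6], self.freqs, self.fixed, self.base_noise,
            self.hrf)

    def jacobian(self, phi: np.ndarray, g0: np.ndarray,
                 h: float = 1e-4) -> np.ndarray:
        J = np.zeros((self.n, 6))
        for j in range(6):
            dp = np.zeros_like(phi)
            dp[j] = h
            J[:, j] = (self.g(phi + dp) - self.g(phi - dp)) / (2 * h)
        return J

    def evaluate(self, phi: np.ndarray):
        """Return (F, grad, curvature H, residual e, J)."""
        g0 = self.g(phi)
        e = self.y - g0
        lam = phi[6]
        prec = np.exp(np.clip(lam, -40.0, 40.0))
        J = self.jacobian(phi, g0)
        dphi = phi - self.mu0
        sse = float(e @ e)
        # log joint (likelihood weighted by w + prior)
        L = self.w * (-0.5 * prec * sse + 0.5 * self.n * (lam - np.log(2 * np.pi)))
        L += -0.5 * dphi @ self.P0 @ dphi
        grad = np.zeros(self.p)
        grad[:6] = self.w * prec * (J.T @ e)
        grad[6] = self.w * (0.5 * self.n - 0.5 * prec * sse)
        grad -= self.P0 @ dphi
        H = np.zeros((self.p, self.p))
        H[:6, :6] = self.w * prec * (J.T @ J)
        H[6, 6] = self.w * 0.5 * prec * sse
        H += self.P0
        sign, logdet = np.linalg.slogdet(H)
        F = L + 0.5 * self.p * np.log(2 * np.pi) - 0.5 * logdet
        return F, grad, H, e, g0


def _psd_floor(C: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    return (V * np.maximum(w, floor)) @ V.T


def invert_subject(observed: CrossSpectralData,
                   priors: PriorSpec = PriorSpec(),
                   subject_id: str = "subject",
                   data_weight: float | str = "auto",
                   fixed: FixedNeuralParams = FixedNeuralParams(),
                   base_noise: NoiseParams = NoiseParams(),
                   hrf: HRFParams = HRFParams(),
                   max_iter: int = 128,
                   tol: float = 0.01,
                   weighting: str = "wishart",
                   n_starts: int = 1,
                   start_jitter: float = 0.25,
                   restart_seed: int = 0) -> SubjectPosterior:
    """Variational-Laplace inversion of one subject's observed CSD.

    Returns the Gaussian posterior over the four connectivity parameters,
    the final free energy, and the percent explained variance of the fit.
    ``data_weight`` scales the likelihood.  The default ``"auto"`` uses
    ``effective_dof / n_features`` when the CSD came from a parametric
    spectral estimator: the features are then a deterministic transform of
    a handful of estimator parameters, and counting all of them as
    independent observations would overstate the evidence (and shrink the
    posterior spread) several-fold.  ``0`` switches the likelihood off
    entirely (posterior == prior), which is occasionally useful for testing
    and for prior-predictive checks.

    With ``n_starts > 1`` the Gauss-Newton scheme is additionally run from
    deterministic jittered initializations of the connectivity parameters
    and the solution with the highest free energy is kept — a cheap guard
    against local optima on noisy spectra.

    ``weighting`` selects the residual whitening: ``"wishart"`` (default)
    scales each frequency by sqrt(S11*S22) of the observed CSD, the
    standard spectral-DCM-style heuristic; ``"sampling_sd"`` standardizes
    by the spectral estimator's propagated per-feature sampling SD;
    ``"full"`` whitens by the full propagated sampling covariance on its
    numerical rank, which calibrates posterior spread best but shrinks
    point estimates hardest on short records.
    """
    if not observed.is_psd(tol=1e-8):
        raise ValueError("observed CSD violates positive semidefiniteness")
    if data_weight == "auto":
        if observed.effective_dof is not None:
            data_weight = min(1.0, observed.effective_dof
                              / (4.0 * observed.freqs.size))
        else:
            data_weight = 1.0
    y = observed.feature_vector()
    freqs = observed.freqs
    if weighting == "full" and observed.feature_cov is None:
        raise ValueError("'full' weighting needs feature_cov on the CSD")
    if weighting == "sampling_sd" and observed.feature_sd is None:
        raise ValueError("'sampling_sd' weighting needs feature_sd on the CSD")
    if weighting == "full":
        # whiten by the estimator's sampling covariance on its numerical
        # rank; lambda is then centred on unit precision
        w_eig, U = np.linalg.eigh(0.5 * (observed.feature_cov
                                         + observed.feature_cov.T))
        keep = w_eig > 1e-10 * w_eig.max()
        whiten = (U[:, keep] / np.sqrt(w_eig[keep])).T
        default_lam_prior = (0.0, 1.0)
    elif weighting == "sampling_sd":
        floor = 1e-6 * float(np.abs(y).max())
        whiten = np.diag(1.0 / np.maximum(observed.feature_sd, floor))
        default_lam_prior = (0.0, 1.0)
    elif weighting == "wishart":
        s11 = np.maximum(observed.csd[:, 0, 0].real, 1e-12)
        s22 = np.maximum(observed.csd[:, 1, 1].real, 1e-12)
        scale = np.repeat(np.sqrt(s11 * s22)[:, None], 4, axis=1).ravel()
        whiten = np.diag(1.0 / scale)
        var_y = float(np.var(y / scale))
        default_lam_prior = (float(-np.log(max(0.09 * var_y, 1e-12))), 1.0)
    else:
        raise ValueError("weighting must be 'wishart', 'sampling_sd' or 'full'")
    lam_prior = priors.log_data_precision or default_lam_prior

    mu0 = np.concatenate([priors.theta_mean,
                          [priors.log_alpha_neural[0],
                           priors.log_alpha_obs[0], lam_prior[0]]])
    prior_var = np.zeros(7)
    prior_prec = np.zeros((7, 7))
    theta_cov = _psd_floor(priors.theta_cov, 1e-12)
    prior_prec[:4, :4] = np.linalg.inv(theta_cov)
    prior_var[4:] = [priors.log_alpha_neural[1], priors.log_alpha_obs[1],
                     lam_prior[1]]
    for i in range(4, 7):
        prior_prec[i, i] = 1.0 / prior_var[i]

    obj = _Objective(y, freqs, whiten, mu0, prior_prec,
                     float(data_weight), fixed, base_noise, hrf)

    def gauss_newton(phi0):
        phi = phi0.copy()
        F, grad, H, _, _ = obj.evaluate(phi)
        traj = [F]
        stall = 0
        it = 0
        accepted = True
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            norm = float(np.linalg.norm(step))
            if norm > 8.0:  # trust region: avoid wild hyperparameter jumps
                step *= 8.0 / norm
            accepted = False
            for half in range(8):
                cand = phi + step / (2 ** half)
                try:
                    Fc, gc, Hc, _, _ = obj.evaluate(cand)
                except Exception:
                    continue
                if np.isfinite(Fc) and Fc >= F - 1e-12:
                    dF = Fc - F
                    phi, F, grad, H = cand, Fc, gc, Hc
                    traj.append(F)
                    accepted = True
                    break
            if not accepted:
                break
            stall = stall + 1 if abs(dF) < tol else 0
            if stall >= 3:
                break
        converged = stall >= 3 or (not accepted and it < max_iter)
        return phi, F, H, traj, it, converged

    f_prior = obj.evaluate(mu0)[0]
    starts = [mu0.copy()]
    if n_starts > 1:
        rng = np.random.default_rng(restart_seed)
        for _ in range(n_starts - 1):
            jittered = mu0.copy()
            jittered[:4] += start_jitter * rng.standard_normal(4)
            starts.append(jittered)
    best = None
    for phi0 in starts:
        try:
            result = gauss_newton(phi0)
        except Exception:
            continue
        if best is None or result[1] > best[1]:
            best = result
    if best is None:  # pragma: no cover - all starts failed
        raise RuntimeError(f"subject {subject_id}: inversion failed")
    phi, F, H, traj, it, converged = best

    Sigma = _psd_floor(np.linalg.inv(H))
    theta_hat = phi[:4]
    pred = predicted_csd(ConnectionParams.from_array(theta_hat), fixed,
                        NoiseParams(alpha_neural=float(np.exp(phi[4])),
                                    beta_neural=base_noise.beta_neural,
                                    alpha_obs=float(np.exp(phi[5])),
                                    beta_obs=base_noise.beta_obs),
                        freqs, hrf)
    ev = explained_variance(observed, pred)
    improved = F > f_prior - 1e-9
    if not improved:
        log.warning("subject %s: free energy did not improve on the prior",
                    subject_id)
    post = SubjectPosterior(
        subject_id=subject_id,
        mean=theta_hat,
        covariance=Sigma[:4, :4],
        free_energy=float(F),
        explained_variance_pct=ev,
        hyper_mean=phi[4:].copy(),
        f_trajectory=tuple(traj),
        converged=bool(converged),
        improved=bool(improved),
        n_iterations=it,
    )
    log.info("subject %s: F=%.2f, EV=%.1f%%, %d iterations, converged=%s",
             subject_id, F, ev, it, converged)
    return post


@dataclass(frozen=True)
class CohortDiagnostics:
    mean_ev_pct: float
    sd_ev_pct: float | None
    flagged_subjects: tuple[str, ...]
    n_subjects: int

    @property
    def acceptable(self) -> bool:
        """Cohort-level criterion: mean explained variance of at least 10%."""
        return self.mean_ev_pct >= ACCEPTABLE_EV_PCT


def summarize_explained_variance(subject_ids: Sequence[str],
                                 ev_values: Sequence[float]) -> CohortDiagnostics:
    """Mean/SD of explained variance; flags subjects strictly below 10%.

    Flagged subjects are reported, not excluded: the hierarchical (PEB) step
    down-weights them automatically via their posterior precision.
    """
    ev = np.asarray(ev_values, dtype=float)
    if ev.size == 0:
        raise ValueError("need at least one subject")
    ids = [str(s) for s in subject_ids]
    flagged = tuple(i for i, v in zip(ids, ev) if v < ACCEPTABLE_EV_PCT)
    sd = float(ev.std(ddof=1)) if ev.size > 1 else None
    return CohortDiagnostics(float(ev.mean()), sd, flagged, int(ev.size))


def cohort_diagnostics(posteriors: Sequence[SubjectPosterior]) -> CohortDiagnostics:
    return summarize_explained_variance(
        [p.subject_id for p in posteriors],
        [p.explained_variance_pct for p in posteriors])
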