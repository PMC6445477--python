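"""Dynamical mean-field reduction and its iterative self-consistency solver.

In the large-N limit the deterministic recurrent input to a unit is
replaced by a Gaussian process xi(t) with moments tied to the rate
statistics of a single prototypical unit:

    [xi]              = J_eff <phi>
    [xi(t) xi(t+tau)] = J_cs^2 (C(tau) - <phi>^2)  (+ sigma_eta^2/2 delta(tau))

where C(tau) = <phi(t) phi(t+tau)> and J_eff, J_cs are the mean and
standard-deviation order parameters of the connectivity.  The solver
iterates: synthesize xi from the current moments (Fourier synthesis with
random phases), simulate the two-variable stochastic unit, re-estimate
the moments, and damp the update with a factor alpha.  Gaussian
quadrature closures for <phi> and C(tau) in terms of (mu, Delta) provide
an independent audit of the converged state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.stats

logger = logging.getLogger(__name__)

from .model_core import ADAPTATION, TransferParams, UnitParams, transfer
from .analysis import AutocorrEstimate, autocorrelation
from .meanfield import fixed_point

__all__ = [
    "DMFTState",
    "synthesize_gaussian_process",
    "single_unit_stochastic_sim",
    "gaussian_rate_mean",
    "gaussian_rate_mean_closed",
    "gaussian_rate_autocorr",
    "dmft_solve",
]

_CLIP_WARN_FRACTION = 0.01


@dataclass(frozen=True)
class DMFTState:
    """Outcome of the damped iterative self-consistency scheme."""

    estimate: AutocorrEstimate
    noise_mean: float
    noise_autocorr: np.ndarray = field(repr=False)
    lags: np.ndarray = field(repr=False)
    alpha: float = 0.6
    iterations: int = 0
    history: tuple = ()
    converged: bool = False
    clip_warnings: tuple = ()

    @property
    def rate_variance(self) -> float:
        """Firing-rate variance C(0) - <phi>^2 of the converged state."""
        return float(self.estimate.C[0] - self.estimate.mean_rate**2)


def synthesize_gaussian_process(
    target_autocorr: np.ndarray,
    n_samples: int,
    dt: float,
    rng: np.random.Generator | int,
    n_series: int = 1,
) -> tuple[np.ndarray, dict]:
    """Stationary zero-mean series with a prescribed autocovariance.

    ``target_autocorr`` samples the autocovariance on lags 0..L*dt.  It is
    embedded symmetrically into a circulant covariance of period
    ``n_samples``, whose discrete spectral density (clipped at zero) gives
    the Fourier amplitudes; phases are i.i.d. uniform in [-pi, pi]
    (Hermitian-symmetrized so the series is real).  Returns
    (series of shape (n_series, n_samples), metadata); metadata records
    the fraction of spectral power clipped, with a warning entry when it
    exceeds 1% of the total.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    G = np.asarray(target_autocorr, dtype=float)
    L = len(G) - 1
    M = int(n_samples)
    if M < 2 * L + 2:
        raise ValueError(
            f"series length {M} too short for {L} autocovariance lags"
        )
    Gc = np.zeros(M)
    Gc[: L + 1] = G
    if L > 0:
        Gc[M - L :] = G[1:][::-1]
    S = np.fft.rfft(Gc).real
    total = float(np.sum(np.abs(S)))
    clipped = float(np.sum(np.abs(S[S < 0])))
    clip_fraction = clipped / total if total > 0 else 0.0
    S = np.clip(S, 0.0, None)
    amp = np.sqrt(M * S)

    n_freq = len(S)
    phases = rng.uniform(-np.pi, np.pi, size=(n_series, n_freq))
    # DC and (for even M) Nyquist bins must be real: random sign
    phases[:, 0] = np.pi * rng.integers(0, 2, size=n_series)
    if M % 2 == 0:
        phases[:, -1] = np.pi * rng.integers(0, 2, size=n_series)
    series = np.fft.irfft(amp * np.exp(1j * phases), n=M, axis=1)
    meta = {"clip_fraction": clip_fraction, "warnings": ()}
    if clip_fraction > _CLIP_WARN_FRACTION:
        msg = f"spectral clipping removed {clip_fraction:.1%} of total power"
        meta["warnings"] = (msg,)
        logger.warning(msg)
    else:
        logger.debug("spectral clip fraction %.3e", clip_fraction)
    return series, meta


def single_unit_stochastic_sim(
    params: UnitParams,
    noise_mean: float,
    noise_autocorr: np.ndarray,
    sigma_eta: float = 0.0,
    T: float = 1000.0,
    dt: float = 0.05,
    trials: int = 100,
    seed: int | np.random.Generator = 0,
    burn_in: float | None = None,
    max_lag: float | None = None,
) -> AutocorrEstimate:
    """Simulate the two-variable stochastic prototype unit.

    The Gaussian drive xi (mean ``noise_mean``, autocovariance
    ``noise_autocorr`` on the dt lag grid, plus a white component of
    spectral density sigma_eta^2/2 if ``sigma_eta`` > 0) enters the
    mechanism's input pathway: the current equation for adaptation, the
    synaptic variable for filtering.  After a burn-in (default 20x the
    slowest time constant) the moments mu, Delta(tau), <phi>, C(tau) are
    estimated by trial-and-time averaging.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tm, t_hidden = params.tau_m, params.tau_slow
    if burn_in is None:
        burn_in = 20.0 * max(tm, t_hidden)
    if burn_in > T / 2:
        raise ValueError(f"burn-in {burn_in} exceeds half the horizon {T}")
    if max_lag is None:
        max_lag = min(10.0 * max(tm, t_hidden), (T - burn_in) / 4.0)
    n_steps = int(round(T / dt))

    G = np.array(noise_autocorr, dtype=float)
    # Split off the long-lag plateau as a static (frozen) Gaussian offset:
    # the Fourier synthesis is circular and would otherwise force the
    # drive to decorrelate beyond the stored lags, suppressing the frozen
    # across-units variability of the self-consistent solution.
    n_tail = max(1, len(G) // 20)
    plateau = float(np.clip(G[-n_tail:].mean(), 0.0, max(G[0], 0.0)))
    if sigma_eta > 0:
        G = G.copy()
        G[0] += sigma_eta**2 / (2.0 * dt)
    xi, meta = synthesize_gaussian_process(
        G - plateau, n_steps, dt, rng, n_series=trials
    )
    xi += noise_mean
    if plateau > 0:
        xi += np.sqrt(plateau) * rng.standard_normal((trials, 1))

    adapt = params.mechanism == ADAPTATION
    gamma = params.transfer.gamma
    x = np.full(trials, noise_mean if not adapt else
                (noise_mean + params.g_w * gamma) / (1.0 + params.g_w))
    hidden = np.full(trials, (x[0] - gamma) if adapt else x[0])

    xs = np.empty((trials, n_steps))
    if adapt:
        gw, tw = params.g_w, params.tau_w
        for n in range(n_steps):
            dx = (-x - gw * hidden + xi[:, n]) * (dt / tm)
            dh = (-hidden + x - gamma) * (dt / tw)
            x = x + dx
            hidden = hidden + dh
            xs[:, n] = x
    else:
        ts_ = params.tau_s
        for n in range(n_steps):
            dx = (-x + hidden) * (dt / tm)
            dh = (-hidden + xi[:, n]) * (dt / ts_)
            x = x + dx
            hidden = hidden + dh
            xs[:, n] = x
    if not np.all(np.isfinite(xs[:, -1])):
        raise FloatingPointError("stochastic unit simulation diverged")
    rates = transfer(xs, params.transfer)
    return autocorrelation(xs, rates, dt=dt, max_lag=max_lag, burn_in=burn_in)


# --- Gaussian closures ------------------------------------------------------

def gaussian_rate_mean(
    mu: float, Delta0: float, tf: TransferParams, z_max: float = 10.0
) -> float:
    """<phi> = int Dz phi(mu + sqrt(Delta0) z) by adaptive quadrature.

    The integrand is split at the two kinks of the transfer function so
    the quadrature sees only smooth pieces; agrees with the closed form
    to better than 1e-8.
    """
    if Delta0 < 0:
        if Delta0 < -1e-12:
            raise ValueError(f"Delta0 must be >= 0, got {Delta0}")
        Delta0 = 0.0
    if Delta0 == 0.0:
        return float(transfer(mu, tf))
    sigma = np.sqrt(Delta0)
    kinks = [
        z for z in ((tf.gamma - mu) / sigma, (tf.gamma + tf.phi_max - mu) / sigma)
        if -z_max < z < z_max
    ]

    def integrand(z: float) -> float:
        return float(transfer(mu + sigma * z, tf)) * np.exp(-z * z / 2.0)

    val, _ = scipy.integrate.quad(
        integrand, -z_max, z_max, points=sorted(kinks) or None, limit=200,
        epsabs=1e-12, epsrel=1e-12,
    )
    return val / np.sqrt(2.0 * np.pi)


def gaussian_rate_mean_closed(
    mu: float, Delta0: float, tf: TransferParams
) -> float:
    """Closed form of the Gaussian rate mean for the piecewise-linear phi.

    With X ~ N(mu, Delta0), a = gamma, b = gamma + phi_max:
    <phi> = (mu - gamma)(Phi(beta) - Phi(alpha)) +
            sigma (pdf(alpha) - pdf(beta)) + phi_max (1 - Phi(beta)).
    """
    if Delta0 < 0:
        raise ValueError(f"Delta0 must be >= 0, got {Delta0}")
    if Delta0 == 0.0:
        return float(transfer(mu, tf))
    sigma = np.sqrt(Delta0)
    a, b = tf.gamma, tf.gamma + tf.phi_max
    alpha, beta = (a - mu) / sigma, (b - mu) / sigma
    norm = scipy.stats.norm
    lin = (mu - tf.gamma) * (norm.cdf(beta) - norm.cdf(alpha)) + sigma * (
        norm.pdf(alpha) - norm.pdf(beta)
    )
    return float(lin + tf.phi_max * norm.sf(beta))


def gaussian_rate_autocorr(
    mu: float,
    Delta0: float,
    Delta_tau: float,
    tf: TransferParams,
    degree: int = 120,
) -> float:
    """Rate second moment C(tau) for current moments (mu, Delta0, Delta_tau).

    The currents at t and t + tau are written as correlated Gaussians
    sharing a component z3 of variance |Delta(tau)| (with the sign of
    Delta(tau) carried by the first factor); conditioning on z3 the two
    factors are independent Gaussian rate means, integrated over z3 by
    Gauss-Hermite quadrature.
    """
    if abs(Delta_tau) > Delta0 + 1e-10 * max(Delta0, 1.0):
        raise ValueError(
            f"|Delta(tau)|={abs(Delta_tau)} exceeds Delta(0)={Delta0}"
        )
    Delta_tau = float(np.clip(Delta_tau, -Delta0, Delta0))
    var_c = Delta0 - abs(Delta_tau)
    s = float(np.sign(Delta_tau))
    root = np.sqrt(abs(Delta_tau))
    if var_c <= 1e-14 * max(Delta0, 1.0):
        # perfectly (anti-)correlated limit: a single Gaussian integral,
        # done adaptively because the integrand is kinked
        sigma = np.sqrt(Delta0)

        def integrand(z: float) -> float:
            a = float(transfer(mu + sigma * z, tf))
            b = float(transfer(mu + s * sigma * z, tf))
            return a * b * np.exp(-z * z / 2.0)

        val, _ = scipy.integrate.quad(
            integrand, -10.0, 10.0, limit=200, epsabs=1e-12, epsrel=1e-12
        )
        return val / np.sqrt(2.0 * np.pi)
    nodes, weights = np.polynomial.hermite.hermgauss(degree)
    z3 = np.sqrt(2.0) * nodes
    f2 = np.array(
        [gaussian_rate_mean_closed(mu + root * z, var_c, tf) for z in z3]
    )
    if s >= 0:
        f1 = f2
    else:
        f1 = np.array(
            [gaussian_rate_mean_closed(mu - root * z, var_c, tf) for z in z3]
        )
    return float(np.sum(weights * f1 * f2) / np.sqrt(np.pi))


# --- self-consistency loop --------------------------------------------------

def dmft_solve(
    params: UnitParams,
    J_eff: float,
    J_cs: float,
    sigma_eta: float = 0.0,
    alpha: float = 0.6,
    tol: float = 2e-3,
    tol_rel: float = 0.015,
    max_iter: int = 80,
    T: float | None = None,
    dt: float = 0.05,
    trials: int = 100,
    seed: int = 0,
    max_lag: float | None = None,
    init_mean: float | None = None,
    init_spectral_density: float = 1.0,
) -> DMFTState:
    """Damped fixed-point iteration on the noise moments.

    Each iteration simulates the prototype unit under the current xi
    statistics, re-estimates <phi> and C(tau), and partially updates

        [xi]    <- (1 - alpha) [xi]    + alpha J_eff <phi>
        [xi xi] <- (1 - alpha) [xi xi] + alpha J_cs^2 (C - <phi>^2)

    (the intrinsic-noise delta sigma_eta^2/2 is added at simulation
    time).  Convergence requires the sup-norm change of both moments to
    stay below max(tol, tol_rel * peak autocovariance) for three
    consecutive iterations — the relative part keeps the threshold above
    the Monte-Carlo estimator noise of a fluctuating solution, the
    absolute part handles the collapse to the quiescent one.  Otherwise
    the state is returned with ``converged=False`` and the full residual
    history (the scheme is known to struggle close to bifurcations).

    The iteration starts from white noise with spectral density
    ``init_spectral_density`` and mean ``init_mean`` (default: the
    noise-free fixed-point value J_eff <phi(x0)>).
    """
    tm, t_hidden = params.tau_m, params.tau_slow
    if T is None:
        T = 200.0 * max(tm, t_hidden)
    if max_lag is None:
        max_lag = min(10.0 * max(tm, t_hidden), T / 8.0)
    L = int(round(max_lag / dt))
    lags = np.arange(L + 1) * dt

    if init_mean is None:
        fp = fixed_point(params, J_eff)
        init_mean = J_eff * fp.rate0 if fp.regime != "none" else 0.0
    mean = float(init_mean)
    autocov = np.zeros(L + 1)
    autocov[0] = init_spectral_density / dt

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(max_iter)
    history: list[dict] = []
    clip_warnings: list[str] = []
    estimate = None
    streak = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rng = np.random.default_rng(child_seeds[it - 1])
        estimate = single_unit_stochastic_sim(
            params,
            noise_mean=mean,
            noise_autocorr=autocov,
            sigma_eta=sigma_eta,
            T=T,
            dt=dt,
            trials=trials,
            seed=rng,
            max_lag=max_lag,
        )
        new_mean = J_eff * estimate.mean_rate
        new_autocov = J_cs**2 * (estimate.C - estimate.mean_rate**2)
        d_mean = abs(new_mean - mean)
        d_cov = float(np.max(np.abs(new_autocov - autocov)))
        mean = (1.0 - alpha) * mean + alpha * new_mean
        autocov = (1.0 - alpha) * autocov + alpha * new_autocov
        history.append(
            {"iteration": it, "d_mean": d_mean, "d_autocov": d_cov,
             "mean_rate": estimate.mean_rate, "Delta0": float(estimate.Delta[0])}
        )
        tol_eff = max(tol, tol_rel * float(np.abs(autocov).max()))
        streak = streak + 1 if max(d_mean, d_cov) < tol_eff else 0
        if streak >= 3:
            converged = True
            break
    return DMFTState(
        estimate=estimate,  # type: ignore[arg-type]
        noise_mean=mean,
        noise_autocorr=autocov,
        lags=lags,
        alpha=alpha,
        iterations=it,
        history=tuple(history),
        converged=converged,
        clip_warnings=tuple(clip_warnings),
    )
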