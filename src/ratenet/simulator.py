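"""Direct Euler-Maruyama integration of the full 2N-dimensional network.

Adaptation:
    tau_m dx_i = (-x_i + sum_j J_ij phi(x_j) - g_w w_i + I_i + eta_i) dt
    tau_w dw_i = (-w_i + x_i - gamma) dt
Synaptic filtering:
    tau_m dx_i = (-x_i + s_i) dt
    tau_s ds_i = (-s_i + sum_j J_ij phi(x_j) + I_i + eta_i) dt

The intrinsic white noise eta_i has <eta_i(t) eta_j(t')> =
delta_ij (sigma_eta^2/2) delta(t - t') and enters where external input
enters the model: the current equation for adaptation, the synaptic
variable for filtering (where it is low-pass filtered along with the
recurrent input).  Discretized, the noisy equation receives a per-step
increment of standard deviation (sigma_eta / tau) sqrt(dt / 2) with tau
the time constant of that equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ADAPTATION, NoiseParams, UnitParams, transfer
from .connectivity import ConnectivityMatrix
from .meanfield import fixed_point

__all__ = ["Trajectory", "simulate", "population_average"]

_DT_SAFETY = 0.1  # dt must not exceed this fraction of the fastest time constant


@dataclass(frozen=True)
class Trajectory:
    """Sampled network state: currents, hidden variables and rates."""

    times: np.ndarray
    x: np.ndarray  # (N, T) currents
    hidden: np.ndarray  # (N, T) adaptation or synaptic variables
    dt: float
    seed: int
    params: UnitParams
    noise: NoiseParams
    rates: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rates is None:
            object.__setattr__(
                self, "rates", transfer(self.x, self.params.transfer)
            )
        if self.x.shape != self.hidden.shape or self.x.shape[1] != len(self.times):
            raise ValueError("inconsistent trajectory shapes")


def simulate(
    W: ConnectivityMatrix,
    params: UnitParams,
    noise: NoiseParams | None = None,
    T: float = 100.0,
    dt: float | None = None,
    init: str | tuple[np.ndarray, np.ndarray] = "fixed_point",
    I_ext: np.ndarray | None = None,
    record_every: int = 1,
    record_units: int | np.ndarray | None = None,
    nonlinear_adaptation: bool = False,
) -> Trajectory:
    """Integrate the network for a duration T with step dt.

    ``init`` is either the string ``"fixed_point"`` (equilibrium state plus
    i.i.d. uniform(-0.01, 0.01) current perturbation) or an explicit
    (x0, hidden0) pair of length-N arrays.  ``I_ext``, if given, is an
    (N, n_steps) or (n_steps,) external input added where synaptic input
    enters.  ``record_every`` thins the stored samples; ``record_units``
    (a count or an index array) stores only a subset of units, keeping
    memory bounded for large networks — integration always uses the full
    state.

    ``nonlinear_adaptation`` switches the adaptation drive from the
    linearized (x - gamma) to the full phi(x); it is off by default and
    excluded from all calibrated analyses.
    """
    noise = noise or NoiseParams()
    tm = params.tau_m
    t_hidden = params.tau_slow
    max_dt = _DT_SAFETY * min(tm, t_hidden)
    if dt is None:
        dt = 0.05 * tm
    if dt > max_dt + 1e-12:
        raise ValueError(
            f"dt={dt} too large; require dt <= 0.1 * min(tau_m, tau_hidden)"
            f" = {max_dt}"
        )
    N = W.N
    n_steps = int(round(T / dt))
    adapt = params.mechanism == ADAPTATION
    gamma = params.transfer.gamma

    rng = np.random.default_rng(noise.seed)
    if isinstance(init, str):
        if init != "fixed_point":
            raise ValueError(f"unknown init keyword {init!r}")
        fp = fixed_point(params, W.J_eff)
        if fp.regime == "none":
            raise ValueError("no fixed point available for init")
        x = np.full(N, fp.x0) + rng.uniform(-0.01, 0.01, size=N)
        if adapt:
            hidden = np.full(N, fp.x0 - gamma)
        else:
            hidden = np.full(N, fp.x0)
    else:
        x = np.array(init[0], dtype=float)
        hidden = np.array(init[1], dtype=float)
        if x.shape != (N,) or hidden.shape != (N,):
            raise ValueError("explicit init must be two length-N arrays")

    if record_units is None:
        rec_idx = np.arange(N)
    elif np.isscalar(record_units):
        rec_idx = (
            np.arange(N)
            if record_units >= N
            else rng.choice(N, size=int(record_units), replace=False)
        )
    else:
        rec_idx = np.asarray(record_units, dtype=int)

    tau_in = tm if adapt else params.tau_s
    noise_scale = (noise.sigma_eta / tau_in) * np.sqrt(dt / 2.0)

    n_rec = n_steps // record_every + 1
    xs = np.empty((len(rec_idx), n_rec))
    hs = np.empty((len(rec_idx), n_rec))
    ts = np.empty(n_rec)
    xs[:, 0], hs[:, 0], ts[0] = x[rec_idx], hidden[rec_idx], 0.0
    k = 1

    Wcsr = W.weights
    for step in range(1, n_steps + 1):
        phi = transfer(x, params.transfer)
        rec = Wcsr @ phi
        if I_ext is not None:
            rec = rec + (
                I_ext[:, step - 1] if I_ext.ndim == 2 else I_ext[step - 1]
            )
        if adapt:
            dx = (-x + rec - params.g_w * hidden) * (dt / tm)
            w_in = (phi if nonlinear_adaptation else x - gamma)
            dh = (-hidden + w_in) * (dt / params.tau_w)
            if noise_scale > 0:
                dx += noise_scale * rng.standard_normal(N)
        else:
            dx = (-x + hidden) * (dt / tm)
            dh = (-hidden + rec) * (dt / params.tau_s)
            if noise_scale > 0:
                dh += noise_scale * rng.standard_normal(N)
        x = x + dx
        hidden = hidden + dh
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"integration blew up at t={step * dt:.3f}"
            )
        if step % record_every == 0:
            xs[:, k], hs[:, k], ts[k] = x[rec_idx], hidden[rec_idx], step * dt
            k += 1
    return Trajectory(
        times=ts[:k],
        x=xs[:, :k],
        hidden=hs[:, :k],
        dt=dt * record_every,
        seed=noise.seed,
        params=params,
        noise=noise,
    )


def population_average(traj: Trajectory) -> np.ndarray:
    """Mean firing rate across units at each recorded time."""
    return traj.rates.mean(axis=0)
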