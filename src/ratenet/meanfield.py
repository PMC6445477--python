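"""Fixed points and population-averaged (homogeneous-mode) linear dynamics.

Because the connectivity has constant in-degree, a perturbation that is
identical across units evolves under a single 2x2 linear system whose only
coupling parameter is the effective recurrent input J_eff = J(C_E - g C_I).
This module finds the network fixed points, assembles the 2x2 Jacobian of
the population-averaged dynamics, classifies its stability (saddle-node
vs Hopf boundaries) and gives the slow-limit closed forms for the two
response timescales and the homogeneous-response filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ADAPTATION, UnitParams, transfer, transfer_derivative
from .single_unit import (
    EigenPair2D,
    LinearFilter,
    _eig2,
    filter_from_matrix,
)

__all__ = [
    "FixedPoint",
    "PopAvgReport",
    "fixed_point",
    "popavg_jacobian",
    "popavg_eigensystem",
    "popavg_filter",
    "popavg_stability",
    "popavg_slow_limit",
]

_MARGIN_TOL = 1e-9

STABLE = "stable"
SADDLE_NODE_UNSTABLE = "saddle_node_unstable"
HOPF_UNSTABLE = "hopf_unstable"
MARGINAL = "marginal"


@dataclass(frozen=True)
class FixedPoint:
    """Self-consistent equilibrium current of the population.

    ``regime`` names the branch of the transfer function the primary
    solution sits on; ``all_solutions`` lists every self-consistent
    (x0, regime) pair found across the three branches.
    """

    x0: float
    rate0: float
    regime: str
    all_solutions: tuple[tuple[float, str], ...]


@dataclass(frozen=True)
class PopAvgReport:
    """Stability report for the population-averaged 2x2 dynamics."""

    jacobian: np.ndarray = field(repr=False)
    eigen: EigenPair2D
    classification: str
    critical_couplings: dict
    slow_limit_timescales: tuple[float, float] | None
    filter: LinearFilter | None


def _solutions_synaptic(J_eff: float, gamma: float, phi_max: float):
    sols = []
    # silent branch: phi = 0, x0 = 0, valid if x0 <= gamma
    if 0.0 <= gamma:
        sols.append((0.0, "silent"))
    # linear branch: x0 = J_eff (x0 - gamma)
    if abs(1.0 - J_eff) > 1e-14:
        x0 = -J_eff * gamma / (1.0 - J_eff)
        if gamma < x0 < gamma + phi_max:
            sols.append((x0, "linear"))
    # saturated branch: x0 = J_eff phi_max
    x0 = J_eff * phi_max
    if x0 >= gamma + phi_max:
        sols.append((x0, "saturated"))
    return sols


def _solutions_adaptive(J_eff: float, g_w: float, gamma: float, phi_max: float):
    sols = []
    # silent: (1+g_w) x0 = g_w gamma
    x0 = g_w * gamma / (1.0 + g_w)
    if x0 <= gamma:
        sols.append((x0, "silent"))
    # linear: (1+g_w) x0 = J_eff (x0 - gamma) + g_w gamma
    denom = 1.0 + g_w - J_eff
    if abs(denom) > 1e-14:
        x0 = gamma * (g_w - J_eff) / denom
        if gamma < x0 < gamma + phi_max:
            sols.append((x0, "linear"))
    # saturated: (1+g_w) x0 = J_eff phi_max + g_w gamma
    x0 = (J_eff * phi_max + g_w * gamma) / (1.0 + g_w)
    if x0 >= gamma + phi_max:
        sols.append((x0, "saturated"))
    return sols


def fixed_point(params: UnitParams, J_eff: float) -> FixedPoint:
    """All self-consistent population fixed points for a given J_eff.

    Scans the silent, linear and saturated branches of the transfer
    function.  The linear-regime solution, when it exists, is returned as
    primary (the linear analysis is carried out around it); otherwise the
    first solution found is primary.  An empty solution set is reported
    with ``regime='none'`` rather than raised.
    """
    tf = params.transfer
    if params.mechanism == ADAPTATION:
        sols = _solutions_adaptive(J_eff, params.g_w, tf.gamma, tf.phi_max)
    else:
        sols = _solutions_synaptic(J_eff, tf.gamma, tf.phi_max)
    for x0, regime in sols:
        resid = _residual(params, J_eff, x0)
        if abs(resid) > 1e-10:
            raise AssertionError(
                f"fixed-point residual {resid:.2e} for x0={x0} ({regime})"
            )
    if not sols:
        return FixedPoint(np.nan, np.nan, "none", ())
    primary = next(
        ((x0, r) for x0, r in sols if r == "linear"), sols[0]
    )
    x0, regime = primary
    return FixedPoint(
        x0=x0,
        rate0=float(transfer(x0, tf)),
        regime=regime,
        all_solutions=tuple(sols),
    )


def _residual(params: UnitParams, J_eff: float, x0: float) -> float:
    """Defect of the transcendental fixed-point equation at x0."""
    phi0 = float(transfer(x0, params.transfer))
    if params.mechanism == ADAPTATION:
        return (1.0 + params.g_w) * x0 - (
            J_eff * phi0 + params.g_w * params.transfer.gamma
        )
    return x0 - J_eff * phi0


def popavg_jacobian(
    params: UnitParams, J_eff: float, phi_prime: float
) -> np.ndarray:
    """2x2 dynamic matrix of the population-averaged linear response.

    For synaptic filtering the recurrent term phi' J_eff enters the
    s-equation; for adaptation it enters the diagonal of the x-equation.
    With J_eff = 0 or phi' = 0 the matrix reduces to the single-unit one.
    """
    tm = params.tau_m
    if params.mechanism == ADAPTATION:
        tw, gw = params.tau_w, params.g_w
        return np.array(
            [
                [(-1.0 + phi_prime * J_eff) / tm, -gw / tm],
                [1.0 / tw, -1.0 / tw],
            ]
        )
    ts = params.tau_s
    return np.array(
        [[-1.0 / tm, 1.0 / tm], [phi_prime * J_eff / ts, -1.0 / ts]]
    )


def popavg_eigensystem(
    params: UnitParams, J_eff: float, phi_prime: float = 1.0
) -> EigenPair2D:
    A = popavg_jacobian(params, J_eff, phi_prime)
    lp, lm, vp, vm = _eig2(A)
    return EigenPair2D(A, lp, lm, vp, vm)


def popavg_filter(
    params: UnitParams, J_eff: float, phi_prime: float = 1.0
) -> LinearFilter:
    """Exact filter of the population-averaged response to a common input.

    The input enters where external input enters the model: the current
    equation for adaptation, the synaptic variable for filtering.
    """
    A = popavg_jacobian(params, J_eff, phi_prime)
    if params.mechanism == ADAPTATION:
        return filter_from_matrix(A, in_idx=0, in_scale=1.0 / params.tau_m)
    return filter_from_matrix(A, in_idx=1, in_scale=1.0 / params.tau_s)


def popavg_stability(
    params: UnitParams, J_eff: float, phi_prime: float | None = 1.0
) -> PopAvgReport:
    """Classify the population-averaged dynamics.

    Synaptic filtering: stable iff J_eff < 1, saddle-node boundary at
    J_eff = 1 for any (tau_m, tau_s).  Adaptation: stable iff
    J_eff < min(1 + g_w, 1 + tau_m/tau_w); the active boundary is the
    Hopf one (trace crossing) when tau_m/tau_w < g_w, else the
    saddle-node (determinant crossing).  Boundary equalities within
    1e-9 are reported as ``marginal``.

    The default ``phi_prime=1`` classifies the linear-regime branch (the
    equilibrium is assumed inside the linear range of the transfer
    function, which is where the phase-diagram boundaries live).  Pass
    ``phi_prime=None`` to derive the slope from the actual fixed point
    instead; off the linear regime that yields phi' = 0, i.e. always
    stable single-unit dynamics.
    """
    if phi_prime is None:
        fp = fixed_point(params, J_eff)
        phi_prime = (
            1.0
            if fp.regime == "linear"
            else 0.0
            if fp.regime == "none"
            else float(transfer_derivative(fp.x0, params.transfer))
        )
    eigen = popavg_eigensystem(params, J_eff, phi_prime)
    A = eigen.matrix
    tr = A[0, 0] + A[1, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]

    if params.mechanism == ADAPTATION:
        crit = {
            "saddle_node": 1.0 + params.g_w,
            "hopf": 1.0 + params.tau_m / params.tau_w,
        }
    else:
        crit = {"saddle_node": 1.0}

    if abs(det) <= _MARGIN_TOL or (det > 0 and abs(tr) <= _MARGIN_TOL):
        cls = MARGINAL
    elif det < 0:
        cls = SADDLE_NODE_UNSTABLE
    elif tr > 0:
        cls = HOPF_UNSTABLE
    else:
        cls = STABLE

    slow = filt = None
    if cls == STABLE and phi_prime == 1.0:
        try:
            slow, filt = popavg_slow_limit(params, J_eff)
        except ValueError:
            pass
    return PopAvgReport(
        jacobian=A,
        eigen=eigen,
        classification=cls,
        critical_couplings=crit,
        slow_limit_timescales=slow,
        filter=filt,
    )


def popavg_slow_limit(
    params: UnitParams, J_eff: float
) -> tuple[tuple[float, float], LinearFilter]:
    """Slow-hidden-variable closed forms for timescales and filter.

    Synaptic (tau_s >> tau_m):
        tau+ = tau_s / (1 - J_eff)            [slow mode]
        tau- = tau_m / (1 + J_eff tau_m/tau_s)  [fast mode]
    with equal-magnitude mode amplitudes (from the leading-order
    eigenvector expansion).

    Adaptation (tau_w >> tau_m):
        tau+ = tau_m / (1 - J_eff)
        tau- = tau_w (1 - J_eff) / (1 + g_w - J_eff)
    with the slow-mode area tending to
    -g_w / ((J_eff - 1)(J_eff - 1 - g_w)).

    Both sets derive from the leading-order expansion of the exact 2x2
    eigenvalues; they require a stable configuration.
    """
    tm = params.tau_m
    if params.mechanism == ADAPTATION:
        tw, gw = params.tau_w, params.g_w
        if J_eff >= min(1.0 + gw, 1.0 + tm / tw):
            raise ValueError("slow-limit timescales require a stable J_eff")
        lam_fast = (J_eff - 1.0) / tm  # the mode on the membrane timescale
        lam_slow = -(1.0 + gw - J_eff) / (tw * (1.0 - J_eff))
        tau_plus = -1.0 / lam_fast
        tau_minus = -1.0 / lam_slow
        # amplitudes from the printed slow-adaptation filter
        a_fast = (
            (1.0 / tm)
            * (J_eff - 1.0 + (tm / tw) * (1.0 - gw * J_eff))
            / (J_eff - 1.0 + (tm / tw) * (1.0 - 2.0 * gw * J_eff))
        )
        a_slow = -gw / (tw * (J_eff - 1.0) ** 2 + tm * (J_eff - 1.0 - 2.0 * gw))
        filt = LinearFilter((a_fast, a_slow), (lam_fast, lam_slow))
        return (tau_plus, tau_minus), filt
    ts = params.tau_s
    if J_eff >= 1.0:
        raise ValueError("slow-limit timescales require J_eff < 1")
    lam_plus = (J_eff - 1.0) / ts
    lam_minus = -1.0 / tm - J_eff / ts
    tau_plus = -1.0 / lam_plus
    tau_minus = -1.0 / lam_minus
    a = (
        (1.0 / ts)
        * (ts - tm * (1.0 - J_eff))
        / (ts - tm * (1.0 - 2.0 * J_eff))
    )
    filt = LinearFilter((a, -a), (lam_plus, lam_minus))
    return (tau_plus, tau_minus), filt
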