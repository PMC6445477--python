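"""Single-unit impulse-response filters and their timescales.

An isolated unit is a two-variable linear system, so its current response
to an input I(t) is a convolution x = h * I with a causal filter

    h(t) = sum_k a_k t^{p_k} exp(lambda_k t),   t >= 0,

a sum of (possibly complex-conjugate) exponential modes; the polynomial
powers p_k are only nonzero in the degenerate equal-rate case.  The two
mechanisms differ qualitatively:

* synaptic filtering: two modes of equal magnitude and opposite sign with
  rates -1/tau_s and -1/tau_m — the response rises on tau_m and decays on
  tau_s, and the effective timescale grows proportionally to tau_s;
* adaptation: the slow mode's amplitude shrinks as 1/tau_w, so its area
  saturates at -g_w/(1+g_w) and the effective timescale is bounded no
  matter how slow adaptation is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np

from .model_core import ADAPTATION, SYNAPTIC, UnitParams

__all__ = [
    "LinearFilter",
    "EigenPair2D",
    "single_unit_matrix",
    "filter_from_matrix",
    "synaptic_filter",
    "adaptive_eigensystem",
    "adaptive_filter",
    "unit_filter",
    "filter_response",
    "filter_timescale",
    "white_noise_variance_gain",
]

_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class LinearFilter:
    """Sum-of-modes causal filter h(t) = sum_k a_k t^{p_k} e^{lambda_k t}.

    ``amplitudes`` and ``rates`` are conjugate-closed so h is real-valued;
    ``powers`` holds the polynomial degree of each mode (0 except in the
    degenerate equal-rate limit, where h picks up a factor of t).
    """

    amplitudes: tuple[complex, ...]
    rates: tuple[complex, ...]
    powers: tuple[int, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.powers is None:
            object.__setattr__(self, "powers", (0,) * len(self.amplitudes))
        if not (len(self.amplitudes) == len(self.rates) == len(self.powers)):
            raise ValueError("modes must have matching lengths")

    @property
    def polynomial(self) -> bool:
        """True if any mode carries a power of t (degenerate rates)."""
        return any(p > 0 for p in self.powers)

    @property
    def stable(self) -> bool:
        return all(np.real(r) < 0 for r in self.rates)

    def __call__(self, t) -> np.ndarray:
        """Evaluate h on times t (h = 0 for t < 0)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=complex)
        pos = t >= 0
        for a, lam, p in zip(self.amplitudes, self.rates, self.powers):
            out[pos] += a * t[pos] ** p * np.exp(lam * t[pos])
        return out.real

    @property
    def area(self) -> float:
        """Integral of h over t >= 0 (finite for stable filters)."""
        total = 0.0 + 0.0j
        for a, lam, p in zip(self.amplitudes, self.rates, self.powers):
            total += a * math.factorial(p) / (-lam) ** (p + 1)
        return float(total.real)

    def mode_areas(self) -> np.ndarray:
        """Per-mode integrals a_k p_k! / (-lambda_k)^{p_k+1}."""
        return np.array(
            [
                a * math.factorial(p) / (-lam) ** (p + 1)
                for a, lam, p in zip(self.amplitudes, self.rates, self.powers)
            ]
        )


@dataclass(frozen=True)
class EigenPair2D:
    """Eigen-decomposition of a 2x2 dynamic matrix."""

    matrix: np.ndarray
    lambda_plus: complex
    lambda_minus: complex
    xi_plus: np.ndarray = field(repr=False)
    xi_minus: np.ndarray = field(repr=False)

    @property
    def timescales(self) -> tuple[float, float]:
        """(tau_plus, tau_minus) = -1/Re(lambda) for each branch."""
        return (
            -1.0 / float(np.real(self.lambda_plus)),
            -1.0 / float(np.real(self.lambda_minus)),
        )


def single_unit_matrix(params: UnitParams) -> np.ndarray:
    """2x2 dynamic matrix of an isolated unit, state (x, hidden)."""
    tm = params.tau_m
    if params.mechanism == ADAPTATION:
        tw, gw = params.tau_w, params.g_w
        return np.array([[-1.0 / tm, -gw / tm], [1.0 / tw, -1.0 / tw]])
    ts = params.tau_s
    return np.array([[-1.0 / tm, 1.0 / tm], [0.0, -1.0 / ts]])


def _eig2(A: np.ndarray) -> tuple[complex, complex, np.ndarray, np.ndarray]:
    """Closed-form eigensystem of a 2x2 matrix, (+) branch first."""
    a, b, c, d = A[0, 0], A[0, 1], A[1, 0], A[1, 1]
    tr, det = a + d, a * d - b * c
    disc = complex(tr * tr / 4.0 - det)
    root = np.sqrt(disc)
    lp, lm = tr / 2.0 + root, tr / 2.0 - root
    vecs = []
    for lam in (lp, lm):
        if abs(b) > 0:
            v = np.array([b, lam - a], dtype=complex)
        elif abs(c) > 0:
            v = np.array([lam - d, c], dtype=complex)
        else:  # diagonal matrix
            v = np.array([1.0, 0.0]) if lam == a else np.array([0.0, 1.0])
        vecs.append(v / np.linalg.norm(v))
    return lp, lm, vecs[0], vecs[1]


def filter_from_matrix(A: np.ndarray, in_idx: int, in_scale: float) -> LinearFilter:
    """Impulse response from input channel ``in_idx`` to the first state.

    For dz/dt = A z + e_{in_idx} in_scale I(t), returns the filter h with
    x(t) = (h * I)(t), i.e. h(t) = in_scale [exp(A t)]_{0, in_idx}.
    Degenerate (defective) matrices get an explicit polynomial-in-t mode.
    """
    lp, lm, vp, vm = _eig2(A)
    scale = abs(lp) + abs(lm)
    if abs(lp - lm) <= _DEGENERATE_RTOL * max(scale, 1.0):
        # exp(At) = e^{lam t} (I + (A - lam I) t)
        lam = (lp + lm) / 2.0
        N = A - lam.real * np.eye(2)
        a0 = in_scale * (1.0 if in_idx == 0 else 0.0)
        a1 = in_scale * N[0, in_idx]
        amps, rates, powers = [], [], []
        if a0 != 0.0:
            amps.append(a0); rates.append(lam); powers.append(0)
        amps.append(a1); rates.append(lam); powers.append(1)
        return LinearFilter(tuple(amps), tuple(rates), tuple(powers))
    V = np.column_stack([vp, vm]).astype(complex)
    Vinv = np.linalg.inv(V)
    a_p = in_scale * V[0, 0] * Vinv[0, in_idx]
    a_m = in_scale * V[0, 1] * Vinv[1, in_idx]
    return LinearFilter((complex(a_p), complex(a_m)), (complex(lp), complex(lm)))


def synaptic_filter(tau_m: float, tau_s: float) -> LinearFilter:
    """Filter of a unit with synaptic filtering (input drives the s-variable).

    h_s(t) = (e^{-t/tau_s} - e^{-t/tau_m}) / (tau_s - tau_m): two modes of
    equal magnitude and opposite sign, unit total area.  The equal-rate
    limit tau_s = tau_m is represented exactly as t e^{-t/tau_m} / tau_m^2.
    """
    if not (tau_m > 0 and tau_s > 0):
        raise ValueError("tau_m and tau_s must be positive")
    if abs(tau_s - tau_m) <= _DEGENERATE_RTOL * max(tau_s, tau_m):
        tau = 0.5 * (tau_s + tau_m)
        return LinearFilter((1.0 / tau**2,), (-1.0 / tau,), (1,))
    a = 1.0 / (tau_s - tau_m)
    return LinearFilter((a, -a), (-1.0 / tau_s, -1.0 / tau_m))


def adaptive_eigensystem(tau_m: float, tau_w: float, g_w: float) -> EigenPair2D:
    """Eigenvalues/vectors of the adaptive unit's 2x2 dynamic matrix.

    lambda_w^{+/-} = (-1/tau_m - 1/tau_w)/2
                     +/- sqrt((1/tau_m + 1/tau_w)^2 - 4(1+g_w)/(tau_m tau_w))/2;
    complex iff g_w > (tau_w - tau_m)^2 / (4 tau_m tau_w), in which case
    Re lambda = -(tau_m + tau_w) / (2 tau_m tau_w).
    """
    if not (tau_m > 0 and tau_w > 0 and g_w >= 0):
        raise ValueError("require tau_m, tau_w > 0 and g_w >= 0")
    A = single_unit_matrix(
        UnitParams(tau_m=tau_m, mechanism=ADAPTATION, tau_w=tau_w, g_w=g_w)
    )
    lp, lm, vp, vm = _eig2(A)
    return EigenPair2D(A, lp, lm, vp, vm)


def adaptive_filter(tau_m: float, tau_w: float, g_w: float) -> LinearFilter:
    """Filter of an adaptive unit (input drives the current directly).

    h_w(0+) = 1/tau_m; for slow adaptation the slow mode tends to
    (-g_w/tau_w) e^{-(1+g_w) t / tau_w} so its area saturates at
    -g_w/(1+g_w) independently of tau_w.
    """
    es = adaptive_eigensystem(tau_m, tau_w, g_w)
    return filter_from_matrix(es.matrix, in_idx=0, in_scale=1.0 / tau_m)


def unit_filter(params: UnitParams) -> LinearFilter:
    """Filter of an isolated unit for the given mechanism."""
    if params.mechanism == ADAPTATION:
        return adaptive_filter(params.tau_m, params.tau_w, params.g_w)
    return synaptic_filter(params.tau_m, params.tau_s)


def filter_response(h: LinearFilter, inp: np.ndarray, dt: float) -> np.ndarray:
    """Causal discrete convolution of a sampled input with the filter.

    The filter is sampled on the input grid; a discrete delta of height
    1/dt returns the filter samples up to O(dt).
    """
    inp = np.asarray(inp, dtype=float)
    if inp.ndim != 1:
        raise ValueError("input must be one-dimensional")
    t = np.arange(len(inp)) * dt
    kernel = h(t)
    return np.convolve(kernel, inp)[: len(inp)] * dt


def filter_timescale(h: LinearFilter) -> float:
    """Amplitude-weighted average of the mode decay times.

    tau_corr = sum_k |a_k| tau_k / sum_k |a_k| with tau_k = -1/Re(lambda_k).
    Members of a complex-conjugate pair share one decay timescale, so the
    pair contributes a single term (with twice the weight of one member).
    """
    if not h.stable:
        raise ValueError("timescale undefined for unstable filters")
    w = np.abs(np.asarray(h.amplitudes))
    taus = -1.0 / np.real(np.asarray(h.rates))
    return float(np.sum(w * taus) / np.sum(w))


def white_noise_variance_gain(h: LinearFilter) -> float:
    """Output variance under unit-spectral-density white noise input.

    With <I(t) I(t')> = delta(t - t'), Var[x] = int_0^inf h(t)^2 dt,
    evaluated in closed form from the modes:
    int t^{p+q} e^{(l1+l2)t} = (p+q)! / (-(l1+l2))^{p+q+1}.
    """
    if not h.stable:
        raise ValueError("variance gain undefined for unstable filters")
    total = 0.0 + 0.0j
    for a1, l1, p1 in zip(h.amplitudes, h.rates, h.powers):
        for a2, l2, p2 in zip(h.amplitudes, h.rates, h.powers):
            n = p1 + p2
            total += a1 * a2 * math.factorial(n) / (-(l1 + l2)) ** (n + 1)
    return float(total.real)
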