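"""Heterogeneous-mode linear stability of the full 2N-dimensional system.

Modes in which units are perturbed independently are governed by the bulk
of the connectivity eigenvalues lambda_J (a circle of radius
J_cs = J sqrt(C_E + g^2 C_I)).  Each lambda_J maps onto two eigenvalues
lambda of the linearized 2N Jacobian through a quadratic, and conversely
the stability line Re(lambda) = i omega maps to a boundary curve
lambda_J^sb(omega) in the connectivity plane:

* synaptic filtering: lambda_J^sb = (1 + i tau_m omega)(1 + i tau_s omega),
  whose modulus is minimal at omega = 0 with value 1 — filtering never
  changes the critical radius;
* adaptation: lambda_J^sb = 1 + i tau_m omega + g_w/(1 + i tau_w omega),
  whose minimum-modulus point R* >= 1 sits at omega* = 0 (zero-frequency
  bifurcation, rate chaos) iff tau_m/tau_w > g_w + sqrt(2 g_w (g_w + 1)),
  and otherwise at finite omega* (Hopf; per-unit oscillations with
  uncorrelated phases).

The instability condition for the bulk is J_cs > R*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .model_core import ADAPTATION, SYNAPTIC, UnitParams
from .connectivity import ConnectivityMatrix

__all__ = [
    "StabilityReport",
    "ZERO_FREQUENCY",
    "HOPF",
    "forward_map",
    "map_lambda_J_to_modes",
    "boundary_curve",
    "hopf_threshold_ratio",
    "critical_radius",
    "full_jacobian",
    "full_jacobian_spectrum",
]

ZERO_FREQUENCY = "zero_frequency"
HOPF = "hopf"

_FULL_JACOBIAN_GUARD = 1500


@dataclass(frozen=True)
class StabilityReport:
    """Critical radius and bifurcation type of the heterogeneous modes."""

    critical_radius: float
    critical_frequency: float
    bifurcation: str
    omega_grid: np.ndarray = field(repr=False)
    boundary: np.ndarray = field(repr=False)
    mechanism: str = ""
    params: UnitParams | None = None


def forward_map(mechanism: str, lam, params: UnitParams):
    """Map a Jacobian eigenvalue lambda to a connectivity eigenvalue lambda_J."""
    lam = np.asarray(lam, dtype=complex)
    tm = params.tau_m
    if mechanism == ADAPTATION:
        return 1.0 + tm * lam + params.g_w / (1.0 + params.tau_w * lam)
    return (1.0 + tm * lam) * (1.0 + params.tau_s * lam)


def map_lambda_J_to_modes(
    mechanism: str, lambda_J: complex, params: UnitParams
) -> tuple[complex, complex]:
    """The two Jacobian eigenvalues associated with one lambda_J.

    Roots of the quadratic obtained from the characteristic equation:
    synaptic: lam^2 + (tau_s + tau_m)/(tau_s tau_m) lam
              + (1 - lambda_J)/(tau_s tau_m) = 0;
    adaptation: (tau_m lam)^2 + (1 + tau_m/tau_w - lambda_J) tau_m lam
                + (tau_m/tau_w)(1 + g_w - lambda_J) = 0.
    """
    tm = params.tau_m
    if mechanism == ADAPTATION:
        tw, gw = params.tau_w, params.g_w
        # quadratic in u = tau_m * lam
        b = 1.0 + tm / tw - lambda_J
        c = (tm / tw) * (1.0 + gw - lambda_J)
        disc = np.sqrt(complex(b * b - 4.0 * c))
        u1, u2 = (-b + disc) / 2.0, (-b - disc) / 2.0
        return u1 / tm, u2 / tm
    ts = params.tau_s
    b = (ts + tm) / (ts * tm)
    c = (1.0 - lambda_J) / (ts * tm)
    disc = np.sqrt(complex(b * b - 4.0 * c))
    return (-b + disc) / 2.0, (-b - disc) / 2.0


def boundary_curve(
    mechanism: str, params: UnitParams, omega_grid: np.ndarray
) -> np.ndarray:
    """Stability boundary lambda_J^sb(omega): the image of lambda = i omega.

    Conjugate-symmetric under omega -> -omega; evaluated from the exact
    forward mapping.
    """
    omega = np.asarray(omega_grid, dtype=float)
    return forward_map(mechanism, 1j * omega, params)


def hopf_threshold_ratio(g_w: float) -> float:
    """Critical tau_m/tau_w ratio separating the bifurcation types.

    The adaptive bulk undergoes a zero-frequency bifurcation iff
    tau_m/tau_w > g_w + sqrt(2 g_w (g_w + 1)) (curvature comparison of
    the boundary parabola against the eigenvalue circle at omega = 0);
    since tau_m/tau_w < 1 by construction, couplings g_w > sqrt(5) - 2
    admit only the Hopf route.
    """
    return g_w + np.sqrt(2.0 * g_w * (g_w + 1.0))


def critical_radius(
    mechanism: str, params: UnitParams, n_grid: int = 100_000
) -> StabilityReport:
    """Minimum modulus of the boundary curve and the frequency attaining it.

    R* = min_omega |lambda_J^sb(omega)|, omega* = argmin (>= 0).  The
    synaptic curve has |lambda_J^sb|^2 = (1 + tau_m^2 w^2)(1 + tau_s^2 w^2),
    minimized trivially at omega = 0 with R* = 1; the minimizer is still
    located numerically.  For adaptation the bifurcation type follows the
    curvature criterion (see :func:`hopf_threshold_ratio`); in the Hopf
    case the minimum is found on a dense logarithmic grid refined by
    bounded scalar minimization (tolerance 1e-8 on R*).
    """
    tm = params.tau_m
    t_hidden = params.tau_slow
    lo, hi = 1e-4 / t_hidden, 1e2 / tm
    omega = np.concatenate([[0.0], np.geomspace(lo, hi, n_grid)])
    curve = boundary_curve(mechanism, params, omega)
    mod = np.abs(curve)
    k = int(np.argmin(mod))

    def modulus(w: float) -> float:
        return float(np.abs(forward_map(mechanism, 1j * w, params)))

    if mechanism == ADAPTATION and params.tau_m / params.tau_w > hopf_threshold_ratio(
        params.g_w
    ):
        # curvature criterion: minimum sits at omega = 0
        omega_star, r_star = 0.0, modulus(0.0)
        bifurcation = ZERO_FREQUENCY
    elif k == 0:
        omega_star, r_star = 0.0, mod[0]
        bifurcation = ZERO_FREQUENCY
    else:
        a = omega[max(k - 1, 0)]
        b = omega[min(k + 1, len(omega) - 1)]
        res = scipy.optimize.minimize_scalar(
            modulus, bounds=(a, b), method="bounded", options={"xatol": 1e-12}
        )
        omega_star, r_star = float(res.x), float(res.fun)
        bifurcation = HOPF if omega_star > 1e-6 else ZERO_FREQUENCY
        if bifurcation == ZERO_FREQUENCY:
            omega_star, r_star = 0.0, modulus(0.0)
    return StabilityReport(
        critical_radius=r_star,
        critical_frequency=omega_star,
        bifurcation=bifurcation,
        omega_grid=omega,
        boundary=curve,
        mechanism=mechanism,
        params=params,
    )


def full_jacobian(W: ConnectivityMatrix, params: UnitParams) -> np.ndarray:
    """Dense 2N x 2N Jacobian of the linearized network at a linear fixed point.

    State ordering (dx_1..dx_N, dh_1..dh_N) with h the hidden variable;
    the transfer derivative is taken as 1 (linear regime).
    """
    N = W.N
    if N > _FULL_JACOBIAN_GUARD:
        raise ValueError(
            f"N={N} exceeds the dense 2N eigendecomposition guard "
            f"({_FULL_JACOBIAN_GUARD})"
        )
    J = W.dense()
    I = np.eye(N)
    tm = params.tau_m
    A = np.zeros((2 * N, 2 * N))
    if params.mechanism == ADAPTATION:
        tw, gw = params.tau_w, params.g_w
        A[:N, :N] = (J - I) / tm
        A[:N, N:] = -gw / tm * I
        A[N:, :N] = I / tw
        A[N:, N:] = -I / tw
    else:
        ts = params.tau_s
        A[:N, :N] = -I / tm
        A[:N, N:] = I / tm
        A[N:, :N] = J / ts
        A[N:, N:] = -I / ts
    return A


def full_jacobian_spectrum(
    W: ConnectivityMatrix, params: UnitParams
) -> dict:
    """Spectrum of the assembled 2N Jacobian plus its predicted envelope.

    Every Jacobian eigenvalue maps through the forward mapping onto an
    eigenvalue of the connectivity matrix; the returned dict carries the
    eigenvalues, the boundary-curve envelope prediction at the matrix's
    spectral radius, and the worst-case forward-mapping mismatch.
    """
    A = full_jacobian(W, params)
    lam = scipy.linalg.eigvals(A)
    lam_J_pred = forward_map(params.mechanism, lam, params)
    lam_J = np.linalg.eigvals(W.dense())
    # nearest-neighbour mismatch between mapped and actual connectivity eigs
    mismatch = np.array(
        [np.min(np.abs(lam_J - z)) for z in lam_J_pred]
    )
    report = critical_radius(params.mechanism, params, n_grid=10_000)
    theta = np.linspace(0, 2 * np.pi, 721)
    circle = W.radius * np.exp(1j * theta)
    envelope = np.array(
        [
            map_lambda_J_to_modes(params.mechanism, z, params)
            for z in circle
        ]
    )
    return {
        "eigenvalues": lam,
        "mapped_to_connectivity": lam_J_pred,
        "connectivity_eigenvalues": lam_J,
        "mapping_mismatch_max": float(mismatch.max()),
        "critical_radius": report.critical_radius,
        "predicted_envelope": envelope,
        "unstable": bool(np.any(lam.real > 0)),
    }
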