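"""Model parameters and the transfer function.

The units of the network carry an input current ``x`` and a hidden slow
variable implementing one of two mechanisms:

* ``adaptation`` — a variable ``w`` that low-pass filters the (linearized)
  firing rate with time constant ``tau_w`` and feeds back into the current
  with negative coupling ``g_w``;
* ``synaptic`` — a variable ``s`` that low-pass filters the summed synaptic
  input with time constant ``tau_s`` before it drives the current.

The firing rate is obtained from the current through a saturating
threshold-linear transfer function with threshold ``gamma`` and maximum
rate ``phi_max``.  Time is measured in units of the membrane time constant
``tau_m`` by default, but ``tau_m`` is kept explicit so every formula stays
general.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "ADAPTATION",
    "SYNAPTIC",
    "TransferParams",
    "UnitParams",
    "NoiseParams",
    "DEFAULT_NETWORK_CONFIG",
    "transfer",
    "transfer_derivative",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

ADAPTATION = "adaptation"
SYNAPTIC = "synaptic"
_MECHANISMS = (ADAPTATION, SYNAPTIC)

#: Default network parameters (units, in-degrees, weights, transfer function).
DEFAULT_NETWORK_CONFIG = {
    "N": 3000,
    "C": 100,
    "C_E": 80,
    "C_I": 20,
    "g": 4.1,
    "gamma": -0.5,
    "phi_max": 2.0,
}


@dataclass(frozen=True)
class TransferParams:
    """Threshold-linear-saturating transfer function parameters.

    Parameters
    ----------
    gamma : float
        Activation threshold (current units).
    phi_max : float
        Maximum firing rate (rate units); must be positive.
    """

    gamma: float = -0.5
    phi_max: float = 2.0

    def __post_init__(self) -> None:
        if not self.phi_max > 0:
            raise ValueError(f"phi_max must be positive, got {self.phi_max}")


@dataclass(frozen=True)
class UnitParams:
    """Single-unit constants: membrane time constant plus mechanism constants.

    ``mechanism`` selects which hidden variable the unit carries.  For
    ``adaptation`` the coupling ``g_w`` (dimensionless, >= 0) and time
    constant ``tau_w`` must be set; for ``synaptic`` the filter time
    constant ``tau_s`` must be set.  All time constants share the units of
    ``tau_m``.
    """

    tau_m: float = 1.0
    mechanism: str = SYNAPTIC
    g_w: float | None = None
    tau_w: float | None = None
    tau_s: float | None = None
    transfer: TransferParams = field(default_factory=TransferParams)

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if self.mechanism not in _MECHANISMS:
            raise ValueError(
                f"mechanism must be one of {_MECHANISMS}, got {self.mechanism!r}"
            )
        if self.mechanism == ADAPTATION:
            if self.tau_w is None or not self.tau_w > 0:
                raise ValueError("adaptation requires tau_w > 0")
            if self.g_w is None or self.g_w < 0:
                raise ValueError("adaptation requires g_w >= 0")
        else:
            if self.tau_s is None or not self.tau_s > 0:
                raise ValueError("synaptic filtering requires tau_s > 0")

    @property
    def tau_slow(self) -> float:
        """Time constant of the hidden variable for the active mechanism."""
        return self.tau_w if self.mechanism == ADAPTATION else self.tau_s  # type: ignore[return-value]


@dataclass(frozen=True)
class NoiseParams:
    """Intrinsic white-noise input.

    ``sigma_eta`` sets the intensity of the per-unit white noise
    eta_i(t) with <eta_i(t) eta_j(t')> = delta_ij (sigma_eta^2 / 2) delta(t - t').
    """

    sigma_eta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_eta < 0:
            raise ValueError(f"sigma_eta must be >= 0, got {self.sigma_eta}")


def transfer(x, tf: TransferParams):
    """Saturating threshold-linear transfer function phi(x).

    phi(x) = min(max(x - gamma, 0), phi_max): zero below the threshold
    ``gamma``, linear with unit slope above it, clipped at ``phi_max``.
    Accepts scalars or arrays.
    """
    return np.clip(np.asarray(x, dtype=float) - tf.gamma, 0.0, tf.phi_max)


def transfer_derivative(x, tf: TransferParams):
    """Derivative phi'(x): 1 on the open linear region, 0 elsewhere.

    The two kink points (x = gamma and x = gamma + phi_max) return 0;
    linearizations are only ever applied at fixed points strictly inside
    one region.
    """
    x = np.asarray(x, dtype=float)
    return ((x > tf.gamma) & (x < tf.gamma + tf.phi_max)).astype(float)


# --- flat (de)serialization -------------------------------------------------

def params_to_dict(params: UnitParams) -> dict:
    """Flatten UnitParams (and its TransferParams) into one plain dict."""
    d = asdict(params)
    tf = d.pop("transfer")
    d.update(tf)
    return {k: v for k, v in d.items() if v is not None}


def params_from_dict(d: dict) -> UnitParams:
    """Inverse of :func:`params_to_dict`; rejects unknown keys."""
    d = dict(d)
    tf = TransferParams(
        gamma=d.pop("gamma", -0.5), phi_max=d.pop("phi_max", 2.0)
    )
    known = {"tau_m", "mechanism", "g_w", "tau_w", "tau_s"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return UnitParams(transfer=tf, **d)


def save_params(params: UnitParams, path: Union[str, Path]) -> None:
    path = Path(path)
    text = json.dumps(params_to_dict(params), indent=2, sort_keys=True)
    path.write_text(text + "\n")


def load_params(path: Union[str, Path]) -> UnitParams:
    with open(path) as fh:
        return params_from_dict(json.load(fh))
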