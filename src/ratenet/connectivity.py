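"""Sparse constant-in-degree excitatory-inhibitory connectivity.

Every unit receives exactly ``C_E`` excitatory inputs of weight ``+J`` and
``C_I`` inhibitory inputs of weight ``-g*J``; each presynaptic unit is
purely excitatory or purely inhibitory (Dale's principle).  Two ensemble
summaries control the network dynamics:

* the common row sum ``J_eff = J (C_E - g C_I)`` — the outlier eigenvalue
  of the connectivity, order parameter of the population-averaged mode;
* the bulk spectral radius ``J_cs = J sqrt(C_E + g^2 C_I)`` — the radius of
  the circle enclosing the remaining eigenvalues, order parameter of the
  heterogeneous modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ConnectivitySpec",
    "ConnectivityMatrix",
    "effective_coupling",
    "coupling_radius",
    "radius_to_J",
    "build_connectivity",
    "spectrum_summary",
    "save_connectivity",
    "load_connectivity",
]

_DENSE_EIG_GUARD = 5000


@dataclass(frozen=True)
class ConnectivitySpec:
    """Specification of the fixed in-degree E-I ensemble."""

    N: int = 3000
    C_E: int = 80
    C_I: int = 20
    J: float = 1.0
    g: float = 4.1
    seed: int = 0
    allow_self: bool = False

    def __post_init__(self) -> None:
        for name in ("N", "C_E", "C_I"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        budget = self.N - (0 if self.allow_self else 1)
        if self.C_E + self.C_I > budget:
            raise ValueError(
                f"in-degree C_E + C_I = {self.C_E + self.C_I} exceeds the "
                f"{budget} available presynaptic partners"
            )

    @property
    def C(self) -> int:
        return self.C_E + self.C_I

    @property
    def N_E(self) -> int:
        """Excitatory pool size; fraction matches the in-degree split."""
        return int(round(self.N * self.C_E / self.C))

    @property
    def N_I(self) -> int:
        return self.N - self.N_E

    @property
    def J_eff(self) -> float:
        return effective_coupling(self.J, self.C_E, self.C_I, self.g)

    @property
    def radius(self) -> float:
        return coupling_radius(self.J, self.C_E, self.C_I, self.g)


def effective_coupling(J: float, C_E: int, C_I: int, g: float) -> float:
    """Common row sum J (C_E - g C_I) of the connectivity."""
    return J * (C_E - g * C_I)


def coupling_radius(J: float, C_E: int, C_I: int, g: float) -> float:
    """Bulk spectral radius J sqrt(C_E + g^2 C_I)."""
    return J * np.sqrt(C_E + g * g * C_I)


def radius_to_J(radius: float, C_E: int, C_I: int, g: float) -> float:
    """Excitatory weight J giving a requested bulk spectral radius."""
    return radius / np.sqrt(C_E + g * g * C_I)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A sampled weight matrix with its generating spec.

    ``weights`` is an N x N CSR matrix (entry [i, j] couples presynaptic j
    to postsynaptic i); ``e_mask`` flags the excitatory units.
    """

    weights: sp.csr_matrix
    e_mask: np.ndarray
    spec: ConnectivitySpec

    @property
    def N(self) -> int:
        return self.spec.N

    @property
    def J_eff(self) -> float:
        return self.spec.J_eff

    @property
    def radius(self) -> float:
        return self.spec.radius

    def dense(self) -> np.ndarray:
        return self.weights.toarray()


def build_connectivity(spec: ConnectivitySpec) -> ConnectivityMatrix:
    """Sample a constant-in-degree Dale-respecting weight matrix.

    Each row independently draws ``C_E`` excitatory and ``C_I`` inhibitory
    presynaptic partners uniformly without replacement (self-connections
    excluded unless ``allow_self``).  Deterministic given ``spec.seed``.
    """
    N, C_E, C_I = spec.N, spec.C_E, spec.C_I
    N_E = spec.N_E
    if N_E < C_E or spec.N_I < C_I:
        raise ValueError(
            f"pool sizes (N_E={N_E}, N_I={spec.N_I}) cannot supply "
            f"in-degrees (C_E={C_E}, C_I={C_I})"
        )
    e_mask = np.zeros(N, dtype=bool)
    e_mask[:N_E] = True

    rng = np.random.default_rng(spec.seed)
    e_pool = np.arange(N_E)
    i_pool = np.arange(N_E, N)

    rows = np.repeat(np.arange(N), spec.C)
    cols = np.empty(N * spec.C, dtype=np.int64)
    data = np.empty(N * spec.C, dtype=float)
    for i in range(N):
        ep = e_pool if (spec.allow_self or i >= N_E) else e_pool[e_pool != i]
        ip = i_pool if (spec.allow_self or i < N_E) else i_pool[i_pool != i]
        if len(ep) < C_E or len(ip) < C_I:
            raise ValueError(
                f"row {i}: pool too small after excluding self-connection"
            )
        sel_e = rng.choice(ep, size=C_E, replace=False)
        sel_i = rng.choice(ip, size=C_I, replace=False)
        base = i * spec.C
        cols[base : base + C_E] = sel_e
        cols[base + C_E : base + spec.C] = sel_i
        data[base : base + C_E] = spec.J
        data[base + C_E : base + spec.C] = -spec.g * spec.J
    W = sp.csr_matrix((data, (rows, cols)), shape=(N, N))
    return ConnectivityMatrix(weights=W, e_mask=e_mask, spec=spec)


def spectrum_summary(W: ConnectivityMatrix) -> dict:
    """Dense eigenspectrum of the weights plus the ensemble theory values.

    Returns ``eigenvalues`` (complex array), ``radius_theory``
    (J sqrt(C_E + g^2 C_I), encloses the bulk) and ``outlier_theory``
    (J (C_E - g C_I), the row-sum eigenvalue).  Guarded to N <= 5000.
    """
    if W.N > _DENSE_EIG_GUARD:
        raise ValueError(
            f"N={W.N} exceeds the dense eigendecomposition guard "
            f"({_DENSE_EIG_GUARD})"
        )
    eig = np.linalg.eigvals(W.dense())
    return {
        "eigenvalues": eig,
        "radius_theory": W.radius,
        "outlier_theory": W.J_eff,
    }


# --- Matrix Market + JSON sidecar I/O --------------------------------------

def save_connectivity(W: ConnectivityMatrix, path: Union[str, Path]) -> None:
    """Write weights as Matrix Market with a `.json` sidecar for the spec."""
    path = Path(path)
    mmwrite(str(path), sp.coo_matrix(W.weights))
    sidecar = {
        "spec": {
            "N": W.spec.N, "C_E": W.spec.C_E, "C_I": W.spec.C_I,
            "J": W.spec.J, "g": W.spec.g, "seed": W.spec.seed,
            "allow_self": W.spec.allow_self,
        },
        "e_mask": W.e_mask.astype(int).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar) + "\n")


def load_connectivity(path: Union[str, Path]) -> ConnectivityMatrix:
    path = Path(path)
    weights = sp.csr_matrix(mmread(str(path)))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = ConnectivitySpec(**sidecar["spec"])
    e_mask = np.asarray(sidecar["e_mask"], dtype=bool)
    return ConnectivityMatrix(weights=weights, e_mask=e_mask, spec=spec)
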