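"""Linear controllability metrics for symmetric weighted networks.

The network acts as the system matrix of the discrete-time linear
time-invariant dynamics x(t+1) = A x(t) + B u(t).  Before computing
control metrics, A is scaled by its largest eigenvalue so that the
fastest-evolving mode is consistent across networks (lambda_max = 1).

Metrics, all at a finite control horizon T (default 4):

* finite-time controllability Gramian W(T) = sum_{t<T} A^t B B' A^t;
  with the full control set B = I this is I + A^2 + A^4 + ...
* minimum control energy E_i = e_i' W(T)^{-1} e_i: the smallest input
  energy driving the state from zero to the one-hot activation of node i;
* average controllability a_i = Tr of the Gramian with B = e_i
  = sum_{t<T} (A^{2t})_{ii};
* modal controllability phi_i = sum_j (1 - lambda_j^2) v_ij^2: how well
  node i can steer the fast-decaying ("hard-to-reach") modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .generators import WeightedNetwork

_SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class ControlConfig:
    """Control horizon and control set used for Gramian-based metrics."""

    horizon: int = 4
    control_set: str = "full"  # "full" or "single_node"

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("control horizon T must be >= 1")
        if self.control_set not in ("full", "single_node"):
            raise ValueError(f"unknown control set: {self.control_set!r}")


def as_matrix(network) -> np.ndarray:
    """Accept a WeightedNetwork or array; return a validated symmetric array.

    Asymmetry below 1e-10 (max absolute elementwise) is symmetrized away;
    anything larger is an error.
    """
    if isinstance(network, WeightedNetwork):
        return network.weights
    a = np.asarray(network, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"matrix must be square, got shape {a.shape}")
    asym = np.abs(a - a.T).max() if a.size else 0.0
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance {_SYMMETRY_TOL}")
    return (a + a.T) / 2.0


def spectral_normalize(network) -> np.ndarray:
    """Scale A by its largest eigenvalue (Perron root) so lambda_max = 1."""
    a = as_matrix(network)
    if not np.any(a > 0):
        raise ValueError("cannot normalize an all-zero matrix")
    lam_max = scipy.linalg.eigvalsh(a, subset_by_index=(a.shape[0] - 1,) * 2)[0]
    if lam_max <= 0:
        raise ValueError("largest eigenvalue is not positive")
    return a / lam_max


def spectrum(network) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (sorted descending) and matching orthonormal eigenvectors."""
    a = as_matrix(network)
    lam, vec = scipy.linalg.eigh(a)
    return lam[::-1], vec[:, ::-1]


def controllability_gramian(
    network, horizon: int = 4, control_set: str = "full", node: int | None = None
) -> np.ndarray:
    """Finite-time controllability Gramian of the (normalized) system matrix.

    With the full control set the Gramian is the truncated power series
    I + A^2 + ... + A^{2(T-1)}.  With ``control_set="single_node"`` input
    enters only at ``node`` and W = sum_{t<T} (A^t e_i)(A^t e_i)'.
    """
    cfg = ControlConfig(horizon=horizon, control_set=control_set)
    a = as_matrix(network)
    n = a.shape[0]
    if cfg.control_set == "full":
        w = np.zeros((n, n))
        power = np.eye(n)  # A^{2t}
        for _ in range(cfg.horizon):
            w += power
            power = a @ power @ a
        return (w + w.T) / 2.0
    if node is None or not (0 <= node < n):
        raise ValueError("single_node control requires a valid node index")
    w = np.zeros((n, n))
    x = np.zeros(n)
    x[node] = 1.0
    for _ in range(cfg.horizon):
        w += np.outer(x, x)
        x = a @ x
    return (w + w.T) / 2.0


def min_control_energy(network, horizon: int = 4) -> np.ndarray:
    """Per-node minimum energy E_i = (W(T)^{-1})_{ii}, full control set.

    Computed by solving the symmetric positive-definite system W X = I with
    a Cholesky factorization rather than forming the inverse explicitly.
    """
    w = controllability_gramian(network, horizon=horizon, control_set="full")
    try:
        cho = scipy.linalg.cho_factor(w)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - W >= I is SPD
        raise ValueError("controllability Gramian is numerically singular") from exc
    inv = scipy.linalg.cho_solve(cho, np.eye(w.shape[0]))
    return np.diag(inv).copy()


def average_controllability(network, horizon: int = 4) -> np.ndarray:
    """Per-node average controllability a_i = sum_{t<T} (A^{2t})_{ii}."""
    ControlConfig(horizon=horizon)
    a = as_matrix(network)
    n = a.shape[0]
    out = np.zeros(n)
    power = np.eye(n)
    for _ in range(horizon):
        out += np.diag(power)
        power = a @ power @ a
    return out


def modal_controllability(network) -> np.ndarray:
    """Per-node modal controllability phi_i = sum_j (1 - lambda_j^2) v_ij^2.

    For repeated eigenvalues the formula depends on the eigenbasis returned
    by the symmetric solver; any orthonormal basis of the degenerate
    subspace yields the same phi because sum_j v_ij^2 is basis-invariant
    within an eigenspace.
    """
    lam, vec = spectrum(network)
    return (vec**2) @ (1.0 - lam**2)
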