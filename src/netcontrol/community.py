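"""Node- and network-level community structure and centrality statistics.

All functions accept either a :class:`~netcontrol.generators.WeightedNetwork`
or a plain symmetric array.  Partitions are integer label vectors; labels
may be any integers, one per node, with every community non-empty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg

from .control import as_matrix, spectral_normalize
from .generators import (
    KIND_ASSORTATIVE,
    KIND_CORE,
    WeightModel,
    fraction_to_block_spec,
    generate_ensemble,
)

_DEGENERATE_TOL = 1e-12


def _labels(network, partition) -> np.ndarray:
    if partition is None and hasattr(network, "partition"):
        partition = network.partition
    if partition is None:
        raise ValueError("a partition is required")
    labels = np.asarray(partition, dtype=int)
    n = as_matrix(network).shape[0]
    if labels.shape != (n,):
        raise ValueError("partition must assign one label to every node")
    return labels


def node_strength(network) -> np.ndarray:
    """Strength kappa_i = sum_j A_ij (row sums of the weight matrix)."""
    return as_matrix(network).sum(axis=1)


def within_community_strength(network, partition=None) -> pd.DataFrame:
    """kappa_iz: strength of node i restricted to community z (one column per z)."""
    a = as_matrix(network)
    labels = _labels(network, partition)
    comms = np.unique(labels)
    cols = {z: a[:, labels == z].sum(axis=1) for z in comms}
    return pd.DataFrame(cols)


def participation_coefficient(network, partition=None) -> np.ndarray:
    """PC_i = 1 - sum_z (kappa_iz / kappa_i)^2.

    0 when all of a node's strength stays inside its own module, approaching
    1 - 1/K when strength is spread evenly over the K modules.  Isolated
    nodes (kappa_i = 0) get PC_i = 0 by convention.
    """
    kappa_iz = within_community_strength(network, partition).to_numpy()
    kappa = kappa_iz.sum(axis=1)
    pc = np.zeros(len(kappa))
    ok = kappa > 0
    pc[ok] = 1.0 - np.sum((kappa_iz[ok] / kappa[ok, None]) ** 2, axis=1)
    return pc


def intramodule_zscore(network, partition=None) -> np.ndarray:
    """Within-module strength of each node, Z-scored inside its module.

    The standard deviation is the population s.d. (divide by module size).
    Modules whose members all have identical within-module strength give
    Z = 0 for those members.
    """
    a = as_matrix(network)
    labels = _labels(network, partition)
    z = np.zeros(a.shape[0])
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        kin = a[np.ix_(members, members)].sum(axis=1)
        sd = kin.std()  # population convention
        if sd > _DEGENERATE_TOL:
            z[members] = (kin - kin.mean()) / sd
    return z


def modularity_q(network, partition=None, weighted: bool = True) -> float:
    """Normalized Newman-Girvan modularity of a given partition.

    Q = (1/2m) sum_ij (A_ij - kappa_i kappa_j / 2m) delta(z_i, z_j) with
    2m the total weight.  For two balanced blocks Q runs from -0.5 (fully
    disassortative) through 0 (random, or pure core) to +0.5 (fully
    assortative).  ``weighted=False`` evaluates Q on the binarized matrix.
    """
    a = as_matrix(network)
    if not weighted:
        a = (a > 0).astype(float)
    labels = _labels(network, partition)
    two_m = a.sum()
    if two_m <= 0:
        raise ValueError("modularity is undefined for a network with zero total weight")
    kappa = a.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(np.sum((a - np.outer(kappa, kappa) / two_m)[same]) / two_m)


def weighted_subgraph_centrality(network, normalized: bool = False) -> np.ndarray:
    """WSC(i) = [expm(A)]_ii: factorial-discounted closed-walk strength.

    Equivalent to the spectral sum sum_j e^{lambda_j} v_ij^2 and to the
    series sum_k (A^k)_ii / k!.  Evaluated on the raw weighted matrix by
    default; ``normalized=True`` applies spectral normalization first.
    """
    a = as_matrix(network)
    if normalized:
        a = spectral_normalize(a)
    return np.diag(scipy.linalg.expm(a)).copy()


def analytic_q(kind: str, f: float) -> float:
    """Closed-form planted-partition Q for balanced blocks with uniform weights.

    Assortative continuum: Q = f - 1/2.  Core continuum: Q = f - 1/2 - f^2/2
    (f is the fraction of edges in the core block; the [2,2] block is empty).
    """
    if kind == KIND_ASSORTATIVE:
        return f - 0.5
    if kind == KIND_CORE:
        return f - 0.5 - f**2 / 2.0
    raise ValueError(f"unknown continuum kind: {kind!r}")


def q_vs_fraction_curve(
    kind: str,
    fraction_grid,
    n: int = 60,
    density: float = 0.1485,
    weight_model: WeightModel | None = None,
    ensemble_size: int = 10,
    seed=None,
) -> pd.DataFrame:
    """Empirical mean planted-partition Q vs edge fraction, with the analytic curve."""
    model = weight_model or WeightModel()
    rows = []
    for g, f in enumerate(fraction_grid):
        spec = fraction_to_block_spec(kind, f, n=n, density=density)
        nets = generate_ensemble(spec, model, ensemble_size, seed=seed, grid_index=g)
        qs = [modularity_q(net, net.partition) for net in nets]
        rows.append(
            {"fraction": f, "mean_q": float(np.mean(qs)), "analytic_q": analytic_q(kind, f)}
        )
    return pd.DataFrame(rows)
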