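"""Plain-text I/O: dense matrix TSV, partition TSV, per-node metric TSV.

Matrices are written as n header-less rows of n tab-separated floats at 17
significant digits, so write-then-read round-trips bit-identically.
Partition files are two columns (0-based node index, integer community
label).  All writers prepend provenance comment lines starting with '#'.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .generators import WeightedNetwork

_SYMMETRY_TOL = 1e-10


def config_hash(obj) -> str:
    """Short stable hash of a configuration's repr, for provenance headers."""
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


def _header_lines(seed=None, extra: dict | None = None) -> list[str]:
    lines = []
    if seed is not None:
        lines.append(f"seed={seed}")
    for k, v in (extra or {}).items():
        lines.append(f"{k}={v}")
    return lines


def write_network(network, path, seed=None, extra: dict | None = None) -> None:
    w = network.weights if isinstance(network, WeightedNetwork) else np.asarray(network)
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(seed, extra):
            fh.write(f"# {line}\n")
        np.savetxt(fh, w, fmt="%.17g", delimiter="\t")


def read_network(path) -> WeightedNetwork:
    """Read a dense matrix TSV; validates shape, symmetry, sign, and finiteness."""
    try:
        w = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"cannot parse matrix file {path}: {exc}") from exc
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, not square")
    if np.any(~np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ValueError(f"{path}: non-finite entry at ({i}, {j})")
    asym = np.abs(w - w.T)
    if asym.size and asym.max() > _SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path}: asymmetry {asym.max():.3g} at entry ({i}, {j}) exceeds "
            f"tolerance {_SYMMETRY_TOL}"
        )
    w = (w + w.T) / 2.0
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise ValueError(f"{path}: negative weight at ({i}, {j})")
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w)


def write_partition(labels, path, seed=None, extra: dict | None = None) -> None:
    labels = np.asarray(labels, dtype=int)
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(seed, extra):
            fh.write(f"# {line}\n")
        for i, z in enumerate(labels):
            fh.write(f"{i}\t{z}\n")


def read_partition(path) -> np.ndarray:
    data = np.loadtxt(path, delimiter="\t", comments="#", dtype=int, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: partition file must have two columns")
    order = np.argsort(data[:, 0])
    idx = data[order, 0]
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError(f"{path}: node indices must be 0..n-1 without gaps")
    return data[order, 1]


def write_metrics(table: pd.DataFrame, path, seed=None, extra: dict | None = None) -> None:
    """Write a per-node (or summary) metric table as TSV with a header row."""
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(seed, extra):
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
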