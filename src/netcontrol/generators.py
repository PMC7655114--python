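"""Block-structured weighted network generators.

Networks are built in two stages: a binary topology with exact per-block
edge counts on a 2 x 2 block structure (two planted communities), followed
by i.i.d. edge weights drawn from a configurable family.  Two structural
continuums are supported, parameterized by the fraction ``f`` of total
edges placed in the block(s) of interest:

``disassortative_to_assortative``
    fraction ``f`` of edges split equally between the two on-diagonal
    blocks, ``1 - f`` in the off-diagonal block.  ``f = 0`` is fully
    disassortative, ``f = 1`` fully assortative (modular).

``disassortative_to_core``
    fraction ``f`` in the [1,1] block (the core), ``1 - f`` in the
    off-diagonal block, and the [2,2] block empty.  ``f = 1`` is a pure
    core with an unconnected periphery.

Binary density is held fixed along a continuum (default 0.1485, the mean
density of the 234-region structural brain networks the defaults emulate)
so that only the mesoscale arrangement of edges changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

KIND_ASSORTATIVE = "disassortative_to_assortative"
KIND_CORE = "disassortative_to_core"
CONTINUUM_KINDS = (KIND_ASSORTATIVE, KIND_CORE)

#: default node count / binary density of the brain-scale simulations
DEFAULT_N = 234
DEFAULT_DENSITY = 0.1485

# block keys: (0, 0) and (1, 1) are the on-diagonal blocks of the two
# planted communities, (0, 1) the off-diagonal (between-community) block
_BLOCK_KEYS = ((0, 0), (1, 1), (0, 1))
_BLOCK_NAMES = {(0, 0): "[1,1]", (1, 1): "[2,2]", (0, 1): "[1,2]"}


def _block_capacity(block: tuple[int, int], sizes: tuple[int, int]) -> int:
    n1, n2 = sizes
    if block == (0, 0):
        return n1 * (n1 - 1) // 2
    if block == (1, 1):
        return n2 * (n2 - 1) // 2
    return n1 * n2


@dataclass(frozen=True)
class WeightedNetwork:
    """A symmetric non-negative weight matrix with an optional planted partition.

    Parameters
    ----------
    weights : (n, n) ndarray
        Symmetric, non-negative, zero diagonal.
    partition : (n,) ndarray of int, optional
        Planted community labels (1-based).
    """

    weights: np.ndarray
    partition: Optional[np.ndarray] = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix must be exactly symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")
        object.__setattr__(self, "weights", w)
        if self.partition is not None:
            p = np.asarray(self.partition, dtype=int)
            if p.shape != (w.shape[0],):
                raise ValueError("partition length must match node count")
            object.__setattr__(self, "partition", p)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


@dataclass(frozen=True)
class BlockTopologySpec:
    """Exact per-block binary edge counts for a 2 x 2 block topology."""

    n: int
    sizes: tuple[int, int]
    edge_counts: dict  # {(0,0): int, (1,1): int, (0,1): int}
    total_density: float

    def __post_init__(self):
        n1, n2 = self.sizes
        if n1 + n2 != self.n or n1 < 1 or n2 < 1:
            raise ValueError("community sizes must be positive and sum to n")
        counts = {k: int(self.edge_counts[k]) for k in _BLOCK_KEYS}
        for blk in _BLOCK_KEYS:
            cap = _block_capacity(blk, self.sizes)
            if counts[blk] < 0:
                raise ValueError(f"negative edge count for block {_BLOCK_NAMES[blk]}")
            if counts[blk] > cap:
                raise ValueError(
                    f"edge count {counts[blk]} exceeds capacity {cap} of "
                    f"block {_BLOCK_NAMES[blk]}"
                )
        total_pairs = self.n * (self.n - 1) // 2
        expected = int(round(self.total_density * total_pairs))
        if sum(counts.values()) != expected:
            raise ValueError(
                f"edge counts sum to {sum(counts.values())}, expected "
                f"{expected} = round(density * n(n-1)/2)"
            )
        object.__setattr__(self, "edge_counts", counts)

    @property
    def total_edges(self) -> int:
        return sum(self.edge_counts.values())


@dataclass(frozen=True)
class WeightModel:
    """Edge weight distribution.

    families
    --------
    ``normal``
        N(mu, sigma^2), non-positive draws redrawn so weights stay positive.
    ``geometric``
        integer weights k in {1, 2, ...} with P(k) = p^(k-1) (1-p); an edge
        that exists always carries weight >= 1.  If ``p`` is None it is set
        per block from the planted partition: the block's binary density
        (``p_mode="block_density"``) or the block's share of total edges
        (``p_mode="edge_fraction"``).
    ``lognormal``
        exp(N(log_mean, log_sigma^2)); used for fat-tailed surrogate
        networks emulating streamline-count weights.
    """

    family: str = "normal"
    mu: float = 0.5
    sigma: float = 0.12
    p: Optional[float] = None
    p_mode: str = "block_density"
    log_mean: float = 0.0
    log_sigma: float = 1.0

    def __post_init__(self):
        if self.family not in ("normal", "geometric", "lognormal"):
            raise ValueError(f"unknown weight family: {self.family!r}")
        if self.family == "normal" and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.p is not None and not (0 < self.p < 1):
            raise ValueError("geometric p must lie in (0, 1)")
        if self.p_mode not in ("block_density", "edge_fraction"):
            raise ValueError(f"unknown p_mode: {self.p_mode!r}")
        if self.family == "lognormal" and self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")


@dataclass(frozen=True)
class ContinuumSpec:
    """A sweep along one structural continuum."""

    kind: str
    fraction_grid: tuple
    n: int = DEFAULT_N
    density: float = DEFAULT_DENSITY
    weight_model: WeightModel = field(default_factory=WeightModel)
    ensemble_size: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CONTINUUM_KINDS:
            raise ValueError(f"unknown continuum kind: {self.kind!r}")
        grid = tuple(float(f) for f in self.fraction_grid)
        if any(not (0 <= f <= 1) for f in grid):
            raise ValueError("fraction grid values must lie in [0, 1]")
        if list(grid) != sorted(grid):
            raise ValueError("fraction grid must be sorted ascending")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        object.__setattr__(self, "fraction_grid", grid)


def fraction_to_block_spec(
    kind: str, f: float, n: int = DEFAULT_N, density: float = DEFAULT_DENSITY
) -> BlockTopologySpec:
    """Translate a continuum position ``f`` into exact per-block edge counts.

    Fractional targets are rounded by largest-remainder allocation so the
    total edge count round(density * n(n-1)/2) is preserved exactly; ties
    are broken toward the off-diagonal block, then block [1,1].
    """
    if kind not in CONTINUUM_KINDS:
        raise ValueError(f"unknown continuum kind: {kind!r}")
    if not (0 <= f <= 1):
        raise ValueError("fraction f must lie in [0, 1]")
    if n % 2:
        raise ValueError("n must be even (equal planted communities)")
    n1 = n2 = n // 2
    total_pairs = n * (n - 1) // 2
    m = int(round(density * total_pairs))

    if kind == KIND_ASSORTATIVE:
        targets = {(0, 0): f * m / 2.0, (1, 1): f * m / 2.0, (0, 1): (1 - f) * m}
    else:
        targets = {(0, 0): f * m, (1, 1): 0.0, (0, 1): (1 - f) * m}

    counts = {blk: int(np.floor(t)) for blk, t in targets.items()}
    leftover = m - sum(counts.values())
    # tie-break priority: off-diagonal first, then [1,1], then [2,2]
    priority = {(0, 1): 0, (0, 0): 1, (1, 1): 2}
    order = sorted(
        _BLOCK_KEYS, key=lambda blk: (-(targets[blk] - counts[blk]), priority[blk])
    )
    for blk in order[:leftover]:
        counts[blk] += 1

    for blk in _BLOCK_KEYS:
        cap = _block_capacity(blk, (n1, n2))
        if counts[blk] > cap:
            raise ValueError(
                f"fraction f={f} places {counts[blk]} edges in block "
                f"{_BLOCK_NAMES[blk]} but its capacity is only {cap}"
            )
    return BlockTopologySpec(n=n, sizes=(n1, n2), edge_counts=counts, total_density=density)


def _sample_block_pairs(
    block: tuple[int, int], count: int, sizes: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pick `count` distinct node pairs uniformly at random within a block."""
    n1, n2 = sizes
    cap = _block_capacity(block, sizes)
    idx = rng.choice(cap, size=count, replace=False)
    if block == (0, 1):
        return idx // n2, n1 + idx % n2
    offset = 0 if block == (0, 0) else n1
    size = n1 if block == (0, 0) else n2
    iu, ju = np.triu_indices(size, k=1)
    return offset + iu[idx], offset + ju[idx]


def sample_binary_topology(spec: BlockTopologySpec, seed=None) -> WeightedNetwork:
    """Realize a binary adjacency with exactly the spec's per-block edge counts."""
    rng = np.random.default_rng(seed)
    n1, n2 = spec.sizes
    adj = np.zeros((spec.n, spec.n))
    for blk in _BLOCK_KEYS:
        count = spec.edge_counts[blk]
        if count == 0:
            continue
        ii, jj = _sample_block_pairs(blk, count, spec.sizes, rng)
        adj[ii, jj] = 1.0
    adj = adj + adj.T
    labels = np.repeat([1, 2], [n1, n2])
    return WeightedNetwork(adj, labels)


def _geometric_block_probs(
    binary: np.ndarray, partition: np.ndarray, p_mode: str
) -> np.ndarray:
    """Per-block geometric success probabilities as a 2 x 2 table."""
    sizes = (int(np.sum(partition == 1)), int(np.sum(partition == 2)))
    upper = np.triu(binary, 1) > 0
    total_edges = int(upper.sum())
    probs = np.zeros((2, 2))
    for blk in _BLOCK_KEYS:
        mask_r = partition == blk[0] + 1
        mask_s = partition == blk[1] + 1
        edges = int(upper[np.ix_(mask_r, mask_s)].sum())
        if blk != (0, 1):
            edges = int(upper[np.ix_(mask_r, mask_r)].sum())
        if p_mode == "block_density":
            cap = _block_capacity(blk, sizes)
            p = edges / cap if cap else 0.0
        else:
            p = edges / total_edges if total_edges else 0.0
        if edges > 0 and not (0 < p < 1):
            raise ValueError(
                f"block {_BLOCK_NAMES[blk]} yields geometric p={p}; "
                "p must lie strictly in (0, 1)"
            )
        probs[blk[0], blk[1]] = probs[blk[1], blk[0]] = p
    return probs


def assign_weights(
    network, model: WeightModel, seed=None, partition: Optional[np.ndarray] = None
) -> WeightedNetwork:
    """Draw an independent weight for every existing edge.

    Zero entries stay zero and symmetry is preserved.  For the geometric
    family without an explicit ``model.p``, a planted 2-community partition
    is required to derive the per-block success probabilities.
    """
    if isinstance(network, WeightedNetwork):
        binary = network.weights
        if partition is None:
            partition = network.partition
    else:
        binary = np.asarray(network, dtype=float)
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(binary, 1))
    n_edges = len(iu)
    weights = np.zeros_like(binary, dtype=float)

    if model.family == "normal":
        w = rng.normal(model.mu, model.sigma, size=n_edges)
        bad = w <= 0
        while np.any(bad):  # redraw non-positive samples (prob ~1.5e-5 at defaults)
            w[bad] = rng.normal(model.mu, model.sigma, size=int(bad.sum()))
            bad = w <= 0
    elif model.family == "geometric":
        if model.p is not None:
            p_edge = np.full(n_edges, model.p)
        else:
            if partition is None:
                raise ValueError(
                    "geometric weights need either an explicit p or a planted "
                    "2-community partition to derive per-block p"
                )
            probs = _geometric_block_probs(binary, partition, model.p_mode)
            p_edge = probs[partition[iu] - 1, partition[ju] - 1]
        # success prob of the numpy geometric is 1 - p: P(k) = p^(k-1) (1-p)
        w = rng.geometric(1.0 - p_edge).astype(float) if n_edges else np.zeros(0)
    elif model.family == "lognormal":
        w = rng.lognormal(model.log_mean, model.log_sigma, size=n_edges)
    else:  # pragma: no cover - guarded by WeightModel validation
        raise ValueError(f"unknown weight family: {model.family!r}")

    weights[iu, ju] = w
    weights = weights + weights.T
    return WeightedNetwork(weights, partition)


def generate_ensemble(
    spec: BlockTopologySpec,
    model: WeightModel,
    m: int,
    seed=None,
    grid_index: int = 0,
) -> list[WeightedNetwork]:
    """Generate ``m`` independent networks for one continuum grid point.

    Per-network seeds are derived deterministically from the master seed and
    the (grid point, replicate) position, so identical inputs reproduce the
    ensemble exactly.
    """
    if m < 1:
        raise ValueError("ensemble size must be >= 1")
    master = np.random.SeedSequence(seed, spawn_key=(grid_index,))
    nets = []
    for child in master.spawn(m):
        rng = np.random.default_rng(child)
        binary = sample_binary_topology(spec, rng)
        nets.append(assign_weights(binary, model, rng))
    return nets


def surrogate_empirical_network(
    n: int = DEFAULT_N,
    density: float = DEFAULT_DENSITY,
    style: str = "qa_like",
    seed=None,
) -> WeightedNetwork:
    """A random-topology surrogate for an empirical structural brain network.

    ``qa_like`` carries normal(0.5, 0.12) weights (quantitative-anisotropy
    style, approximately symmetric distribution); ``streamline_like``
    carries log-normal(0, 1) weights (streamline-count style, fat-tailed).
    No planted partition is attached.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0 < density < 1):
        raise ValueError("density must lie strictly in (0, 1)")
    if style not in ("qa_like", "streamline_like"):
        raise ValueError(f"unknown surrogate style: {style!r}")
    rng = np.random.default_rng(seed)
    total_pairs = n * (n - 1) // 2
    m = int(round(density * total_pairs))
    if m < 1:
        raise ValueError("density too low: no edges at this network size")
    iu, ju = np.triu_indices(n, k=1)
    idx = rng.choice(total_pairs, size=m, replace=False)
    adj = np.zeros((n, n))
    adj[iu[idx], ju[idx]] = 1.0
    adj = adj + adj.T
    model = (
        WeightModel(family="normal", mu=0.5, sigma=0.12)
        if style == "qa_like"
        else WeightModel(family="lognormal", log_mean=0.0, log_sigma=1.0)
    )
    net = assign_weights(adj, model, rng)
    return WeightedNetwork(net.weights, None)


def surrogate_empirical_ensemble(
    n: int = DEFAULT_N,
    density: float = DEFAULT_DENSITY,
    style: str = "qa_like",
    n_networks: int = 24,
    seed=None,
    rewire_fraction: float = 0.1,
    weight_noise: float = 0.1,
) -> list[WeightedNetwork]:
    """Repeated noisy instantiations of one surrogate network.

    Emulates repeated structural scans of the same anatomy: a single
    template network is generated, then each instantiation rewires a small
    fraction of its edges to random empty pairs (with fresh weights) and
    jitters the surviving weights multiplicatively (log-normal noise with
    s.d. ``weight_noise`` on the log scale).  Node identity therefore
    persists across the ensemble, which is what makes region-level
    aggregation meaningful; fully independent draws would leave no
    persistent regional profile to aggregate.
    """
    if n_networks < 1:
        raise ValueError("need at least one instantiation")
    if not (0 <= rewire_fraction < 1):
        raise ValueError("rewire_fraction must lie in [0, 1)")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_networks + 1)
    template = surrogate_empirical_network(n, density, style, seed=children[0])
    iu, ju = np.triu_indices(n, k=1)
    base = template.weights[iu, ju]
    present = np.flatnonzero(base > 0)
    absent = np.flatnonzero(base == 0)
    n_rewire = int(round(rewire_fraction * len(present)))
    nets = []
    for child in children[1:]:
        rng = np.random.default_rng(child)
        w = base.copy()
        if n_rewire:
            drop = rng.choice(present, size=n_rewire, replace=False)
            add = rng.choice(absent, size=n_rewire, replace=False)
            if style == "qa_like":
                fresh = rng.normal(0.5, 0.12, size=n_rewire)
                while np.any(fresh <= 0):
                    bad = fresh <= 0
                    fresh[bad] = rng.normal(0.5, 0.12, size=int(bad.sum()))
            else:
                fresh = rng.lognormal(0.0, 1.0, size=n_rewire)
            w[drop] = 0.0
            w[add] = fresh
        keep = w > 0
        if weight_noise > 0:
            w[keep] *= rng.lognormal(0.0, weight_noise, size=int(keep.sum()))
        mat = np.zeros((n, n))
        mat[iu, ju] = w
        nets.append(WeightedNetwork(mat + mat.T, None))
    return nets
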