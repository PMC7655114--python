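"""Experiment orchestration: continuum sweeps and region-level analysis.

Two experiments mirror the study design the synthetic generators emulate:

* a *continuum sweep* generates ensembles of block-structured networks at
  each point of a fraction grid, computes network-level controllability
  (the mean over the per-node values), and summarizes each metric as a
  Z-scored curve against the ensemble-mean weighted modularity Q;
* a *region-level analysis* partitions each network with the WSBM, computes
  per-node community and controllability metrics, averages them across
  network instantiations (rows are "regions"), and reports plain and
  partial Spearman correlations (controlling node strength) between the
  structure metrics {PC, Z, WSC} and the control metrics {E, a, phi}.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .community import (
    intramodule_zscore,
    modularity_q,
    node_strength,
    participation_coefficient,
    weighted_subgraph_centrality,
)
from .control import (
    average_controllability,
    min_control_energy,
    modal_controllability,
    spectral_normalize,
)
from .generators import (
    ContinuumSpec,
    WeightedNetwork,
    fraction_to_block_spec,
    generate_ensemble,
)
from .stats import aggregate_regions, partial_spearman, spearman, zscore_series
from .wsbm import WeightedSBM, central_partition, select_k

logger = logging.getLogger("netcontrol")

CONTROL_METRICS = ("energy", "avg_ctrl", "modal_ctrl")
STRUCTURE_METRICS = ("participation", "within_module_z", "wsc")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a continuum sweep experiment."""

    continuum: ContinuumSpec
    horizon: int = 4
    normalize: bool = True
    node_aggregate: str = "mean"  # or "median"
    out_dir: str | None = None
    plot: bool = False

    def __post_init__(self):
        if self.node_aggregate not in ("mean", "median"):
            raise ValueError("node_aggregate must be 'mean' or 'median'")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


def compute_node_metrics(
    network,
    partition=None,
    horizon: int = 4,
    normalize: bool = True,
    wsc_normalized: bool = False,
) -> pd.DataFrame:
    """Per-node metric table: strength, E_i, a_i, phi_i, WSC, and (with a
    partition) participation coefficient and intramodule strength Z-score.

    Control metrics are computed on the spectrally normalized matrix;
    strength and WSC on the raw weighted matrix (``wsc_normalized=True``
    switches WSC to the normalized matrix as well).
    """
    if isinstance(network, WeightedNetwork) and partition is None:
        partition = network.partition
    a_norm = spectral_normalize(network) if normalize else network
    table = pd.DataFrame(
        {
            "strength": node_strength(network),
            "energy": min_control_energy(a_norm, horizon=horizon),
            "avg_ctrl": average_controllability(a_norm, horizon=horizon),
            "modal_ctrl": modal_controllability(a_norm),
            "wsc": weighted_subgraph_centrality(network, normalized=wsc_normalized),
        }
    )
    if partition is not None:
        table["participation"] = participation_coefficient(network, partition)
        table["within_module_z"] = intramodule_zscore(network, partition)
    return table


def run_continuum_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Sweep a structural continuum; return (and optionally write) the summary.

    One row per grid point: fraction, ensemble-mean weighted Q, and for each
    controllability metric the ensemble mean, s.d., and across-grid Z-score
    of the mean.
    """
    spec = config.continuum
    agg = np.mean if config.node_aggregate == "mean" else np.median
    rows = []
    for g, f in enumerate(spec.fraction_grid):
        t0 = time.perf_counter()
        block = fraction_to_block_spec(spec.kind, f, n=spec.n, density=spec.density)
        nets = generate_ensemble(
            block, spec.weight_model, spec.ensemble_size, seed=spec.seed, grid_index=g
        )
        per_net = {m: [] for m in CONTROL_METRICS}
        qs = []
        for net in nets:
            qs.append(modularity_q(net, net.partition))
            a_norm = spectral_normalize(net) if config.normalize else net.weights
            per_net["energy"].append(agg(min_control_energy(a_norm, config.horizon)))
            per_net["avg_ctrl"].append(
                agg(average_controllability(a_norm, config.horizon))
            )
            per_net["modal_ctrl"].append(agg(modal_controllability(a_norm)))
        row = {"fraction": f, "mean_q": float(np.mean(qs))}
        for m in CONTROL_METRICS:
            row[f"{m}_mean"] = float(np.mean(per_net[m]))
            row[f"{m}_sd"] = float(np.std(per_net[m], ddof=1)) if len(nets) > 1 else 0.0
        rows.append(row)
        logger.info(
            "grid point %d/%d f=%.3f Q=%.4f (%.2fs, seed=%s)",
            g + 1, len(spec.fraction_grid), f, row["mean_q"],
            time.perf_counter() - t0, spec.seed,
        )
    summary = pd.DataFrame(rows)
    for m in CONTROL_METRICS:
        col = summary[f"{m}_mean"]
        summary[f"{m}_z"] = zscore_series(col) if col.nunique() > 1 else 0.0
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        name = f"sweep_{spec.kind}_{spec.weight_model.family}"
        # hash only the scientific parameters, not output paths
        chash = nio.config_hash(
            (spec, config.horizon, config.normalize, config.node_aggregate)
        )
        nio.write_metrics(summary, out / f"{name}.tsv", seed=spec.seed,
                          extra={"config": chash})
        if config.plot:
            _plot_sweep(summary, out / f"{name}.png")
    return summary


def _plot_sweep(summary: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.4), sharex=True)
    for ax, m in zip(axes, CONTROL_METRICS):
        mean = summary[f"{m}_mean"]
        sd = summary[f"{m}_sd"]
        scale = mean.std(ddof=1) or 1.0
        ax.errorbar(summary["mean_q"], summary[f"{m}_z"], yerr=sd / scale, fmt="o", ms=3)
        ax.set_xlabel("mean weighted Q")
        ax.set_ylabel(f"Z-scored mean {m}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _network_partition(
    a, n_communities, k_grid, weight_family, alpha, n_restarts, seed
) -> np.ndarray:
    """WSBM partition of one network: VI-central across restart partitions."""
    if k_grid is not None:
        k, _ = select_k(
            a, k_grid, seed=seed, weight_family=weight_family, alpha=alpha,
            n_restarts=max(1, n_restarts // 2),
        )
    else:
        k = n_communities
    parts = []
    ss = np.random.SeedSequence(seed, spawn_key=(1,))
    for child in ss.spawn(n_restarts):
        est = WeightedSBM(
            n_communities=k, weight_family=weight_family, alpha=alpha,
            n_restarts=1, random_state=child.generate_state(1)[0],
        ).fit(a)
        parts.append(est.labels_)
    return central_partition(parts)


def run_region_analysis(
    networks,
    n_communities: int = 2,
    k_grid=None,
    weight_family: str = "normal",
    alpha: float = 0.5,
    n_restarts: int = 10,
    horizon: int = 4,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-level correlation analysis across network instantiations.

    Each network is partitioned with the WSBM (fixed K, or K selected over
    ``k_grid``), per-node metrics are computed and averaged across networks,
    and every {structure metric} x {control metric} pair is correlated with
    both plain Spearman and partial Spearman controlling node strength.

    Returns ``(correlations, region_table)``; a failed network is skipped
    with a warning and the usable count is recorded.
    """
    networks = list(networks)
    if not networks:
        raise ValueError("need at least one network")
    ss = np.random.SeedSequence(seed)
    tables = []
    failures = 0
    for idx, (net, child) in enumerate(zip(networks, ss.spawn(len(networks)))):
        t0 = time.perf_counter()
        try:
            labels = _network_partition(
                net, n_communities, k_grid, weight_family, alpha, n_restarts,
                child.generate_state(1)[0],
            )
            tables.append(
                compute_node_metrics(net, partition=labels, horizon=horizon)
            )
            logger.info(
                "network %d/%d done (%.2fs)", idx + 1, len(networks),
                time.perf_counter() - t0,
            )
        except Exception as exc:  # noqa: BLE001 - per-network isolation
            failures += 1
            logger.warning("network %d failed and was skipped: %s", idx + 1, exc)
    if not tables:
        raise ValueError("all networks failed")
    region = aggregate_regions(tables)
    strength = region["strength"].to_numpy()
    rows = []
    for sm in STRUCTURE_METRICS:
        for cm in CONTROL_METRICS:
            x = region[sm].to_numpy()
            y = region[cm].to_numpy()
            plain = spearman(x, y)
            part = partial_spearman(x, y, strength, covariate_name="strength")
            for res in (plain, part):
                rows.append(
                    {
                        "structure_metric": sm,
                        "control_metric": cm,
                        "method": res.method,
                        "rho": res.rho,
                        "p_value": res.p_value,
                        "n": res.n,
                        "degenerate": res.degenerate,
                    }
                )
    report = pd.DataFrame(rows)
    report.attrs["n_networks_used"] = len(tables)
    report.attrs["n_networks_failed"] = failures
    return report, region
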