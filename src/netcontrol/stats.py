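"""Region-level aggregation and rank-correlation machinery.

Partial Spearman correlation is the Pearson partial correlation computed on
midranks (average ranks for ties), with the p-value from the large-sample t
approximation on n - 3 degrees of freedom.  This is the standard definition
used by common statistics toolkits, and the one assumed when "correcting
for node strength" in the region-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats


@dataclass(frozen=True)
class CorrelationResult:
    """A (partial) rank correlation: coefficient, p-value, and bookkeeping."""

    method: str
    rho: float
    p_value: float
    n: int
    covariates: tuple = ()
    degenerate: bool = False


def aggregate_regions(tables) -> pd.DataFrame:
    """Mean of each per-node metric across network instantiations.

    All tables must share node count and columns.  The number of
    instantiations is recorded in ``result.attrs["n_instantiations"]``.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one metric table")
    first = tables[0]
    for t in tables[1:]:
        if t.shape != first.shape or list(t.columns) != list(first.columns):
            raise ValueError("metric tables must share shape and columns")
    mean = sum(t.to_numpy() for t in tables) / len(tables)
    out = pd.DataFrame(mean, index=first.index, columns=first.columns)
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError("aggregated means must be finite")
    out.attrs["n_instantiations"] = len(tables)
    return out


def _check_lengths(*vectors, minimum: int):
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs) or n < minimum:
        raise ValueError(f"inputs must have equal length >= {minimum}")
    return arrs


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Constant input makes rho undefined; the result is returned with
    rho = nan and the degenerate flag set rather than raising.
    """
    x, y = _check_lengths(x, y, minimum=3)
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult("spearman", np.nan, np.nan, n, degenerate=True)
    rho, p = scipy.stats.spearmanr(x, y)
    return CorrelationResult("spearman", float(rho), float(p), n)


def partial_spearman(x, y, z, covariate_name: str = "z") -> CorrelationResult:
    """Spearman correlation of x and y after partialling out covariate z.

    Rank-transforms all three vectors, then applies the standard partial
    Pearson formula r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)).
    A degenerate covariate (constant after ranking) falls back to the plain
    Spearman correlation with the degenerate flag set.
    """
    x, y, z = _check_lengths(x, y, z, minimum=4)
    n = len(x)
    rz = scipy.stats.rankdata(z)
    if np.ptp(rz) == 0:
        plain = spearman(x, y)
        return CorrelationResult(
            "partial_spearman", plain.rho, plain.p_value, n,
            covariates=(covariate_name,), degenerate=True,
        )
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(
            "partial_spearman", np.nan, np.nan, n,
            covariates=(covariate_name,), degenerate=True,
        )
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        return CorrelationResult(
            "partial_spearman", np.nan, np.nan, n,
            covariates=(covariate_name,), degenerate=True,
        )
    rho = float(np.clip((r_xy - r_xz * r_yz) / denom, -1.0, 1.0))
    df = n - 3
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return CorrelationResult("partial_spearman", rho, p, n, covariates=(covariate_name,))


def zscore_series(values) -> np.ndarray:
    """(v - mean) / s.d. with the sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot Z-score a constant series")
    return (v - v.mean()) / sd


def smooth3(values) -> np.ndarray:
    """3-point moving average with truncated windows at the ends."""
    v = np.asarray(values, dtype=float)
    return np.array([v[max(0, i - 1): i + 2].mean() for i in range(len(v))])


def locate_extremum(summary, metric: str, mode: str = "min") -> float:
    """Q value at which an ensemble-mean metric attains its extremum.

    The mean curve is smoothed with a 3-point moving average before taking
    the arg-extremum, which makes the readout deterministic in the presence
    of ensemble noise.  Ties return the midpoint of the tied Q values.

    ``summary`` is a sweep summary frame with columns ``mean_q`` and
    ``{metric}_mean`` (or plain arrays via :func:`locate_extremum_arrays`).
    """
    return locate_extremum_arrays(
        summary["mean_q"].to_numpy(), summary[f"{metric}_mean"].to_numpy(), mode
    )


def locate_extremum_arrays(q, values, mode: str = "min") -> float:
    q = np.asarray(q, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(q) != len(v) or len(q) < 5:
        raise ValueError("need matching arrays with at least 5 grid points")
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    sm = smooth3(v)
    ext = sm.min() if mode == "min" else sm.max()
    tied = q[np.isclose(sm, ext, rtol=0.0, atol=1e-12)]
    return float((tied.min() + tied.max()) / 2.0)
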