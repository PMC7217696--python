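"""Relating criticality to network function across the E/I phase space.

Networks are binned by their DFA exponent (bins of 0.02 over 0.5-0.9); the
association between criticality and a function metric (dynamic range,
Reg_amp, Reg_phase) is the Spearman correlation between the per-bin mean
DFA and the per-bin mean metric. When the metric is resolved over
post-stimulus latencies, multiple comparisons are corrected with a
cluster-based permutation test: clusters are maximal runs of latencies with
p <= alpha, a cluster's size is the summed |rho| over its run, and the
significance threshold is the (1-alpha) percentile of the maximum cluster
size under latency-wise independent permutation of the metric values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.stats import rankdata
from scipy.stats import t as t_dist

__all__ = [
    "PhaseSpaceMap",
    "ClusterTestResult",
    "bin_by_dfa",
    "dfa_function_correlation",
    "cluster_permutation",
    "spearman_rho_p",
]

DFA_BIN_RANGE = (0.5, 0.9)
DFA_BIN_WIDTH = 0.02
DEFAULT_ALPHA = 0.001
DEFAULT_N_PERM = 10000


@dataclass
class PhaseSpaceMap:
    """Per-(CE, CI) cell means of the criticality and function metrics over
    replicate networks; backed by a tidy DataFrame."""

    table: "object"  # pandas.DataFrame with columns CE, CI, metric, mean, n

    def cell(self, ce: float, ci: float, metric: str) -> float:
        t = self.table
        row = t[(t.CE == ce) & (t.CI == ci) & (t.metric == metric)]
        if len(row) == 0:
            raise KeyError(f"no cell ({ce}, {ci}, {metric})")
        return float(row["mean"].iloc[0])


@dataclass
class ClusterTestResult:
    rho: np.ndarray                  # per-latency Spearman rho
    p: np.ndarray                    # per-latency p-values
    latencies: np.ndarray
    clusters: list[tuple[int, int]]  # significant [start, end) latency index runs
    cluster_sizes: np.ndarray        # summed |rho| of the significant clusters
    threshold: float                 # permutation threshold on max cluster size
    alpha: float
    n_perm: int
    all_clusters: list[tuple[int, int]] = field(default_factory=list)


def bin_by_dfa(
    function_values,
    dfa_values,
    bin_range: tuple[float, float] = DFA_BIN_RANGE,
    bin_width: float = DFA_BIN_WIDTH,
):
    """Bin per-network function values by the networks' DFA exponents.

    Returns (bin_mean_dfa, bin_mean_function, bin_count) over occupied bins.
    Bins are [lo, lo+width) half-open; values outside ``bin_range`` are
    ignored.
    """
    f = np.asarray(function_values, float)
    d = np.asarray(dfa_values, float)
    if f.shape != d.shape:
        raise ValueError("function and DFA arrays must match")
    if not np.all(np.isfinite(d)):
        raise ValueError("DFA values must be finite")
    lo, hi = bin_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.floor((d - lo) / bin_width).astype(int)
    inside = (d >= lo) & (d < hi)
    if not inside.any():
        raise ValueError("all DFA values outside the binning range")
    mean_d, mean_f, count = [], [], []
    for b in range(len(edges) - 1):
        sel = inside & (idx == b)
        if sel.any():
            mean_d.append(d[sel].mean())
            mean_f.append(f[sel].mean())
            count.append(int(sel.sum()))
    return np.asarray(mean_d), np.asarray(mean_f), np.asarray(count)


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p by the large-sample t approximation."""
    n = len(x)
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    if n < 3 or abs(rho) == 1.0:
        return rho, 0.0 if abs(rho) == 1.0 else 1.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return rho, p


def dfa_function_correlation(binned) -> float:
    """Spearman rho between bin-mean DFA and bin-mean function value.

    ``binned`` is the (mean_dfa, mean_function, count) triple from
    :func:`bin_by_dfa` (count optional).
    """
    mean_d, mean_f = np.asarray(binned[0], float), np.asarray(binned[1], float)
    if len(mean_d) < 3:
        raise ValueError("need at least 3 occupied DFA bins")
    rho, _ = spearman_rho_p(mean_d, mean_f)
    return rho


def _find_clusters(p: np.ndarray, rho: np.ndarray, alpha: float):
    """Maximal runs of p <= alpha with their summed |rho| sizes."""
    sig = p <= alpha
    clusters, sizes = [], []
    i = 0
    n = len(p)
    while i < n:
        if sig[i]:
            j = i
            while j < n and sig[j]:
                j += 1
            clusters.append((i, j))
            sizes.append(float(np.abs(rho[i:j]).sum()))
            i = j
        else:
            i += 1
    return clusters, np.asarray(sizes)


def cluster_permutation(
    dfa_bin_means: np.ndarray,
    function_by_latency: np.ndarray,
    latencies: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-based permutation test of the DFA-function association over
    post-stimulus latencies.

    Parameters
    ----------
    dfa_bin_means : (n_bins,) bin-mean DFA values (ordering held fixed).
    function_by_latency : (n_latencies, n_bins) bin-mean function values.
    alpha : per-latency significance level, also the cluster-level level.
    n_perm : permutations; the metric values are shuffled across bins
        independently at each latency.

    A cluster's size is the sum of |rho| over its run of consecutive
    significant latencies; observed clusters whose size exceeds the
    (1-alpha) percentile of the permutation max-cluster-size distribution
    are reported significant.
    """
    d = np.asarray(dfa_bin_means, float)
    F = np.atleast_2d(np.asarray(function_by_latency, float))
    n_lat, n_bins = F.shape
    if len(d) != n_bins:
        raise ValueError("bin count mismatch between DFA and function data")
    if latencies is None:
        latencies = np.arange(n_lat)
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable cluster threshold",
                      stacklevel=2)

    rng = np.random.default_rng(seed)
    rx = rankdata(d)
    rx = rx - rx.mean()
    sx = np.sqrt((rx**2).sum())

    def rho_p_rows(Y: np.ndarray):
        """Vectorized Spearman rho/p of rx against each row of Y."""
        ry = rankdata(Y, axis=1)
        ry = ry - ry.mean(axis=1, keepdims=True)
        sy = np.sqrt((ry**2).sum(axis=1))
        denom = sx * sy
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, ry @ rx / np.where(denom == 0, 1, denom), 0.0)
        rho = np.clip(rho, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n_bins - 2) / (1.0 - rho**2))
        p = np.where(
            np.abs(rho) == 1.0, 0.0,
            2.0 * t_dist.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), n_bins - 2),
        )
        return rho, p

    obs_rho, obs_p = rho_p_rows(F)

    # permutation null: shuffle metric values across bins, per latency
    max_sizes = np.empty(n_perm)
    for b in range(n_perm):
        perm = F.copy()
        for row in perm:
            rng.shuffle(row)
        prho, pp = rho_p_rows(perm)
        _, sizes = _find_clusters(pp, prho, alpha)
        max_sizes[b] = sizes.max() if len(sizes) else 0.0
    threshold = float(np.percentile(max_sizes, (1.0 - alpha) * 100.0))

    all_clusters, all_sizes = _find_clusters(obs_p, obs_rho, alpha)
    keep = [k for k, s in enumerate(all_sizes) if s > threshold]
    return ClusterTestResult(
        rho=obs_rho,
        p=obs_p,
        latencies=np.asarray(latencies),
        clusters=[all_clusters[k] for k in keep],
        cluster_sizes=np.asarray([all_sizes[k] for k in keep]),
        threshold=threshold,
        alpha=alpha,
        n_perm=n_perm,
        all_clusters=all_clusters,
    )
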