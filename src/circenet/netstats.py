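"""Degree-distribution diagnostics for the scale-free property.

Biological interaction networks typically show heavy-tailed degree
distributions P(k) ~ k^-alpha. Two complementary summaries are computed:
the continuous maximum-likelihood exponent

    alpha = 1 + n / sum(ln(x_i / xmin))    over degrees x_i >= xmin

and an ordinary least-squares fit of log(count) on log(degree) over the
nonzero histogram bins, whose R^2 quantifies how straight the log-log
distribution is. Neither is a formal goodness-of-fit test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from circenet.network import TripartiteNetwork


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    xmin: float
    n_tail: int
    loglog_slope: float
    loglog_r2: float


def degree_distribution(network: TripartiteNetwork) -> dict[int, int]:
    """Map degree -> node count over all three node classes pooled."""
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    deg: Counter[str] = Counter()
    for mir, target, _cls in network.edges:
        deg[mir] += 1
        deg[target] += 1
    for node in network.all_nodes():
        deg.setdefault(node, 0)
    return dict(sorted(Counter(deg.values()).items()))


def fit_power_law(degrees, xmin: float = 1.0) -> PowerLawFit:
    """Fit P(k) ~ k^-alpha to the degrees at and above ``xmin``."""
    x = np.asarray(degrees, dtype=float)
    tail = x[x >= xmin]
    if tail.size < 2:
        raise ValueError(f"need >= 2 degrees >= xmin={xmin}, got {tail.size}")
    log_ratio = np.log(tail / xmin)
    denom = float(log_ratio.sum())
    if denom == 0.0:
        raise ValueError("all degrees equal xmin; exponent undefined")
    alpha = 1.0 + tail.size / denom

    counts = Counter(tail.tolist())
    ks = np.array(sorted(counts))
    ns = np.array([counts[k] for k in ks], dtype=float)
    if ks.size >= 2:
        fit = sps.linregress(np.log(ks), np.log(ns))
        slope, r2 = float(fit.slope), float(fit.rvalue**2)
    else:
        slope, r2 = float("nan"), float("nan")
    return PowerLawFit(
        alpha=float(alpha),
        xmin=float(xmin),
        n_tail=int(tail.size),
        loglog_slope=slope,
        loglog_r2=r2,
    )


def network_degrees(network: TripartiteNetwork) -> np.ndarray:
    """Per-node degrees (unordered) for downstream fitting."""
    dist = degree_distribution(network)
    return np.repeat(
        np.fromiter(dist.keys(), dtype=int), np.fromiter(dist.values(), dtype=int)
    )


def plot_degree_distribution(dist: dict[int, int], path) -> None:
    """Log-log scatter of the degree histogram (diagnostic figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = [k for k in sorted(dist) if k > 0 and dist[k] > 0]
    ns = [dist[k] for k in ks]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.loglog(ks, ns, "o", ms=4)
    ax.set_xlabel("degree k")
    ax.set_ylabel("number of nodes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
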