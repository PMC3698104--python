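"""Convergence diagnostics: Brooks-Gelman PSRF and trace summaries.

The potential scale reduction factor (PSRF) follows Gelman-Rubin with the
Brooks-Gelman sampling-variability correction: the pooled-vs-within
variance ratio is multiplied by (d+3)/(d+1), where d is a method-of-moments
estimate of the degrees of freedom of the variance estimate.  Values near
1 indicate that the parallel chains have mixed into the same distribution.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

__all__ = ["psrf", "gelman_rubin", "trace_summary", "lag1_autocorrelation"]


def psrf(chains: np.ndarray) -> float:
    """Brooks-Gelman corrected PSRF for one parameter.

    ``chains`` has shape (m, n): m >= 2 chains of n >= 10 draws.  Raises on
    zero within-chain variance (constant chains), where the statistic is
    undefined.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("PSRF requires at least 2 chains")
    if n < 10:
        raise ValueError("PSRF requires at least 10 draws per chain")

    means = x.mean(axis=1)
    vars_ = x.var(axis=1, ddof=1)
    W = float(vars_.mean())
    if W <= 0.0:
        raise ValueError("zero within-chain variance: PSRF undefined")
    B_over_n = float(means.var(ddof=1))
    B = n * B_over_n
    sigma2 = (n - 1) / n * W + B_over_n
    V = sigma2 + B_over_n / m

    # sampling variance of V (Brooks & Gelman 1998)
    var_si2 = float(vars_.var(ddof=1)) if m > 1 else 0.0
    xbar = float(means.mean())
    cov_s_m2 = float(np.cov(vars_, means**2, ddof=1)[0, 1])
    cov_s_m = float(np.cov(vars_, means, ddof=1)[0, 1])
    var_V = (
        ((n - 1) / n) ** 2 / m * var_si2
        + ((m + 1) / (m * n)) ** 2 * 2.0 / (m - 1) * B * B
        + 2.0 * (m + 1) * (n - 1) / (m * n * n) * (n / m) * (cov_s_m2 - 2.0 * xbar * cov_s_m)
    )
    if var_V <= 0 or V <= 0:
        d = math.inf
    else:
        d = 2.0 * V * V / var_V
    correction = (d + 3.0) / (d + 1.0) if math.isfinite(d) else 1.0
    return math.sqrt(correction * V / W)


def _scalar_series(draws: PosteriorDraws) -> Iterator[tuple[str, np.ndarray]]:
    """Yield (name, (chains, draws) array) for every scalar component."""
    for name, v in draws.values.items():
        if v.ndim == 2:
            yield name, v
        else:
            labs = draws.labels.get(name) or [str(k) for k in range(v.shape[2])]
            for k in range(v.shape[2]):
                yield f"{name}[{labs[k]}]", v[:, :, k]


def _select(draws: PosteriorDraws, param_selector) -> list[tuple[str, np.ndarray]]:
    if param_selector is None:
        pred: Callable[[str], bool] = lambda s: True
    elif callable(param_selector):
        pred = param_selector
    elif isinstance(param_selector, str):
        pred = lambda s: s == param_selector or s.startswith(param_selector + "[")
    else:
        wanted = set(param_selector)
        pred = lambda s: s in wanted or s.split("[")[0] in wanted
    return [(nm, arr) for nm, arr in _scalar_series(draws) if pred(nm)]


def gelman_rubin(draws: PosteriorDraws, param_selector=None) -> dict[str, float]:
    """Brooks-Gelman PSRF per selected parameter.

    ``param_selector`` may be None (everything), a block/parameter name, a
    collection of names, or a predicate on the scalar parameter name.
    Constant (zero-variance) series are reported as NaN rather than raising,
    so a single degenerate coordinate does not mask the rest.
    """
    if draws.chains < 2:
        raise ValueError("PSRF requires at least 2 chains")
    out: dict[str, float] = {}
    for name, arr in _select(draws, param_selector):
        try:
            out[name] = psrf(arr)
        except ValueError:
            out[name] = float("nan")
    return out


def lag1_autocorrelation(series: np.ndarray) -> float:
    """Lag-1 autocorrelation; NaN for a constant series."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0.0:
        return float("nan")
    return float(np.dot(x[:-1], x[1:]) / denom)


def trace_summary(
    draws: PosteriorDraws, param_selector=None, n_segments: int = 4
) -> pd.DataFrame:
    """Deterministic per-parameter trace statistics.

    For each scalar parameter: overall mean and SD, per-chain means over
    ``n_segments`` equal segments (drift check, the numerical content of a
    trace plot), mean lag-1 autocorrelation across chains, and a
    ``degenerate`` flag for constant series.
    """
    rows = []
    for name, arr in _select(draws, param_selector):
        m, n = arr.shape
        seg = np.array_split(np.arange(n), n_segments)
        seg_means = np.array([[arr[c, s].mean() for s in seg] for c in range(m)])
        ac = [lag1_autocorrelation(arr[c]) for c in range(m)]
        ac = [a for a in ac if not math.isnan(a)]
        degenerate = len(ac) == 0
        row = {
            "parameter": name,
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
            "lag1_autocorr": float(np.mean(ac)) if ac else float("nan"),
            "degenerate": degenerate,
        }
        for s in range(n_segments):
            row[f"segment_mean_{s + 1}"] = float(seg_means[:, s].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def plot_traces(draws: PosteriorDraws, param_selector=None, max_params: int = 12):
    """Optional matplotlib trace plot; returns the figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    selected = _select(draws, param_selector)[:max_params]
    fig, axes = plt.subplots(len(selected), 1, figsize=(8, 2 * max(len(selected), 1)), squeeze=False)
    for ax, (name, arr) in zip(axes[:, 0], selected):
        for c in range(arr.shape[0]):
            ax.plot(arr[c], lw=0.5)
        ax.set_ylabel(name, fontsize=8)
    fig.tight_layout()
    return fig
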