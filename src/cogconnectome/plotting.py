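"""Simple diagnostic plots: difference-vs-density curves with permutation
null bands, and canonical-function group means."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .design import group_label
from .permutation import PermutationComparison
from .stats import ManovaResult


def plot_difference_curves(comparison: PermutationComparison, path: str | Path) -> None:
    """Observed group difference per density; shaded 2.5–97.5% null band
    when permutation quantiles were kept."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if comparison.is_scalar:
        raise ValueError("difference curve requires a density-resolved measure")
    dens = np.array(list(comparison.observed_diff.keys()))
    diff = np.array(list(comparison.observed_diff.values()))
    fig, ax = plt.subplots(figsize=(6, 4))
    if comparison.null_quantiles:
        lo = np.array([comparison.null_quantiles[d][0] for d in dens])
        hi = np.array([comparison.null_quantiles[d][1] for d in dens])
        ax.fill_between(dens * 100, lo, hi, alpha=0.25, color="grey",
                        label="permutation 2.5-97.5%")
    sig = np.array([comparison.p_values[d] < comparison.alpha for d in dens])
    ax.plot(dens * 100, diff, "-", color="steelblue")
    ax.plot(dens[sig] * 100, diff[sig], "o", color="crimson", label="p < alpha")
    ax.plot(dens[~sig] * 100, diff[~sig], "o", color="steelblue", mfc="white")
    a, b = (group_label(g) for g in comparison.group_pair)
    ax.set_xlabel("network density (%)")
    ax.set_ylabel(f"{comparison.measure_name} difference ({a} - {b})")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_canonical_means(result: ManovaResult, path: str | Path) -> None:
    """Bar plot of per-group means on the first canonical function."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.canonical_group_means is None:
        raise ValueError("result carries no canonical structure")
    means = result.canonical_group_means["canonical_1"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(means)), means.to_numpy(), color="steelblue")
    ax.set_xticks(range(len(means)))
    ax.set_xticklabels(means.index, rotation=45, ha="right")
    ax.set_ylabel("canonical function 1 (higher = better performance)")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
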