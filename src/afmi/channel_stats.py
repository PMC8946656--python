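"""Per-channel nonparametric group comparisons.

Relative intensities (rss) of each spectral channel are compared between
tissue classes with the two-tailed Mann-Whitney U test.  Significance is
annotated with stars: * p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu

__all__ = [
    "ChannelComparison",
    "ChannelStatsError",
    "mann_whitney_u",
    "stars_for_p",
    "compare_channel_groups",
    "compare_channels",
]

DEFAULT_PAIRS = (("normal", "PTG"), ("normal", "OSSN"), ("PTG", "OSSN"))


class ChannelStatsError(ValueError):
    """Invalid comparison input."""


@dataclass
class ChannelComparison:
    channel_index: int
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    stars: str
    method: str
    degenerate: bool = False


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], exact_threshold: int = 8
) -> tuple[float, float, str]:
    """Two-tailed Mann-Whitney U of sample ``a`` vs ``b``.

    Uses exact null enumeration when min(n_a, n_b) <= ``exact_threshold``
    and the pooled sample is tie-free; otherwise the normal approximation
    with tie and continuity corrections.  Returns (U_a, p, method).
    Constant pooled data yields p = 1.0 with method "degenerate".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ChannelStatsError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return a.size * b.size / 2.0, 1.0, "degenerate"
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= exact_threshold and not has_ties:
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "asymptotic"


def _group_values(
    rss_df: pd.DataFrame,
    channel_index: int,
    cls: str,
    mode: str,
    purity_threshold: float,
) -> np.ndarray:
    col = f"rss_{channel_index}"
    if col not in rss_df.columns:
        raise ChannelStatsError(f"table lacks column {col!r}; run normalization first")
    sub = rss_df[(rss_df["label"] == cls) & (rss_df["purity"] >= purity_threshold)]
    if "tissue_fraction" in sub.columns:
        # border sectors mix in background pixels; exclude from group stats
        sub = sub[sub["tissue_fraction"] >= 0.999]
    if mode == "sectors":
        return sub[col].to_numpy(dtype=float)
    if mode == "patients":
        return sub.groupby("patient_id")[col].median().to_numpy(dtype=float)
    raise ChannelStatsError(f"unknown aggregation mode {mode!r}")


def compare_channel_groups(
    rss_df: pd.DataFrame,
    channel_index: int,
    pair: tuple[str, str],
    mode: str = "sectors",
    purity_threshold: float = 0.8,
    exact_threshold: int = 8,
) -> ChannelComparison:
    """Mann-Whitney comparison of one channel's rss between two classes.

    ``mode="sectors"`` pools sectors as observations; ``mode="patients"``
    uses per-patient medians instead (guards against inflated n).
    """
    cls_a, cls_b = pair
    a = _group_values(rss_df, channel_index, cls_a, mode, purity_threshold)
    b = _group_values(rss_df, channel_index, cls_b, mode, purity_threshold)
    if a.size == 0 or b.size == 0:
        raise ChannelStatsError(f"empty group in pair {pair}")
    u, p, method = mann_whitney_u(a, b, exact_threshold=exact_threshold)
    return ChannelComparison(
        channel_index=channel_index,
        group_a=cls_a,
        group_b=cls_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=u,
        p_value=p,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        stars=stars_for_p(p),
        method=method,
        degenerate=method == "degenerate",
    )


def compare_channels(
    rss_df: pd.DataFrame,
    channels: Optional[Sequence[int]] = None,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    mode: str = "sectors",
    purity_threshold: float = 0.8,
    fdr: bool = False,
) -> pd.DataFrame:
    """Comparison table over channels x class pairs.

    No multiple-testing correction by default; ``fdr=True`` adds a
    Benjamini-Hochberg adjusted p column (stars stay tied to raw p).
    """
    if channels is None:
        channels = sorted(
            int(c.split("_")[1]) for c in rss_df.columns if c.startswith("rss_")
        )
    rows = []
    for ch in channels:
        for pair in pairs:
            comp = compare_channel_groups(
                rss_df, ch, pair, mode=mode, purity_threshold=purity_threshold
            )
            rows.append(
                {
                    "channel": comp.channel_index,
                    "group_a": comp.group_a,
                    "group_b": comp.group_b,
                    "n_a": comp.n_a,
                    "n_b": comp.n_b,
                    "U": comp.u_statistic,
                    "p": comp.p_value,
                    "median_a": comp.median_a,
                    "median_b": comp.median_b,
                    "stars": comp.stars,
                    "method": comp.method,
                }
            )
    table = pd.DataFrame(rows)
    if fdr and len(table):
        table["p_bh"] = false_discovery_control(table["p"], method="bh")
    return table


def plot_channel_distributions(
    rss_df: pd.DataFrame,
    channels: Sequence[int],
    path: str,
    purity_threshold: float = 0.8,
) -> str:
    """Box plots of per-class relative intensities for the given channels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = ("normal", "PTG", "OSSN")
    fig, axes = plt.subplots(
        1, len(channels), figsize=(3.2 * len(channels), 3.6), squeeze=False
    )
    for ax, ch in zip(axes[0], channels):
        data = [
            _group_values(rss_df, ch, cls, "sectors", purity_threshold)
            for cls in classes
        ]
        ax.boxplot(data, tick_labels=classes, showfliers=False)
        ax.set_title(f"Channel {ch}")
        ax.set_ylabel("relative intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
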