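"""Strain-level distribution summaries and rank-based comparison.

Focus intensity distributions are summarised as box statistics (median,
25/75 percentiles, 10/90 percentile whiskers) and compared across strains
with the Kruskal-Wallis rank test ("ANOVA on ranks"), followed by Dunn's
pairwise post-hoc z-tests with Holm adjustment. Rank tests are invariant
under any strictly increasing transform of the intensities, so they do not
depend on camera gain or offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntensityDistribution",
    "BoxSummary",
    "box_summary",
    "rank_anova",
    "dunn_posthoc",
    "compare_strains",
    "StrainComparison",
]


@dataclass
class IntensityDistribution:
    """Focus mean intensities (arbitrary fluorescence units) for one strain."""

    strain_label: str
    values: np.ndarray
    background_corrected: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class BoxSummary:
    median: float
    p25: float
    p75: float
    p10: float
    p90: float
    n: int

    def __post_init__(self) -> None:
        if not (self.p10 <= self.p25 <= self.median <= self.p75 <= self.p90):
            raise ValueError("percentiles out of order")


def box_summary(values, method: str = "linear") -> BoxSummary:
    """Box-and-whisker statistics: median, quartile box, 10/90 whiskers.

    Percentiles use linear interpolation between closest order statistics
    by default; ``method`` accepts any numpy percentile method name.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("box_summary of an empty sample")
    p10, p25, med, p75, p90 = np.percentile(
        values, [10, 25, 50, 75, 90], method=method
    )
    return BoxSummary(
        median=float(med), p25=float(p25), p75=float(p75),
        p10=float(p10), p90=float(p90), n=int(values.size),
    )


def rank_anova(
    groups: list[IntensityDistribution] | list[np.ndarray],
    permutation: int = 0,
    seed: int | None = None,
) -> tuple[float, float]:
    """Kruskal-Wallis H and p across >= 2 groups.

    Uses midranks with the standard tie correction; p comes from the
    chi-square approximation with (k - 1) degrees of freedom, or from a
    seeded permutation of group labels when ``permutation`` > 0 (useful at
    small N where the asymptotic p is unreliable). When every observation
    across all groups is identical there is no rank separation at all; the
    conventional (H, p) = (0, 1) is returned rather than an error.
    """
    arrays = [
        np.asarray(g.values if isinstance(g, IntensityDistribution) else g, float)
        for g in groups
    ]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    if permutation > 0:
        rng = np.random.default_rng(seed)
        sizes = [a.size for a in arrays]
        splits = np.cumsum(sizes)[:-1]
        count = 0
        for _ in range(permutation):
            perm = rng.permutation(pooled)
            parts = np.split(perm, splits)
            try:
                h_perm, _ = stats.kruskal(*parts)
            except ValueError:  # all values identical in permutation draw
                h_perm = 0.0
            if h_perm >= h:
                count += 1
        p = (count + 1) / (permutation + 1)
    return float(h), float(p)


def dunn_posthoc(
    groups: list[IntensityDistribution],
    adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled midranks with tie correction.

    Returns a table with one row per strain pair: z, raw two-sided p and
    the adjusted p (Holm step-down by default, ``adjust='none'`` to skip).
    """
    labels = [g.strain_label for g in groups]
    arrays = [np.asarray(g.values, float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term for the Dunn variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    splits = np.cumsum([a.size for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ni, nj = arrays[i].size, arrays[j].size
            se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / ni + 1 / nj))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            rows.append(
                {"strain_a": labels[i], "strain_b": labels[j], "z": z, "p_raw": p}
            )
    table = pd.DataFrame(rows, columns=["strain_a", "strain_b", "z", "p_raw"])
    if adjust == "holm" and len(table):
        p = table["p_raw"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        table["p_adj"] = adj
    elif adjust == "none":
        table["p_adj"] = table["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


@dataclass
class StrainComparison:
    summaries: pd.DataFrame
    h_statistic: float
    p_value: float
    significant: bool
    posthoc: pd.DataFrame
    alpha: float
    background_corrected: bool = True


def compare_strains(
    distributions: list[IntensityDistribution],
    alpha: float = 0.05,
    percentile_method: str = "linear",
) -> StrainComparison:
    """Full strain comparison: box summaries, omnibus rank test, post-hoc.

    The returned report records whether the compared column was
    background-corrected (all inputs must agree on that flag).
    """
    if len(distributions) < 2:
        raise ValueError("need at least two strains to compare")
    corrected = {d.background_corrected for d in distributions}
    if len(corrected) != 1:
        raise ValueError("mixing corrected and raw intensity distributions")
    rows = []
    for d in distributions:
        s = box_summary(d.values, method=percentile_method)
        rows.append(
            {
                "strain_label": d.strain_label,
                "n": s.n,
                "median": s.median,
                "p25": s.p25,
                "p75": s.p75,
                "p10": s.p10,
                "p90": s.p90,
            }
        )
    h, p = rank_anova(distributions)
    posthoc = dunn_posthoc(distributions)
    posthoc["significant"] = posthoc["p_adj"] < alpha
    return StrainComparison(
        summaries=pd.DataFrame(rows),
        h_statistic=h,
        p_value=p,
        significant=bool(p < alpha),
        posthoc=posthoc,
        alpha=alpha,
        background_corrected=corrected.pop(),
    )


def plot_comparison(comparison: StrainComparison, path: str) -> None:
    """Box-and-whisker figure (quartile box, median line, 10/90 whiskers)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = comparison.summaries
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(s), 3.2))
    for i, row in s.iterrows():
        ax.add_patch(
            plt.Rectangle(
                (i - 0.25, row["p25"]), 0.5, row["p75"] - row["p25"],
                fill=False, edgecolor="black",
            )
        )
        ax.hlines(row["median"], i - 0.25, i + 0.25, color="black", lw=2)
        ax.vlines(i, row["p75"], row["p90"], color="black")
        ax.vlines(i, row["p10"], row["p25"], color="black")
        ax.hlines([row["p10"], row["p90"]], i - 0.12, i + 0.12, color="black")
    ax.set_xticks(range(len(s)))
    ax.set_xticklabels(s["strain_label"], rotation=45, ha="right")
    ax.set_ylabel("focus intensity (au)")
    ax.set_xlim(-0.6, len(s) - 0.4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
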