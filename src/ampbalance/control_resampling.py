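"""Matched control-gene resampling test for balancing selection.

For each focal gene (an AMP, or a non-AMP immune gene), a control gene
is sampled uniformly from the nearby genes of comparable size: same
chromosome, midpoint within ``window_bp`` (100,000 bp by default) on
either side, coding length no more than ``size_ratio_max`` (10x) the
focal gene's, and not itself a member of the focal category.  The mean
focal-minus-control difference

    delta_bar = (1/n) * sum_i (X_focal_i - X_control_i)

over the n usable focal genes is one replicate; 10,000 replicates give
an empirical distribution whose summary (% > 0, mean, sd) is the test
output.  Controls are redrawn independently per focal gene per
replicate, so the same control may serve several focal genes within a
replicate and combinations may repeat across replicates.

Because AMPs cluster in the genome, a spaced variant repeats the test
on a random subset of k AMPs at least ``min_dist_bp`` apart, the subset
redrawn every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATISTICS = ("tajimas_d", "pi", "theta_w")


@dataclass(frozen=True)
class ControlPolicy:
    """Rules for drawing matched controls and sizing the resampling."""

    window_bp: int = 100_000
    size_ratio_max: float = 10.0
    exclusion_categories: frozenset[str] | None = None  # None -> focal category
    n_replicates: int = 10_000
    statistic: str = "tajimas_d"
    seed: int = 0

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.size_ratio_max < 1:
            raise ValueError("size_ratio_max must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ReplicateDistribution:
    """The per-replicate mean differences and the focal genes behind them."""

    deltas: np.ndarray
    n_focal: int
    candidate_sizes: dict[str, int] = field(default_factory=dict)
    statistic: str = ""
    category: str = ""

    def __post_init__(self):
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.n_focal < 1:
            raise ValueError("distribution requires at least one focal gene")


@dataclass(frozen=True)
class ResamplingSummary:
    """Percentage of positive replicates, their mean and sample sd."""

    pct_positive: float
    mean_diff: float
    sd_diff: float


def _as_frame(table) -> pd.DataFrame:
    return table.scoped if hasattr(table, "scoped") else table


def candidate_controls(
    table, focal: pd.Series, policy: ControlPolicy
) -> pd.DataFrame:
    """Genes eligible as controls for one focal gene under the policy."""
    df = _as_frame(table)
    exclude = policy.exclusion_categories
    if exclude is None:
        exclude = {focal["category"]}
    mask = (
        (df["chromosome"] == focal["chromosome"])
        & ((df["midpoint"] - focal["midpoint"]).abs() <= policy.window_bp)
        & (df["cds_length"] <= policy.size_ratio_max * focal["cds_length"])
        & ~df["category"].isin(exclude)
        & (df["gene_id"] != focal["gene_id"])
        & df[policy.statistic].notna()
    )
    return df[mask]


def _focal_candidate_values(
    df: pd.DataFrame, category: str, policy: ControlPolicy
) -> tuple[list[str], list[np.ndarray], dict[str, int]]:
    """Candidate statistic values per usable focal gene."""
    focals = df[(df["category"] == category) & df[policy.statistic].notna()]
    ids, values, sizes = [], [], {}
    for _, focal in focals.iterrows():
        cands = candidate_controls(df, focal, policy)
        sizes[focal["gene_id"]] = len(cands)
        if len(cands) == 0:
            logger.warning(
                "focal gene %s has no eligible controls; dropped", focal["gene_id"]
            )
            continue
        ids.append(focal["gene_id"])
        values.append(
            (focal[policy.statistic] - cands[policy.statistic].to_numpy(float))
        )
    return ids, values, sizes


def resample_differences(
    table, category: str, policy: ControlPolicy,
    rng: np.random.Generator | None = None,
) -> ReplicateDistribution:
    """Build the empirical distribution of mean focal-minus-control diffs."""
    df = _as_frame(table)
    ids, diffs, sizes = _focal_candidate_values(df, category, policy)
    if not ids:
        raise ValueError(
            f"no usable focal genes for category={category!r}, "
            f"statistic={policy.statistic!r}"
        )
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    n_focal = len(ids)
    reps = policy.n_replicates
    # one uniform control index per focal gene per replicate
    per_focal = np.empty((reps, n_focal))
    for j, d in enumerate(diffs):
        per_focal[:, j] = d[rng.integers(0, len(d), size=reps)]
    return ReplicateDistribution(
        deltas=per_focal.mean(axis=1),
        n_focal=n_focal,
        candidate_sizes=sizes,
        statistic=policy.statistic,
        category=category,
    )


def subsample_spaced_amps(
    amps: pd.DataFrame,
    k: int = 10,
    min_dist_bp: int = 5_000,
    rng: np.random.Generator | None = None,
    max_restarts: int = 200,
) -> list[str]:
    """Random subset of k AMPs with pairwise midpoint distance >= min_dist_bp.

    Genes on different chromosomes count as infinitely far apart.  The
    subset is drawn by randomized greedy selection (shuffle, then accept
    genes compatible with everything accepted so far), restarting until
    a subset of size k is found.
    """
    if len(amps) < k:
        raise ValueError(f"only {len(amps)} AMPs available, need {k}")
    if rng is None:
        rng = np.random.default_rng()
    chroms = amps["chromosome"].to_numpy()
    mids = amps["midpoint"].to_numpy(float)
    ids = amps["gene_id"].to_numpy()
    order = np.arange(len(amps))
    best = 0
    for _ in range(max_restarts):
        rng.shuffle(order)
        chosen: list[int] = []
        for i in order:
            ok = all(
                chroms[i] != chroms[j] or abs(mids[i] - mids[j]) >= min_dist_bp
                for j in chosen
            )
            if ok:
                chosen.append(i)
                if len(chosen) == k:
                    return [ids[i] for i in chosen]
        best = max(best, len(chosen))
    raise ValueError(
        f"no subset of {k} AMPs at >= {min_dist_bp} bp spacing found; "
        f"maximum achievable subset size was {best}"
    )


def resample_differences_spaced(
    table, policy: ControlPolicy,
    k: int = 10, min_dist_bp: int = 5_000,
    rng: np.random.Generator | None = None,
) -> ReplicateDistribution:
    """AMP resampling with a fresh spaced k-AMP subset every replicate.

    Controls for clustered AMPs pseudoreplicating the same local signal.
    """
    df = _as_frame(table)
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    ids, diffs, sizes = _focal_candidate_values(df, "AMP", policy)
    if not ids:
        raise ValueError("no usable AMP focal genes")
    usable = df[df["gene_id"].isin(ids)].set_index("gene_id").loc[ids].reset_index()
    by_id = {g: d for g, d in zip(ids, diffs)}
    deltas = np.empty(policy.n_replicates)
    for r in range(policy.n_replicates):
        subset = subsample_spaced_amps(usable, k, min_dist_bp, rng)
        vals = [by_id[g][rng.integers(0, len(by_id[g]))] for g in subset]
        deltas[r] = float(np.mean(vals))
    return ReplicateDistribution(
        deltas=deltas, n_focal=k, candidate_sizes=sizes,
        statistic=policy.statistic, category="AMP",
    )


def summarize_replicates(dist: ReplicateDistribution) -> ResamplingSummary:
    """Table-2-style summary: % of replicates > 0 (strict), mean, sample sd."""
    d = dist.deltas
    if d.size == 0:
        raise ValueError("empty replicate distribution")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return ResamplingSummary(
        pct_positive=100.0 * float((d > 0).mean()),
        mean_diff=float(d.mean()),
        sd_diff=sd,
    )


def run_all_statistics(
    table, category: str, policy: ControlPolicy,
) -> dict[str, tuple[ReplicateDistribution, ResamplingSummary]]:
    """Resample all three statistics under per-statistic derived seeds."""
    out = {}
    for i, stat in enumerate(STATISTICS):
        p = replace(policy, statistic=stat, seed=policy.seed + i)
        dist = resample_differences(table, category, p)
        out[stat] = (dist, summarize_replicates(dist))
    return out


def write_replicates_tsv(dist: ReplicateDistribution, path) -> None:
    pd.DataFrame({
        "replicate_index": np.arange(len(dist.deltas)),
        "delta": dist.deltas,
    }).to_csv(path, sep="\t", index=False)


def summary_frame(
    results: dict[str, tuple[ReplicateDistribution, ResamplingSummary]],
    population: str = "",
) -> pd.DataFrame:
    """Long-form summary table (statistic x {pct_positive, mean, sd})."""
    rows = []
    for stat, (_, summ) in results.items():
        rows.append((stat, "diff_gt_0_pct", population, summ.pct_positive))
        rows.append((stat, "mean_diff", population, summ.mean_diff))
        rows.append((stat, "diff_std_dev", population, summ.sd_diff))
    return pd.DataFrame(rows, columns=["statistic", "measure", "population", "value"])
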