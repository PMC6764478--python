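"""Nested linear models and the background-selection residual analysis.

Two model families test whether AMPs carry elevated silent diversity:

* the nested ANOVA  Y = chromosome + gene_length + chromosome/region +
  chromosome/region/AMP, where Y is a per-gene statistic, regions are
  either 200,000-bp tiles or AMP-centred neighbourhoods, and the AMP
  term is an indicator nested in its region;
* the background-selection (BGS) adjusted model  Y = M1 + region/AMP,
  where M1 is the per-gene mean of Comeron-style B values (expected
  diversity retention under purifying selection at linked sites) over
  the 1,000-bp windows the gene overlaps.

Silent polymorphism is also regressed on B across windows; windows with
positive residuals carry more polymorphism than background selection
predicts, and the mean residual of a gene's windows feeds the matched
control resampling as a statistic in its own right.

Term F-tests use Type II sums of squares, computed as nested-model RSS
comparisons with rank-aware degrees of freedom (sparse nested AMP
indicators routinely alias levels, which formula interfaces reject).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .control_resampling import (
    ControlPolicy,
    ReplicateDistribution,
    ResamplingSummary,
    resample_differences,
    summarize_replicates,
)

logger = logging.getLogger(__name__)

WINDOW_BP = 1_000  # B-statistic window width


@dataclass
class AnovaTable:
    """Per-term F tests (term, df, F, P) for one fitted model."""

    terms: pd.DataFrame
    model: str
    scope: str

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


@dataclass
class RegressionFit:
    """OLS of window silent polymorphism on the B statistic."""

    intercept: float
    slope: float
    residuals: pd.Series  # indexed like the window table

    def __post_init__(self):
        if abs(float(self.residuals.mean())) > 1e-8 * max(
            1.0, float(np.abs(self.residuals).max())
        ):
            raise ValueError("OLS residuals do not average to zero")


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

def assign_regions(
    df: pd.DataFrame,
    mode: str = "tiled",
    width: int = 200_000,
    neighborhood_bp: int = 100_000,
    size_ratio_max: float = 10.0,
) -> pd.Series:
    """Region label per gene; NaN marks genes outside every region.

    ``tiled``: region = floor(midpoint / width), labelled within its
    chromosome so identical tile indices on different chromosomes stay
    distinct.  ``amp_neighborhood``: each AMP anchors a region of the
    genes within ``neighborhood_bp`` of its midpoint and at most
    ``size_ratio_max`` times its coding length (the control-eligibility
    rule); genes in several neighbourhoods go to the nearest AMP, genes
    in none are excluded.
    """
    if mode == "tiled":
        tiles = (df["midpoint"] // width).astype(int).astype(str)
        return df["chromosome"].astype(str) + ":" + tiles
    if mode != "amp_neighborhood":
        raise ValueError(f"unknown region mode {mode!r}")

    labels = pd.Series(np.nan, index=df.index, dtype=object)
    dist = pd.Series(np.inf, index=df.index)
    for _, amp in df[df["category"] == "AMP"].iterrows():
        d = (df["midpoint"] - amp["midpoint"]).abs()
        member = (
            (df["chromosome"] == amp["chromosome"])
            & (d <= neighborhood_bp)
            & (df["cds_length"] <= size_ratio_max * amp["cds_length"])
        )
        member |= df["gene_id"] == amp["gene_id"]
        closer = member & (d < dist)
        labels[closer] = amp["gene_id"]
        dist[closer] = d[closer]
    return labels


# ---------------------------------------------------------------------------
# Type II ANOVA via nested-model RSS comparisons
# ---------------------------------------------------------------------------

def _dummies(labels: pd.Series, drop_first_within: pd.Series | None = None):
    """Dummy columns for a categorical, dropping one reference level
    (per group of ``drop_first_within`` when nesting)."""
    labels = labels.astype(str)
    cols = []
    if drop_first_within is None:
        levels = sorted(labels.unique())[1:]
        groups = {lv: labels == lv for lv in levels}
    else:
        groups = {}
        for g in sorted(drop_first_within.astype(str).unique()):
            in_g = drop_first_within.astype(str) == g
            for lv in sorted(labels[in_g].unique())[1:]:
                groups[f"{g}|{lv}"] = in_g & (labels == lv)
    for name, mask in groups.items():
        cols.append(pd.Series(mask.astype(float), name=name))
    return pd.DataFrame(cols).T if cols else pd.DataFrame(index=labels.index)


def _rss_rank(y: np.ndarray, blocks: list[np.ndarray]) -> tuple[float, int]:
    x = np.column_stack([np.ones(len(y))] + [b for b in blocks if b.size])
    fit = sm.OLS(y, x).fit()
    return float(fit.ssr), int(np.linalg.matrix_rank(x))


def _type2_anova(
    y: np.ndarray,
    blocks: dict[str, np.ndarray],
    containment: dict[str, set[str]],
    model: str,
    scope: str,
) -> AnovaTable:
    """Type II F per term: compare the model of all terms not containing
    the term, with and without it, against the full-model error."""
    names = list(blocks)
    rss_full, rank_full = _rss_rank(y, [blocks[t] for t in names])
    df_resid = len(y) - rank_full
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    mse = rss_full / df_resid
    total_ss = float(((y - y.mean()) ** 2).sum())
    degenerate = total_ss <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2) * len(y)
    rows = []
    for term in names:
        others = [t for t in names if t != term and term not in containment.get(t, set())]
        rss_r, rank_r = _rss_rank(y, [blocks[t] for t in others])
        rss_w, rank_w = _rss_rank(y, [blocks[t] for t in others] + [blocks[term]])
        df_t = rank_w - rank_r
        if df_t == 0:
            raise ValueError(f"singular design: term {term!r} fully aliased")
        if degenerate:  # constant response: no variance to attribute
            rows.append((term, df_t, 0.0, 1.0))
            continue
        f = max(0.0, (rss_r - rss_w) / df_t) / mse
        p = float(sps.f.sf(f, df_t, df_resid)) if mse > 0 else 1.0
        rows.append((term, df_t, f, p))
    terms = pd.DataFrame(rows, columns=["term", "df", "F", "P"])
    terms["df_resid"] = df_resid
    return AnovaTable(terms, model=model, scope=scope)


def _amp_block(df: pd.DataFrame, region: pd.Series) -> np.ndarray:
    """One indicator column per AMP-containing region (AMP nested in
    region nested in chromosome)."""
    is_amp = (df["category"] == "AMP").to_numpy(float)
    cols = []
    for r in sorted(region.astype(str).unique()):
        in_r = (region.astype(str) == r).to_numpy(float)
        col = is_amp * in_r
        if col.any():
            cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def fit_nested_anova(
    table, statistic: str = "tajimas_d", mode: str = "tiled",
    width: int = 200_000,
) -> AnovaTable:
    """Fit Y = chromosome + gene_length + chromosome/region +
    chromosome/region/AMP and return Type II F/P per term.

    Genes with an undefined statistic are dropped listwise; degrees of
    freedom reflect the drops.
    """
    df = (table.scoped if hasattr(table, "scoped") else table).copy()
    df = df[df[statistic].notna()].reset_index(drop=True)
    region = assign_regions(df, mode=mode, width=width)
    keep = region.notna()
    if mode == "amp_neighborhood":
        dropped = int((~keep).sum())
        if dropped:
            logger.info("amp_neighborhood mode excluded %d genes", dropped)
    df, region = df[keep].reset_index(drop=True), region[keep].reset_index(drop=True)
    if df["chromosome"].nunique() < 2 and mode == "tiled":
        logger.warning("single chromosome: chromosome term has no contrast")

    y = df[statistic].to_numpy(float)
    blocks = {
        "chromosome": _dummies(df["chromosome"]).to_numpy(),
        "gene_length": df[["cds_length"]].to_numpy(float),
        "region": _dummies(region, drop_first_within=df["chromosome"]).to_numpy(),
        "AMP": _amp_block(df, region),
    }
    containment = {
        "region": {"chromosome"},
        "AMP": {"chromosome", "region"},
    }
    return _type2_anova(
        y, blocks, containment,
        model="Y ~ chromosome + gene_length + chromosome/region + chromosome/region/AMP",
        scope=mode,
    )


# ---------------------------------------------------------------------------
# Background-selection regression and residuals
# ---------------------------------------------------------------------------

def regress_on_b(windows: pd.DataFrame) -> RegressionFit:
    """OLS of window silent polymorphism on the B statistic."""
    if len(windows) < 3:
        raise ValueError("need at least 3 windows")
    b = windows["B"].to_numpy(float)
    if np.ptp(b) == 0:
        raise ValueError("B statistic is constant: degenerate predictor")
    x = sm.add_constant(b)
    fit = sm.OLS(windows["silent_polymorphism"].to_numpy(float), x).fit()
    return RegressionFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        residuals=pd.Series(fit.resid, index=windows.index),
    )


def gene_window_means(
    genes: pd.DataFrame, windows: pd.DataFrame, column: str
) -> pd.Series:
    """Per-gene unweighted mean of a window column over every window the
    gene overlaps by at least one base (windows are 1,000-bp tiles)."""
    by_chrom = {c: g.sort_values("start") for c, g in windows.groupby("chromosome")}
    out = pd.Series(np.nan, index=genes.index)
    for i, gene in genes.iterrows():
        w = by_chrom.get(gene["chromosome"])
        if w is None:
            continue
        lo = int(gene["start"]) // WINDOW_BP * WINDOW_BP
        hit = w[(w["start"] >= lo) & (w["start"] < gene["end"])]
        if len(hit):
            out[i] = float(hit[column].mean())
    return out


def resample_residuals(
    fit: RegressionFit,
    genes, windows: pd.DataFrame,
    category: str,
    policy: ControlPolicy,
) -> tuple[ReplicateDistribution, ResamplingSummary]:
    """Matched-control resampling on per-gene mean regression residuals."""
    df = (genes.scoped if hasattr(genes, "scoped") else genes).copy()
    w = windows.copy()
    w["residual"] = fit.residuals
    df["residual"] = gene_window_means(df, w, "residual")
    unmapped = df[df["residual"].isna()]["gene_id"].tolist()
    if unmapped:
        raise ValueError(f"genes overlap no B window: {unmapped[:5]}...")
    from dataclasses import replace

    policy = replace(policy, statistic="residual")
    dist = resample_differences(df, category, policy)
    return dist, summarize_replicates(dist)


def fit_bgs_anova(
    table, windows: pd.DataFrame,
    statistic: str = "pi",
    scope: str = "genome_wide",
    region_mode: str | None = None,
    width: int = 200_000,
    include_m1: bool = True,
) -> AnovaTable:
    """Fit the BGS-adjusted model Y = M1 + region/AMP (Type II F/P).

    M1 is each gene's mean B over overlapping 1,000-bp windows.  Scope
    ``genome_wide`` uses 200,000-bp tiled regions across the AMP-bearing
    arms; ``amp_regions`` restricts to 100,000-bp AMP neighbourhoods.
    ``include_m1=False`` drops the covariate (the unadjusted comparison
    model Y = region/AMP).
    """
    df = (table.scoped if hasattr(table, "scoped") else table).copy()
    df = df[df[statistic].notna()].reset_index(drop=True)
    df["M1"] = gene_window_means(df, windows, "B")
    df = df[df["M1"].notna()].reset_index(drop=True)
    if region_mode is None:
        region_mode = "tiled" if scope == "genome_wide" else "amp_neighborhood"
    region = assign_regions(df, mode=region_mode, width=width)
    keep = region.notna()
    df, region = df[keep].reset_index(drop=True), region[keep].reset_index(drop=True)

    y = df[statistic].to_numpy(float)
    blocks = {
        "M1": df[["M1"]].to_numpy(float),
        "region": _dummies(region).to_numpy(),
        "AMP": _amp_block(df, region),
    }
    if not include_m1:
        del blocks["M1"]
    containment = {"AMP": {"region"}}
    return _type2_anova(
        y, blocks, containment,
        model="Y ~ M1 + region/AMP" if include_m1 else "Y ~ region/AMP",
        scope=scope,
    )


def residual_window_frame(
    fit: RegressionFit, windows: pd.DataFrame, genes
) -> pd.DataFrame:
    """Plot-ready window table: B, polymorphism, residual, AMP/immune flags."""
    df = (genes.scoped if hasattr(genes, "scoped") else genes)
    out = windows.copy()
    out["residual"] = fit.residuals
    for flag, cat in (("contains_amp", "AMP"), ("contains_immune", "immune")):
        out[flag] = False
        sub = df[df["category"] == cat]
        for _, gene in sub.iterrows():
            lo = int(gene["start"]) // WINDOW_BP * WINDOW_BP
            mask = (
                (out["chromosome"] == gene["chromosome"])
                & (out["start"] >= lo)
                & (out["start"] < gene["end"])
            )
            out.loc[mask, flag] = True
    return out
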