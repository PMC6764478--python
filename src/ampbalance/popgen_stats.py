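"""Per-gene polymorphism statistics on silent sites with missing data.

Computes the number of segregating sites S, per-site nucleotide
diversity pi, per-site Watterson's theta and Tajima's D from a
:class:`~ampbalance.silent_sites.SilentSiteMatrix`.  Missing data is
handled per column: each silent column carries its own usable sample
size n_j, pi uses the unbiased per-column estimator at n_j, theta
divides each segregating site by the harmonic number a1(n_j), and
Tajima's variance constants are evaluated at a single effective sample
size n_eff = round(mean n_j).

D is *undefined* (None) rather than zero when S = 0 or n_eff < 4;
undefined genes are excluded from D-based analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .silent_sites import GeneRecord, SilentSiteMatrix


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of Tajima's D variance at sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError(f"need n >= 2, got {n}")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def harmonic(n: int | np.ndarray) -> np.ndarray:
    """a1(n) = sum_{i=1}^{n-1} 1/i, vectorised over column sample sizes."""
    n = np.asarray(n)
    out = np.zeros(n.shape, dtype=float)
    for val in np.unique(n):
        if val >= 2:
            out[n == val] = np.sum(1.0 / np.arange(1, val))
    return out


def _per_column_pi(m: SilentSiteMatrix) -> np.ndarray:
    """Unbiased heterozygosity per column: (n/(n-1)) (1 - sum p^2).

    Equivalently, mismatching pairs / C(n_j, 2).  Columns with n_j < 2
    contribute zero (they cannot enter with the default n_min anyway).
    """
    n = m.n_j.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = m.counts / n[:, None]
        pi = n / (n - 1) * (1.0 - (freqs**2).sum(axis=1))
    pi[n < 2] = 0.0
    return pi


def segregating_sites(m: SilentSiteMatrix) -> int:
    """Number of silent columns with more than one base present."""
    return int(m.segregating.sum())


def nucleotide_diversity(m: SilentSiteMatrix) -> float:
    """Per-site pi: mean over silent columns of pairwise heterozygosity."""
    if m.l_silent == 0:
        raise ValueError(f"{m.gene_id}: no silent sites")
    return float(_per_column_pi(m).sum() / m.l_silent)


def watterson_theta(m: SilentSiteMatrix) -> float:
    """Per-site Watterson's theta with each site corrected by its own n_j."""
    if m.l_silent == 0:
        raise ValueError(f"{m.gene_id}: no silent sites")
    seg = m.segregating
    a1 = harmonic(m.n_j)
    theta_total = float(np.sum(seg[a1 > 0] / a1[a1 > 0]))
    return theta_total / m.l_silent


def effective_sample_size(m: SilentSiteMatrix) -> int:
    """Rounded mean per-column sample size over included columns."""
    if m.l_silent == 0:
        return 0
    return int(round(float(m.n_j.mean())))


def tajimas_d(m: SilentSiteMatrix) -> float | None:
    """Tajima's D on silent-site totals; None when undefined.

    D = (pi_total - theta_total) / sqrt(e1 S + e2 S (S-1)) with the
    variance constants evaluated at n_eff.  Undefined (None, never 0)
    when S = 0 or n_eff < 4.
    """
    s = segregating_sites(m)
    n_eff = effective_sample_size(m)
    if s == 0 or n_eff < 4:
        return None
    pi_total = float(_per_column_pi(m).sum())
    a1 = harmonic(m.n_j)
    theta_total = float(np.sum(m.segregating[a1 > 0] / a1[a1 > 0]))
    k = TajimaConstants.from_n(n_eff)
    var = k.e1 * s + k.e2 * s * (s - 1)
    return (pi_total - theta_total) / np.sqrt(var)


def footprint_window(rho: float) -> float:
    """Physical footprint (bp) of a balanced polymorphism: 1/rho.

    ``rho`` is the population-scaled recombination rate 4*Ne*r per bp;
    its reciprocal approximates the window of linked polymorphism over
    which a balanced allele leaves a detectable signature.
    """
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    return 1.0 / rho


@dataclass
class GeneStats:
    """Per-gene silent-site summary statistics."""

    gene_id: str
    l_silent: int
    s: int
    pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float | None
    n_eff: int

    def __post_init__(self):
        if self.s > self.l_silent:
            raise ValueError(f"{self.gene_id}: S > L_silent")
        if self.pi_per_site < 0 or self.theta_w_per_site < 0:
            raise ValueError(f"{self.gene_id}: negative diversity")


def compute_gene_stats(m: SilentSiteMatrix) -> GeneStats | None:
    """All statistics for one gene; None if the gene has no silent sites."""
    if m.l_silent == 0:
        return None
    return GeneStats(
        gene_id=m.gene_id,
        l_silent=m.l_silent,
        s=segregating_sites(m),
        pi_per_site=nucleotide_diversity(m),
        theta_w_per_site=watterson_theta(m),
        tajimas_d=tajimas_d(m),
        n_eff=effective_sample_size(m),
    )


STATS_COLUMNS = [
    "gene_id", "chromosome", "start", "end", "strand", "category",
    "cds_length", "L_silent", "S", "pi", "theta_w", "tajimas_d", "n_eff",
]


def stats_table(records: list[GeneRecord], stats: dict[str, GeneStats]):
    """Join gene records with their statistics into the per-gene table.

    Genes without statistics (no silent data) are omitted.  The table is
    both the output of the sequence path and the ingestion format for
    externally computed statistics (the Pool-seq path).
    """
    import pandas as pd

    rows = []
    for rec in records:
        st = stats.get(rec.gene_id)
        if st is None:
            continue
        rows.append({
            "gene_id": rec.gene_id,
            "chromosome": rec.chromosome,
            "start": rec.start,
            "end": rec.end,
            "strand": rec.strand,
            "category": rec.category,
            "cds_length": rec.cds_length,
            "L_silent": st.l_silent,
            "S": st.s,
            "pi": st.pi_per_site,
            "theta_w": st.theta_w_per_site,
            "tajimas_d": np.nan if st.tajimas_d is None else st.tajimas_d,
            "n_eff": st.n_eff,
        })
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def write_stats_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")
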