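"""Data-quality and scope filters, and assembly of the per-gene table.

Three filters are applied before any statistic enters an analysis:

* haplotypes with *over* 25% ambiguous bases in a gene's alignment are
  removed (strict inequality at the boundary);
* sequenced lines may be restricted to a high-quality subset by the
  fraction of sites called in 1,000-bp windows genome-wide;
* non-autosomal (X-linked) genes are always dropped, and the modelling
  and resampling views are restricted to the AMP-bearing autosome arms
  (2L, 2R, 3R by default).

Every removal is appended to a provenance ledger so input and output
row counts always balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen_stats import GeneStats, stats_table
from .silent_sites import AMBIGUOUS, CodingAlignment, GeneRecord

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset({"2L", "2R", "3L", "3R", "4"})
DEFAULT_SCOPE = frozenset({"2L", "2R", "3R"})


def ambiguous_fraction(seq: str) -> float:
    """Fraction of bases that are IUPAC-ambiguous or gaps."""
    if not seq:
        return 0.0
    return sum(c in AMBIGUOUS for c in seq.upper()) / len(seq)


def filter_ambiguous_sequences(
    aln: CodingAlignment, max_frac: float = 0.25
) -> tuple[CodingAlignment, list[str]]:
    """Drop haplotypes whose ambiguous fraction is strictly above max_frac.

    Returns the filtered alignment (survivor order preserved) and the
    removed labels.  An alignment may come back empty; callers flag the
    gene as "no data" and exclude it downstream.
    """
    keep_labels, keep_seqs, removed = [], [], []
    for label, seq in zip(aln.labels, aln.sequences):
        if ambiguous_fraction(seq) > max_frac:
            removed.append(label)
        else:
            keep_labels.append(label)
            keep_seqs.append(seq)
    if removed:
        logger.info(
            "%s: removed %d/%d haplotypes over %.0f%% ambiguous",
            aln.gene_id, len(removed), aln.n_haplotypes, 100 * max_frac,
        )
    out = CodingAlignment(aln.gene_id, keep_labels, keep_seqs)
    out.has_internal_stop = aln.has_internal_stop
    return out, removed


@dataclass
class LineQualityReport:
    """Per-line called fractions in 1,000-bp windows across the genome.

    ``window_fractions`` maps line id -> array of per-window called
    (non-ambiguous) fractions.
    """

    window_fractions: dict[str, np.ndarray]

    def __post_init__(self):
        for line, fr in self.window_fractions.items():
            fr = np.asarray(fr, dtype=float)
            if ((fr < 0) | (fr > 1)).any():
                raise ValueError(f"{line}: called fractions outside [0,1]")
            self.window_fractions[line] = fr

    def overall_fraction(self, line: str) -> float:
        return float(self.window_fractions[line].mean())


def filter_lines_by_completeness(
    report: LineQualityReport,
    min_called_window_frac: float = 0.75,
    min_pass_windows_frac: float = 1.0,
) -> list[str]:
    """Retain lines whose windows are sufficiently complete.

    A window passes when its called fraction is >= min_called_window_frac;
    a line is retained when the fraction of passing windows is >=
    min_pass_windows_frac.  Deterministic; input order preserved.
    """
    retained = []
    for line, fr in report.window_fractions.items():
        pass_frac = float((fr >= min_called_window_frac).mean())
        if pass_frac >= min_pass_windows_frac:
            retained.append(line)
    if not retained:
        raise ValueError(
            "completeness filter retained no lines "
            f"(min_called_window_frac={min_called_window_frac}, "
            f"min_pass_windows_frac={min_pass_windows_frac})"
        )
    return retained


@dataclass
class GeneTable:
    """The assembled per-gene analysis table plus filter provenance.

    ``autosomal`` is the genome-wide autosomal table; ``scoped`` is the
    view restricted to the AMP-bearing chromosome arms used by the
    linear models and the control resampling.
    """

    autosomal: pd.DataFrame
    scoped: pd.DataFrame
    population: str = ""
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        for df in (self.autosomal, self.scoped):
            if len(df) and not set(df["chromosome"]) <= AUTOSOMES:
                raise ValueError("non-autosomal genes present in gene table")


def build_gene_table(
    records: list[GeneRecord],
    stats: dict[str, GeneStats] | pd.DataFrame,
    scope_chromosomes: frozenset[str] = DEFAULT_SCOPE,
    population: str = "",
) -> GeneTable:
    """Join records to statistics and apply the scope filters.

    ``stats`` may be a per-gene statistics DataFrame (the TSV contract)
    or a dict of GeneStats.  X-linked genes are always dropped; the
    scoped view additionally keeps only ``scope_chromosomes``.
    """
    if isinstance(stats, dict):
        df = stats_table(records, stats)
        known = {r.gene_id for r in records}
        orphans = set(stats) - known
        if orphans:
            raise KeyError(f"statistics for unknown genes: {sorted(orphans)}")
    else:
        df = stats.copy()
    provenance: list[tuple[str, int]] = []

    n0 = len(df)
    df = df[df["L_silent"] >= 1]
    provenance.append(("no_silent_data", n0 - len(df)))

    n0 = len(df)
    df = df[df["chromosome"].isin(AUTOSOMES)]
    provenance.append(("non_autosomal", n0 - len(df)))

    df = df.reset_index(drop=True)
    df["midpoint"] = (df["start"] + df["end"]) / 2

    scoped = df[df["chromosome"].isin(scope_chromosomes)].reset_index(drop=True)
    provenance.append(("outside_scope_arms", len(df) - len(scoped)))
    for step, n in provenance:
        if n:
            logger.info("%s: filter %s removed %d genes", population or "-", step, n)
    return GeneTable(df, scoped, population=population, provenance=provenance)


def provenance_frame(table: GeneTable) -> pd.DataFrame:
    return pd.DataFrame(table.provenance, columns=["filter", "genes_removed"])
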