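"""Extraction of coding alignments and four-fold degenerate (silent) sites.

A silent site here is the third position of a codon whose four
third-position variants all encode the same amino acid under the standard
genetic code (e.g. GCN -> Ala).  Restricting polymorphism statistics to
these columns guarantees that every counted variant is synonymous, so
elevated diversity cannot be explained by relaxed constraint on the
protein sequence.

Coordinates are 0-based half-open internally; GFF3 input (1-based,
inclusive) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
AMBIGUOUS = set("NRYSWKMBDHV-")  # IUPAC ambiguity plus alignment gap

CATEGORIES = ("AMP", "immune", "background")


def _codon_to_aa(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def codon_degeneracy(codon: str) -> int | None:
    """Degeneracy class of the codon's third position (1, 2, 3 or 4).

    Returns the number of third-position bases encoding the same amino
    acid as ``codon`` (stop codons are compared like an amino acid and
    flagged by callers, not here).  ``None`` if any base is ambiguous.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        return None
    aa = _codon_to_aa(codon)
    return sum(_codon_to_aa(codon[:2] + b) == aa for b in BASES)


#: Codon prefixes (first two bases) whose third position is four-fold
#: degenerate; derived by brute force from the standard table.
FOURFOLD_PREFIXES: frozenset[str] = frozenset(
    p for p in (a + b for a in BASES for b in BASES)
    if codon_degeneracy(p + "A") == 4
)


@dataclass(frozen=True)
class GeneRecord:
    """A gene's coordinates, strand, CDS length and analysis category."""

    gene_id: str
    chromosome: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    cds_length: int
    category: str = "background"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.cds_length % 3:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown category {self.category!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class CodingAlignment:
    """Equal-length CDS sequences (coding strand, frame 0) per haplotype."""

    gene_id: str
    labels: list[str]
    sequences: list[str]
    has_internal_stop: bool = field(default=False)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        if self.sequences and len(self.sequences[0]) % 3:
            raise ValueError(f"{self.gene_id}: alignment length not a multiple of 3")
        if len(self.labels) != len(self.sequences):
            raise ValueError(f"{self.gene_id}: labels/sequences mismatch")

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class SilentSiteMatrix:
    """Per-gene silent columns with per-base counts and usable sample sizes.

    ``counts`` has one row per included column, columns ordered A,C,G,T;
    ``n_j`` is the row sum (haplotypes whose own codon qualified).
    """

    gene_id: str
    counts: np.ndarray  # (L_silent, 4) int
    n_max: int          # haplotypes in the source alignment

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int).reshape(-1, 4)
        if (self.counts < 0).any():
            raise ValueError("negative base count")
        if (self.n_j > self.n_max).any():
            raise ValueError("column sample size exceeds haplotype count")

    @property
    def n_j(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def l_silent(self) -> int:
        return self.counts.shape[0]

    @property
    def segregating(self) -> np.ndarray:
        """Boolean mask of columns with more than one base present."""
        return (self.counts > 0).sum(axis=1) > 1


def extract_cds_alignment(
    haplotypes: dict[str, str],
    gene: GeneRecord,
    exons: list[tuple[int, int]] | None = None,
) -> CodingAlignment:
    """Slice a gene's CDS out of per-haplotype chromosome sequences.

    Exons (0-based half-open, in genomic order) are concatenated and
    minus-strand genes reverse-complemented so the result is the coding
    strand.  Ambiguity characters are preserved.
    """
    if exons is None:
        exons = [(gene.start, gene.end)]
    total = sum(e - s for s, e in exons)
    if total % 3:
        raise ValueError(f"{gene.gene_id}: exon lengths sum to {total}, not a multiple of 3")
    labels, seqs = [], []
    for label, seq in haplotypes.items():
        for s, e in exons:
            if s < 0 or e > len(seq):
                raise IndexError(
                    f"{gene.gene_id}: exon [{s},{e}) outside sequence of length {len(seq)}"
                )
        cds = "".join(seq[s:e] for s, e in exons).upper()
        if gene.strand == "-":
            cds = reverse_complement(cds)
        labels.append(label)
        seqs.append(cds)
    aln = CodingAlignment(gene.gene_id, labels, seqs)
    aln.has_internal_stop = _reference_has_internal_stop(aln)
    return aln


def _reference_has_internal_stop(aln: CodingAlignment) -> bool:
    """Check the first (reference) haplotype for premature stop codons."""
    if not aln.sequences:
        return False
    ref = aln.sequences[0]
    for i in range(0, len(ref) - 3, 3):  # exclude the terminal codon
        codon = ref[i : i + 3]
        if codon in standard_dna_table.stop_codons:
            return True
    return False


def extract_silent_columns(
    aln: CodingAlignment, n_min: int = 4
) -> SilentSiteMatrix:
    """Reduce a coding alignment to its four-fold degenerate columns.

    A haplotype qualifies at a codon's third position iff its own codon
    is unambiguous and four-fold degenerate.  A column enters the matrix
    iff at least ``n_min`` haplotypes qualify AND all qualifying
    haplotypes share the same first two codon bases — columns mixing
    synonymous families (e.g. Leu TTR vs CTN) are excluded so every
    counted variant is guaranteed synonymous.
    """
    rows = []
    base_index = {b: i for i, b in enumerate(BASES)}
    for ci in range(aln.length // 3):
        prefixes, thirds = [], []
        for seq in aln.sequences:
            codon = seq[3 * ci : 3 * ci + 3]
            if any(b not in BASES for b in codon):
                continue
            if codon[:2] in FOURFOLD_PREFIXES:
                prefixes.append(codon[:2])
                thirds.append(codon[2])
        if len(thirds) < n_min:
            continue
        if len(set(prefixes)) > 1:
            logger.debug(
                "%s codon %d: mixed synonymous families %s, column excluded",
                aln.gene_id, ci, sorted(set(prefixes)),
            )
            continue
        row = np.zeros(4, dtype=int)
        for b in thirds:
            row[base_index[b]] += 1
        rows.append(row)
    counts = np.vstack(rows) if rows else np.zeros((0, 4), dtype=int)
    return SilentSiteMatrix(aln.gene_id, counts, aln.n_haplotypes)


# ---------------------------------------------------------------------------
# File readers (FASTA haplotypes, GFF3 annotation, category table)
# ---------------------------------------------------------------------------

def read_haplotype_fasta(path) -> dict[str, str]:
    """Read a per-chromosome multi-FASTA: one record per haplotype line."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3_genes(path) -> dict[str, dict]:
    """Parse gene models from GFF3 (1-based inclusive -> 0-based half-open).

    Returns a mapping gene_id -> {chromosome, strand, exons} where exons
    are the gene's CDS intervals in genomic order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: dict[str, dict] = {}
    for gene in db.features_of_type("gene"):
        cds = sorted(
            db.children(gene, featuretype="CDS"), key=lambda f: f.start
        )
        intervals = [(f.start - 1, f.end) for f in cds] or [(gene.start - 1, gene.end)]
        genes[gene.id] = {
            "chromosome": gene.seqid,
            "strand": gene.strand,
            "exons": intervals,
        }
    return genes


def read_category_table(path) -> dict[str, str]:
    """Read the gene-category TSV (gene_id, category)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "category"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, category")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"{path}: unknown categories {sorted(bad)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    return dict(zip(df["gene_id"], df["category"]))


def write_silent_site_tsv(matrix: SilentSiteMatrix, path) -> None:
    """Write per-column base counts (gene_id, column_index, A,C,G,T, n_j)."""
    import pandas as pd

    df = pd.DataFrame(matrix.counts, columns=list(BASES))
    df.insert(0, "column_index", np.arange(matrix.l_silent))
    df.insert(0, "gene_id", matrix.gene_id)
    df["n_j"] = matrix.n_j
    df.to_csv(path, sep="\t", index=False)
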