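"""Synthetic genomes with controlled site-frequency spectra.

The generator emulates the statistical structure of a set of inbred-line
population genomes, at the level the downstream analyses measure, by
assigning derived-allele counts to silent sites directly rather than
running a coalescent:

* third positions of four-fold degenerate codons segregate with
  probability ``p_seg`` (a per-site theta proxy);
* at a segregating site the derived count k in 1..n-1 follows the
  neutral spectrum p(k) proportional to 1/k, reweighted multiplicatively
  — a singleton excess (1 + w_s) on k = 1 drives the genome-wide
  Tajima's D negative, as observed in expanding fly populations, while
  an intermediate-frequency excess (1 + w_b) on k in [n/3, 2n/3] mimics
  a balanced polymorphism at designated genes;
* derived alleles stay inside the same four-fold codon family, so every
  haplotype translates to the same protein;
* haplotypes carry ambiguity characters ('N') at a low per-base rate,
  with a configurable fraction of high-ambiguity lines (> 25% N) that
  the quality filters must remove;
* antimicrobial-peptide genes are laid out in tight genomic clusters,
  and a background-selection landscape assigns each 1,000-bp window a
  B value plus a silent-polymorphism response that is linear in B with
  an additive boost over balanced genes.

Everything is deterministic given the master seed; per-gene streams are
keyed by (master seed, gene id) so any gene can be regenerated alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .silent_sites import BASES, FOURFOLD_PREFIXES, CodingAlignment, GeneRecord
from Bio.Data.CodonTable import standard_dna_table

SENSE_CODONS = sorted(standard_dna_table.forward_table)
AMP_ARMS = ("2L", "2R", "3R")  # the X harbors no AMPs


class LayoutError(ValueError):
    """Total gene footprint exceeds the chromosome length."""


@dataclass(frozen=True)
class SFSDistortion:
    """Multiplicative reweighting of the neutral 1/k spectrum.

    ``w_s`` multiplies the singleton class by (1 + w_s); ``w_b``
    multiplies the intermediate band k in [ceil(n/3), floor(2n/3)] by
    (1 + w_b).  Both zero gives the neutral spectrum.
    """

    w_s: float = 0.0
    w_b: float = 0.0

    def __post_init__(self):
        if self.w_s < 0 or self.w_b < 0:
            raise ValueError("distortion weights must be >= 0")

    def weights(self, n: int) -> np.ndarray:
        k = np.arange(1, n)
        w = 1.0 / k
        w[0] *= 1.0 + self.w_s
        lo, hi = int(np.ceil(n / 3)), int(np.floor(2 * n / 3))
        band = (k >= lo) & (k <= hi)
        w[band] *= 1.0 + self.w_b
        return w / w.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic population genome.

    Defaults are calibrated so that background genes show a strongly
    negative mean Tajima's D (around -0.9, the magnitude seen on fly
    autosomes) and balanced AMP genes an AMP-minus-control mean D
    difference near +0.3.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "2L": 1_200_000, "2R": 1_200_000, "3R": 1_200_000, "X": 400_000,
        }
    )
    genes_per_chromosome: dict[str, int] = field(
        default_factory=lambda: {"2L": 150, "2R": 150, "3R": 150, "X": 40}
    )
    cds_length_range: tuple[int, int] = (300, 1200)
    n_haplotypes: int = 20
    p_seg: float = 0.05
    w_s: float = 2.8
    w_b: float = 1.2
    p_seg_balanced_factor: float = 1.6
    amp_count: int = 35
    amp_cluster_size_range: tuple[int, int] = (3, 5)
    amp_cluster_spacing_bp: tuple[int, int] = (1_000, 4_000)
    immune_count: int = 40
    ambiguity_rate: float = 0.005
    high_ambiguity_fraction: float = 0.05
    b_slope: float = 0.02
    b_noise_sd: float = 0.002
    balanced_boost: float = 0.006
    b_amp_depression: float = 0.25
    intergenic_gap_bp: tuple[int, int] = (500, 3_000)
    seed: int = 0

    def __post_init__(self):
        if set(self.chromosome_lengths) != set(self.genes_per_chromosome):
            raise ValueError("chromosome name sets differ between lengths and counts")
        if any(v < 0 for v in self.genes_per_chromosome.values()):
            raise ValueError("gene counts must be >= 0")
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3 or lo <= 0 or hi < lo:
            raise ValueError("CDS length range must be positive multiples of 3")
        if self.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")
        if not 0 <= self.p_seg <= 1:
            raise ValueError("p_seg must be in [0,1]")
        if not 0 <= self.p_seg * self.p_seg_balanced_factor <= 1:
            raise ValueError("balanced p_seg outside [0,1]")
        if self.amp_count < 0 or self.immune_count < 0:
            raise ValueError("category counts must be >= 0")
        if not 0 <= self.ambiguity_rate <= 1 or not 0 <= self.high_ambiguity_fraction <= 1:
            raise ValueError("ambiguity rates must be in [0,1]")


@dataclass
class SyntheticDataset:
    """Layout, per-gene alignments, B landscape and the truth table."""

    layout: list[GeneRecord]
    alignments: dict[str, CodingAlignment]
    b_windows: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def __post_init__(self):
        ids = [g.gene_id for g in self.layout]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in layout")
        if set(ids) != set(self.alignments) or set(ids) != set(self.truth["gene_id"]):
            raise ValueError("gene id sets differ across dataset components")
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in self.layout:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for genes in by_chrom.values():
            genes = sorted(genes, key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                if b.start < a.end:
                    raise ValueError(f"genes {a.gene_id} and {b.gene_id} overlap")


def gene_rng(master_seed: int, gene_id: str) -> np.random.Generator:
    """Reproducible per-gene stream keyed by (master seed, gene id)."""
    return np.random.default_rng([master_seed, zlib.crc32(gene_id.encode())])


def simulate_gene_alignment(
    gene: GeneRecord,
    n: int,
    p_seg: float,
    distortion: SFSDistortion,
    seed_or_rng,
) -> CodingAlignment:
    """Simulate one gene's haplotype alignment at the SFS level.

    Non-degenerate positions are monomorphic; four-fold third positions
    segregate with probability ``p_seg``, the derived count drawn from
    the distorted spectrum and the derived base from the same codon
    family, so the protein is invariant across haplotypes.
    """
    if n < 4:
        raise ValueError("need n >= 4 haplotypes")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n_codons = gene.cds_length // 3
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    ref = "".join(codons)
    seqs = np.frombuffer(ref.encode(), dtype="S1").reshape(1, -1)
    seqs = np.repeat(seqs.copy(), n, axis=0)
    probs = distortion.weights(n)
    base_set = set(BASES)
    for ci, codon in enumerate(codons):
        if codon[:2] not in FOURFOLD_PREFIXES:
            continue
        if rng.random() >= p_seg:
            continue
        k = int(rng.choice(np.arange(1, n), p=probs))
        derived = rng.choice(sorted(base_set - {codon[2]}))
        carriers = rng.choice(n, size=k, replace=False)
        seqs[carriers, 3 * ci + 2] = derived.encode()
    labels = [f"hap{i:03d}" for i in range(n)]
    sequences = ["".join(row.astype(str)) for row in seqs]
    return CodingAlignment(gene.gene_id, labels, sequences)


def inject_missing_data(
    aln: CodingAlignment,
    per_base_rate: float,
    high_ambiguity_fraction: float,
    seed_or_rng,
    high_rate_range: tuple[float, float] = (0.26, 0.40),
) -> CodingAlignment:
    """Overwrite bases with 'N' to emulate ambiguous calls.

    Each haplotype is independently flagged high-ambiguity with the
    given fraction; flagged haplotypes receive Ns at a rate drawn from
    ``high_rate_range`` (above the 25% removal threshold), the rest at
    ``per_base_rate``.
    """
    if not 0 <= per_base_rate <= 1 or not 0 <= high_ambiguity_fraction <= 1:
        raise ValueError("rates must be in [0,1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = []
    for seq in aln.sequences:
        rate = per_base_rate
        if rng.random() < high_ambiguity_fraction:
            rate = rng.uniform(*high_rate_range)
        if rate > 0:
            chars = np.frombuffer(seq.encode(), dtype="S1").copy()
            chars[rng.random(len(chars)) < rate] = b"N"
            seq = chars.tobytes().decode()
        out.append(seq)
    result = CodingAlignment(aln.gene_id, list(aln.labels), out)
    result.has_internal_stop = aln.has_internal_stop
    return result


def _build_layout(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GeneRecord]:
    """Place non-overlapping single-exon genes; AMPs in tight clusters."""
    # distribute AMP clusters over the AMP-bearing arms
    lo_sz, hi_sz = config.amp_cluster_size_range
    cluster_sizes: list[int] = []
    remaining = config.amp_count
    while remaining > 0:
        size = int(min(remaining, rng.integers(lo_sz, hi_sz + 1)))
        cluster_sizes.append(size)
        remaining -= size
    arms = [a for a in AMP_ARMS if a in config.chromosome_lengths]
    if cluster_sizes and not arms:
        raise LayoutError("no AMP-bearing chromosome arm in configuration")
    cluster_arm = [arms[i % len(arms)] for i in range(len(cluster_sizes))]

    records: list[GeneRecord] = []
    gid = 0
    for chrom in sorted(config.chromosome_lengths):
        length = config.chromosome_lengths[chrom]
        n_genes = config.genes_per_chromosome[chrom]
        my_clusters = [
            s for s, a in zip(cluster_sizes, cluster_arm) if a == chrom
        ]
        n_amps = sum(my_clusters)
        if n_amps > n_genes:
            raise LayoutError(
                f"{chrom}: {n_amps} AMPs exceed {n_genes} genes on the arm"
            )
        # mark runs of consecutive gene slots as AMP clusters
        is_amp = np.zeros(n_genes, dtype=bool)
        free_starts = list(range(n_genes))
        for size in my_clusters:
            candidates = [
                s for s in free_starts
                if s + size <= n_genes and not is_amp[max(0, s - 1): s + size + 1].any()
            ]
            if not candidates:
                raise LayoutError(f"{chrom}: cannot place an AMP cluster of {size}")
            s = int(rng.choice(candidates))
            is_amp[s : s + size] = True
        pos = int(rng.integers(*config.intergenic_gap_bp))
        lo, hi = config.cds_length_range
        glo, ghi = config.intergenic_gap_bp
        slo, shi = config.amp_cluster_spacing_bp
        for i in range(n_genes):
            cds = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
            start, end = pos, pos + cds
            if end > length:
                raise LayoutError(
                    f"{chrom}: gene footprint exceeds chromosome length {length}"
                )
            records.append(GeneRecord(
                gene_id=f"g{gid:05d}",
                chromosome=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                cds_length=cds,
                category="AMP" if is_amp[i] else "background",
            ))
            gid += 1
            in_cluster = is_amp[i] and i + 1 < n_genes and is_amp[i + 1]
            gap = int(rng.integers(slo, shi + 1)) if in_cluster else int(rng.integers(glo, ghi + 1))
            pos = end + gap
    # immune labels on random non-AMP genes
    background = [i for i, r in enumerate(records) if r.category == "background"]
    if config.immune_count > len(background):
        raise LayoutError("immune gene count exceeds available background genes")
    immune_idx = rng.choice(background, size=config.immune_count, replace=False)
    for i in immune_idx:
        records[i] = replace(records[i], category="immune")
    return records


def simulate_b_landscape(
    layout: list[GeneRecord],
    chromosome_lengths: dict[str, int],
    slope: float,
    noise_sd: float,
    seed_or_rng,
    balanced_ids: set[str] | None = None,
    boost: float = 0.0,
    b_depression: float = 0.0,
) -> pd.DataFrame:
    """Tile 1,000-bp windows and assign B plus a linear polymorphism response.

    silent_polymorphism = slope * B + N(0, noise_sd) + boost on windows
    overlapping balanced genes; those windows may also have B depressed
    by ``b_depression`` (clipped to stay in (0, 1]) to emulate stronger
    linked purifying selection around the focal loci.  The boost applied
    per window is recorded in ``truth_boost``.
    """
    if not layout:
        raise ValueError("empty layout")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    balanced_ids = balanced_ids or set()
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in layout:
        if g.gene_id in balanced_ids:
            spans.setdefault(g.chromosome, []).append((g.start, g.end))
    frames = []
    for chrom in sorted(chromosome_lengths):
        n_win = chromosome_lengths[chrom] // 1_000
        starts = np.arange(n_win) * 1_000
        ends = starts + 1_000
        b = rng.uniform(0.2, 1.0, size=n_win)
        boosted = np.zeros(n_win, dtype=bool)
        for s, e in spans.get(chrom, []):
            boosted |= (starts < e) & (ends > s)
        b = np.where(boosted, np.clip(b - b_depression, 0.05, 1.0), b)
        poly = slope * b + rng.normal(0.0, noise_sd, size=n_win)
        poly = poly + np.where(boosted, boost, 0.0)
        frames.append(pd.DataFrame({
            "chromosome": chrom, "start": starts, "end": ends,
            "B": b, "silent_polymorphism": poly,
            "truth_boost": np.where(boosted, boost, 0.0),
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_genome(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset under the configuration.

    AMP genes are the balanced class (intermediate-frequency distortion
    ``w_b``); all other genes get the background singleton excess
    ``w_s``.  Deterministic given the master seed; per-gene streams are
    derived from (seed, gene id).
    """
    rng = np.random.default_rng([config.seed, 0xA3])
    layout = _build_layout(config, rng)
    # the singleton excess is demographic and genome-wide, so balanced
    # genes carry it too; the intermediate-frequency excess sits on top
    background = SFSDistortion(w_s=config.w_s)
    balanced = SFSDistortion(w_s=config.w_s, w_b=config.w_b)
    alignments: dict[str, CodingAlignment] = {}
    truth_rows = []
    for gene in layout:
        is_balanced = gene.category == "AMP"
        dist = balanced if is_balanced else background
        # balanced loci carry elevated diversity as well as a shifted
        # spectrum: more sites segregate around a balanced polymorphism
        p = config.p_seg * (config.p_seg_balanced_factor if is_balanced else 1.0)
        grng = gene_rng(config.seed, gene.gene_id)
        aln = simulate_gene_alignment(
            gene, config.n_haplotypes, p, dist, grng
        )
        aln = inject_missing_data(
            aln, config.ambiguity_rate, config.high_ambiguity_fraction, grng
        )
        alignments[gene.gene_id] = aln
        truth_rows.append({
            "gene_id": gene.gene_id,
            "balanced": is_balanced,
            "w_s": dist.w_s,
            "w_b": dist.w_b,
        })
    balanced_ids = {r["gene_id"] for r in truth_rows if r["balanced"]}
    b_windows = simulate_b_landscape(
        layout, config.chromosome_lengths,
        config.b_slope, config.b_noise_sd,
        np.random.default_rng([config.seed, 0xB5]),
        balanced_ids=balanced_ids,
        boost=config.balanced_boost,
        b_depression=config.b_amp_depression,
    )
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(layout, alignments, b_windows, truth, config)


# ---------------------------------------------------------------------------
# Writers: FASTA + GFF3 + TSV round-trip formats
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, list]:
    """Write the dataset as per-chromosome multi-FASTA, GFF3, and TSVs.

    Intergenic sequence is monomorphic random DNA; minus-strand genes
    are placed as the reverse complement of their coding sequence, so
    re-extraction round-trips through the readers.
    """
    from pathlib import Path

    from Bio.Seq import reverse_complement

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ds.config
    n = cfg.n_haplotypes
    paths: dict[str, list] = {"fasta": []}
    frng = np.random.default_rng([cfg.seed, 0xF111])
    for chrom in sorted(cfg.chromosome_lengths):
        length = cfg.chromosome_lengths[chrom]
        backbone = frng.choice(list("ACGT"), size=length)
        haps = np.repeat(backbone[None, :], n, axis=0).astype("U1")
        for gene in ds.layout:
            if gene.chromosome != chrom:
                continue
            aln = ds.alignments[gene.gene_id]
            for h, seq in enumerate(aln.sequences):
                placed = seq if gene.strand == "+" else reverse_complement(seq)
                haps[h, gene.start : gene.end] = list(placed)
        path = outdir / f"{chrom}.fasta"
        with open(path, "w") as fh:
            for h in range(n):
                fh.write(f">hap{h:03d}\n")
                fh.write("".join(haps[h]) + "\n")
        paths["fasta"].append(path)

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in ds.layout:
            base = (
                f"{gene.chromosome}\tampbalance\t{{}}\t{gene.start + 1}\t{gene.end}"
                f"\t.\t{gene.strand}\t{{}}\t{{}}\n"
            )
            fh.write(base.format("gene", ".", f"ID={gene.gene_id}"))
            fh.write(base.format(
                "CDS", "0", f"ID={gene.gene_id}.cds;Parent={gene.gene_id}"
            ))
    paths["gff3"] = [gff]

    cat = outdir / "categories.tsv"
    pd.DataFrame(
        [(g.gene_id, g.category) for g in ds.layout],
        columns=["gene_id", "category"],
    ).to_csv(cat, sep="\t", index=False)
    paths["categories"] = [cat]

    bpath = outdir / "b_windows.tsv"
    ds.b_windows.to_csv(bpath, sep="\t", index=False)
    paths["b_windows"] = [bpath]

    tpath = outdir / "truth.tsv"
    ds.truth.to_csv(tpath, sep="\t", index=False)
    paths["truth"] = [tpath]
    return paths
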