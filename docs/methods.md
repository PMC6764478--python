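# Methods

## Silent-site extraction

A site is *silent* when it is the third position of a codon whose four
third-position variants encode the same amino acid (the eight four-fold
families of the standard code: CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN).
Degeneracy is judged per haplotype from that haplotype's own codon, and
a column enters the analysis only if (a) at least `n_min = 4`
haplotypes carry an unambiguous, four-fold codon and (b) all qualifying
codons share the same first two bases.  Rule (b) excludes columns
mixing synonymous families (e.g. Leu TTR against CTN), where a
third-position change need not be synonymous; exclusion is the
conservative choice that guarantees every counted variant leaves the
protein untouched.  `n_min = 4` is the smallest sample size at which
Tajima's variance constants are meaningful.  Alignment gaps and all
IUPAC ambiguity codes count as missing.  Genes whose reference
haplotype contains an internal stop codon are flagged and excluded.
Coordinates are 0-based half-open internally; GFF3 is converted on
read.

## Statistics under missing data

Each silent column carries its own usable sample size *n_j*:

* π (per site) = mean over columns of the unbiased per-column
  heterozygosity (n_j/(n_j−1))(1 − Σ p²), identical to mismatching
  pairs / C(n_j, 2);
* θ_W (per site) = Σ_j 1(segregating_j)/a₁(n_j) / L, i.e. each
  segregating site corrected by its own harmonic number — the exact
  per-site correction;
* Tajima's D uses totals (not per-site values) and the 1989 variance
  constants evaluated at a single effective sample size
  n_eff = round(mean n_j); the variance formula requires one *n*, and
  the rounded mean is the simplest defensible rule.
* D is *undefined* (not zero) when S = 0 or n_eff < 4; undefined genes
  are excluded from D-based analyses and the exclusions logged.
* Multi-allelic columns count once in S; π uses the full
  heterozygosity over all four bases.

Reported per-gene values are per-site (diversity of order 10⁻³–10⁻²),
so control differences are on the scale familiar from fly population
data.

## Quality and scope filters

Haplotypes with strictly more than 25% ambiguous bases in a gene's
alignment are removed before extraction.  Lines can be filtered
genome-wide by completeness: a line passes a 1,000-bp window when ≥ 75%
of its sites are called, and is retained when its fraction of passing
windows reaches a configurable threshold (default 1.0 — the aggregation
rule is an open choice and is logged).  Coverage-based quality cuts
cannot be evaluated from FASTA input; an external coverage table can
stand in.  X-linked genes are always dropped (no AMPs reside there and
the X has a different effective population size); models and resampling
run on arms 2L, 2R and 3R.  Every filter appends (name, genes removed)
to a provenance ledger so input and output counts balance, and all
filters are idempotent.

## Matched control-gene resampling

Eligible controls for a focal gene: same chromosome arm, midpoint
within `window_bp` (default 100,000; midpoint-to-midpoint distance —
the boundary-distance variant is configurable), coding length ≤ 10×
the focal gene's, not in the focal category, statistic defined.  Per
replicate one control is drawn uniformly and independently per focal
gene; Δ̄ is the mean focal-minus-control difference over the focal
genes with non-empty candidate sets (a constant set within a run;
empty-set focal genes are dropped with a logged count).  Repeated
combinations across replicates are allowed.  The summary reports the
percentage of replicates with Δ̄ strictly > 0, the mean, and the sample
standard deviation.  The spaced variant redraws, per replicate, a
random subset of k = 10 AMPs with pairwise midpoint distance ≥ 5,000 bp
(randomized greedy with restarts), to prevent clustered AMP families
acting as pseudoreplicates.

The percentage of positive replicates is a descriptive bootstrap-style
quantity, not a calibrated p-value: for a fixed gene set the focal
values never vary, so the replicate distribution is centred on that
dataset's fixed mean offset and the percentage for a single dataset is
close to uniformly distributed under exchangeability.  Averaged over
independent datasets it is centred at 50%, which is how the null tests
assess it.

## Linear models

The nested model is Y = chromosome + gene length + chromosome/region +
chromosome/region/AMP.  Regions are either 200,000-bp tiles (anchored
at coordinate 0 of each arm) or AMP-centred neighbourhoods (the genes
within 100 kb and ≤ 10× the AMP's length; genes in several
neighbourhoods go to the nearest AMP; both modes are provided because
either reading of "region" is defensible, and the mode is a required,
logged parameter).  The AMP term is one indicator column per
AMP-containing region.  Term F tests use Type II sums of squares,
computed as nested-model residual-sum-of-squares comparisons against
the full-model mean square, with rank-aware degrees of freedom — sparse
nested AMP indicators routinely alias levels, which formula interfaces
reject outright; fully aliased terms raise a singular-design error.  A
constant response returns F = 0, P = 1 for all terms.  Genes with an
undefined statistic are dropped listwise per model.  No multiplicity
correction is applied across statistics or populations.

The background-selection model is Y = M1 + region/AMP, where M1 is the
gene's unweighted mean B over every 1,000-bp window it overlaps by at
least one base (a length-weighted variant exists).  Window silent
polymorphism is regressed on B by ordinary least squares; residuals
(observed minus expected polymorphism given linked purifying selection)
are averaged per gene and fed to the control resampling unchanged.

## Synthetic data generator

The generator works at the site-frequency-spectrum level rather than
through a coalescent: derived-allele counts are assigned directly, which
gives exact control over the quantities the analyses measure.  For each
gene, a random sense-codon CDS is drawn; each four-fold third position
segregates with probability `p_seg` (default 0.05, giving per-site
silent θ_W ≈ 0.014 at n = 20 — the upper range observed in fly
populations); the derived count k ∈ {1..n−1} follows p(k) ∝ 1/k
reweighted multiplicatively: the singleton class by (1 + w_s) and the
intermediate band k ∈ [⌈n/3⌉, ⌊2n/3⌋] by (1 + w_b), then renormalised.
The derived base stays inside the codon family, so every haplotype
translates identically.

The singleton excess emulates population expansion and is genome-wide,
so balanced genes carry it too, with the intermediate-frequency excess
applied on top — assigning balanced genes a purely neutral-plus-w_b
spectrum would make them differ from the background by the full
demographic effect, which is not the biology being modelled.  Balanced
loci additionally segregate at `p_seg × p_seg_balanced_factor` (default
1.6): a balanced polymorphism elevates linked diversity, and a pure
shape distortion would leave θ_W untouched.

Default conditions: arms 2L/2R/3R of 1.2 Mb with 150 genes each plus a
0.4-Mb X with 40 genes; CDS lengths uniform in 300–1,200 bp (multiples
of 3); n = 20 haplotypes; 35 AMPs placed in clusters of 3–5 genes with
1–4 kb within-cluster spacing on the three arms; 40 immune-labelled
genes; 0.5% ambiguity per base with 5% of haplotypes pushed above the
25% removal threshold (rate drawn in 26–40%).  `w_s = 2.8` puts the
background mean Tajima's D near −0.87 and `w_b = 1.2` puts the
AMP-minus-control mean D difference near +0.3, the magnitudes seen in
ancestral African fly populations; both were fixed once by simulation
and are configuration, not fitted values.

The B landscape tiles each arm with 1,000-bp windows, draws
B ~ U(0.2, 1], and sets window silent polymorphism = slope·B + Gaussian
noise, plus an additive boost (default 0.006) on windows overlapping
balanced genes, whose B is also depressed by 0.25 (clipped to stay
positive) to emulate stronger linked purifying selection around immune
loci.  The truth boost per window is recorded.

What the generator does *not* emulate: linkage disequilibrium and
recombination (sites are independent), indels, selection on
nonsynonymous sites, gene conversion, and any coupling between the
sequence-level statistics and the B landscape beyond gene identity.
Passing tests therefore demonstrate that the statistics, resampling and
models behave correctly on data with the intended marginal structure —
not that the test is robust to LD or to misspecified B.

Randomness: a single master seed; per-gene streams are keyed by
(master seed, CRC32(gene id)), so any gene regenerates independently;
the layout and landscape use fixed offsets of the master seed.  Same
configuration and seed give byte-identical outputs.

## Problem sizes

The test-suite and acceptance-script simulations use the default genome
(490 genes, n = 20, ≈ 3 s to simulate and analyse), a 24-dataset
ensemble of 630-gene exchangeable genomes for null calibration, and a
5-dataset ensemble for balancing recovery.  Ensembles are used wherever
the assessed quantity (percentage of positive replicates) is itself a
random draw per dataset — see the resampling note above.  10,000
replicates are used for every reported resampling distribution.

## Known limitations

* n_eff rounding makes D slightly discontinuous in the missing-data
  pattern; genes dominated by columns of very different n_j are
  summarised by a compromise variance.
* The candidate-control rule measures midpoint distance, so very long
  genes can be eligible while their boundaries lie outside the window.
* Overlapping genes on opposite strands are both retained (no
  de-duplication rule is applied).
* The percentage-positive summary is descriptive; it is not corrected
  for multiple statistics or populations.
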