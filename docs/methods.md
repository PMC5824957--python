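# Methods

## Study design being modeled

A clonal population expanded from a single somatic stem cell reads out
that founder cell's genome: every in-vivo somatic mutation of the founder
is heterozygous in all descendant cells (VAF ≈ 0.5 in the clone's bulk
DNA), absent from the donor's blood; germline variants sit at VAF ≈ 0.5
in both clone and blood; and mutations acquired *during* the expansion
are confined to a sub-lineage. Under a synchronous neutral binary
expansion, a mutation arising in one daughter at division *k* ≥ 1 is
carried by a cell fraction 2⁻ᵏ and hence sampled at VAF 2⁻⁽ᵏ⁺¹⁾ — at most
0.25, for a first-division event. The discovery filter exploits exactly
this separation.

## Synthetic-data generator

`simulate.SimConfig` fixes the study conditions; the defaults are the
emulated design: 7 donors (ages 21, 22, 24, 64, 67, 71, 78 — three young,
four old) contributing (4, 4, 5, 4, 4, 4, 4) = 29 clones; in-vivo SNV
counts Poisson-distributed around `intercept + 13.1 × age` plus a
donor-level Gaussian effect (SD 50 mutations, truncated at zero),
mirroring the mixed-model structure fitted downstream; indel fraction
0.06 (observed indel/SNV burden ratios are in the 5–8% range); mean
sequencing depth 30× (Poisson per site and sample, binomial alt reads at
the true VAF, binomial 50:50 strand split); culture variants with
division-of-origin k ∼ 1 + Geometric(0.5); caller sensitivity 1 by
default (drop-out is a stress parameter, not a baseline condition);
blood contamination by clone-lineage cells 0 by default (not stated in
the emulated design; configurable). Trinucleotide contexts of in-vivo
SNVs are drawn from a three-profile generative mixture (a CpG-focused
C>T deamination-like process, a flat clock-like process, and a
C>A-dominated process) and placed at genome positions whose
pyrimidine-collapsed context matches, so spectra are internally
consistent with the reference sequence. A clone's true variants are
deduplicated by site.

What the generator does **not** emulate: mapping artifacts, sequencing
error profiles, copy-number variation, clustered mutations
(kataegis), context-dependent coverage, or realistic gene structure
(genes are uniform toy models). Tests passing on this generator
demonstrate the statistical machinery — filter calibration against the
binomial read-sampling model, FNR recovery, signature identifiability,
estimator coverage — not robustness to those real-data artifacts.

## Discovery filter and FNR

Candidates are the union of per-caller callsets, pooled per individual
into a comprehensive position list. A candidate is accepted iff: clone
VAF in the closed window [0.4, 0.6] (closed, so a depth-20 het with
exactly 8 alt reads passes); blood VAF strictly < 0.1; depth ≥ 15 in
both clone and blood; ≤ 1000 in the clone; ≥ 1 alt read on each strand;
autosomal; outside the blacklist; and not observed in more than one
individual (keyed on chrom, pos, ref, alt). Rejected candidates record
the *first* failing criterion, in the order the criteria are listed
above, making rejection tallies a partition of the rejected set. Indels
pass through the same criteria as SNVs.

The FNR is estimated from control sites: germline heterozygotes pass
when detected by ≥ 1 caller with clone VAF in the somatic window;
germline homozygotes pass when their blood minor-allele fraction is
below the blood ceiling. The positive prediction rate is the pooled
fraction of passing controls over both sets (the exact weighting of the
two components is a genuinely open detail; pooling is the simplest
symmetric choice, and both component rates are reported separately).
Burden correction divides by (1 − FNR) and floors.

## Signatures

Spectra use the canonical 96-class order (six pyrimidine substitution
classes × 4 × 4 flanks), with purine-reference variants
reverse-complemented. De novo extraction minimizes generalized KL
divergence by multiplicative updates — the canonical formulation for
mutation-signature NMF — with 20 random restarts by default, keeping the
best objective; profiles are column-normalized with scale moved into the
contributions. The packaged reference panel
(`data/reference_signatures_synthetic.tsv`) is a **synthetic** 96 × 30
matrix in the layout of the COSMIC v2 signature table, generated
deterministically by `scripts/make_reference_signatures.py`; it is not
the published COSMIC data, which this package does not redistribute.
Refitting is non-negative least squares; relative contributions divide
by the clone's total reconstructed mutations. Clustering row-normalizes
contributions per clone (row-sum; z-scaling available via a flag —
"per-clone normalization" is ambiguous and row-sum is the convention for
compositional signature data), projects onto the first three principal
components, and runs k-means (k = 2) from many random initializations
(100,000 by default, configurable down for tests), keeping the lowest
within-cluster sum of squares. Cluster labels follow a stable
convention: cluster 0 is the larger cluster, ties broken by the
smallest member clone id.

## Regional burden

Coordinates are 0-based half-open internally, converted at the VCF
boundary. Annotation uses a fixed precedence (exon > 3′UTR > 5′UTR >
splice region > regulatory > intron > upstream > downstream > non-coding
exon > intergenic) with 5 kb up/downstream flanks matching the extended
gene region definition (exons + introns + 5 kb flanks), and an 8 bp
intronic splice-region margin. The enrichment test compares the observed
count in a region set to `total × surveyed_length / callable_length`
(uniform mutation opportunity — deliberately no trinucleotide-composition
adjustment, matching the construction of the test it mirrors) with a
one-sided exact binomial p-value; direction follows the observed
deviation by default and can be fixed by flag. Fixed-direction p-values
are uniform under the null; direction-conditioned p-values are not,
by construction — the calibration test therefore uses the fixed
depletion direction.

CAGE-defined expressed regions: enhancers require score ≥ 1 in ≥ 1 of 3
replicates and are padded ±100 bp; promoters require score ≥ 30 and take
a strand-aware window of 860 bp upstream / 100 bp downstream (a missing
promoter strand is an error, since the window is undefined); exon sets
contain all exons of genes owning an expressed promoter. "Basal" means
expressed at day 0; "upon differentiation" is the union over all
timepoints minus the day-0 set, so the two are disjoint by construction.
Where promoter and enhancer intervals overlap, the promoter wins (a
deterministic rule replacing per-case manual curation).

The disease-gene null draws, with replacement and probability
proportional to exon length, as many exons as there are gene-annotated
mutations, counts draws landing in the disease set, and repeats 10⁴
times (10⁵ in validation tests); the observed count is summarized as a
Z-score against the null mean/SD and an upper-tail empirical p.
Sampling *with* replacement is an explicit choice — the described
procedure does not pin down the replacement policy, and with-replacement
makes the null exactly binomial, enabling closed-form validation.

## Aging inference

The rate fit is a linear mixed model — response: per-clone mutation
count (optionally normalized by callable autosome fraction and/or
FNR-corrected; uncorrected raw counts are the default, matching how
burdens are conventionally plotted); fixed effect: age; random
intercept: donor — made robust by iterative Huber winsorization
(c = 1.345) of the working response. Residuals are computed against the
fixed-effect fit, *not* the BLUP-adjusted fit, so an aberrant clone
cannot hide inside its donor's random intercept. Two variance options
are provided. The model-based SE carries the M-estimation consistency
correction 1/E[ψ′]. The default, however, is a leave-one-donor-out
jackknife SE: with only ~7 donors the model-based SE understates
between-donor sampling variance (a standard few-clusters phenomenon),
while the jackknife attains ≈ 94% empirical coverage for ±2 SE intervals
in simulation at the default study conditions. P-values use a
t-reference with (donors − 1) degrees of freedom. Degenerate designs
(single donor, non-convergence) fall back to a Huber M-estimator without
donor structure, with a warning; per-signature age trends reuse the same
fit with Bonferroni correction for the three signatures examined.

The proliferation threshold takes the young clones' days-in-culture band
(mean ± sample SD; population SD selectable), fits ordinary least
squares of days on mutation count over old clones (the relationship is
displayed as a plain linear regression, and clones are unweighted across
donors), and intersects the regression with the band's upper edge;
raw (uncorrected) mutation counts are used. A non-positive old-clone
slope leaves the threshold undefined. Deleteriousness aggregation sums
PHRED-scaled per-variant scores over the chosen scope per clone;
unscored variants are excluded and counted. Allele→cell fraction is
`min(1, 2 × VAF)` under the heterozygous-per-cell assumption.

## Numerical and scale choices

NMF: restarts share one seeded generator; convergence at relative
objective change < 1e-9 or 2000 iterations; epsilon 1e-12 guards
divisions. NNLS via the Lawson–Hanson solver. Simulated genomes in tests
and the acceptance script are 20 kb–1 Mb with counts tied to age rather
than genome length, so burden statistics match the emulated design at
desk scale; the acceptance script averages the recovered slope over 20
replicate cohorts (Monte Carlo SE ≈ 0.17 SNVs/yr). Seeds derive from a
single configured seed via deterministic streams keyed by stage and
donor, making the full pipeline report bit-reproducible.

## Known limitations

The filter's acceptance probability at 30× (~0.75 for a true VAF-0.5
variant) attenuates observed burdens and hence uncorrected slopes; this
is inherent to the design and is why the FNR correction exists. The FNR
estimated on synthetic data reflects binomial sampling only and is lower
than values seen with real callers. The annotator is an interval
classifier, not a transcript-aware effect predictor (no frame-aware UTR
inference, no splice-donor/acceptor distinction). The NS/S classifier
assumes single-transcript gene models with clean CDS frames. The
enrichment model ignores mutational opportunity heterogeneity
(trinucleotide composition, replication timing). Threshold derivation
assumes the young band and old regression are on comparable
days-in-culture scales.
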