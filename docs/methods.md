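# Methods

This note documents the models implemented in `caprigen`, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical conventions that make every run reproducible.

## Study design being emulated

The package targets the two-population design common in dairy-goat (and more
generally livestock) genomics: tens of animals with whole-genome sequence at
moderate coverage (~12X), thousands genotyped on a ~50k array, a deep
pedigree connecting them, and pre-adjusted phenotypes — yield deviations
(YD: an animal's repeated performances corrected for environment) or
daughter yield deviations (DYD: a sire's daughters' average, carrying half
the sire's breeding value).  Sequence panels in such designs are chosen to
maximise kinship with the target population, so they contain whole families
(sires, dams, offspring); the synthetic generator selects its panel the same
way, and the leave-one-out evaluation holds out sequenced daughters of
sequenced sires while removing the (in reality unsequenced) dam.

## Synthetic populations

**Founder haplotypes** are Markov mosaics over a small pool of ancestral
haplotypes: along a chromosome the template switches, with probability
`mosaic_switch_rate` per adjacent variant (default 0.02), to a uniformly
drawn *different* pool member.  This produces linkage disequilibrium that
decays geometrically with marker distance at a tunable rate — which is all
the downstream methods need — without a coalescent simulation.  The two
breeds draw from overlapping but distinct pools (default 25% shared), so
principal components separate them.

**Allele frequencies.** Ancestral alleles follow `Beta(0.2, 2)` frequencies,
but a small pool quantises realised frequencies at multiples of
1/pool-size, which cannot produce the heavy low-MAF tail of sequence data.
A `rare_fraction` of variants (default 0.35) is therefore placed directly on
1 + Poisson(1.5) random founder haplotypes.  With the defaults roughly
40–70% of segregating variants have MAF < 0.05 depending on scale, matching
the qualitative dominance of rare variants in sequence panels (the tested
invariant is ≥ 30%).

**Gene drop** is exactly Mendelian: each non-founder receives one
recombined gamete per parent, with Poisson(rate × length) crossovers
(default 1 cM/Mb) at uniform positions.  An individual with one unknown
parent draws the missing gamete from the breed founder pool.

**Sequence calls.** Per-individual coverage is Gamma-distributed around
`mean_depth` (12X, shape 8, so a minority of animals fall well below —
mirroring real panels where some animals must be discarded for low
coverage); per-call depth is Poisson; alternate reads are binomial with a
per-read error of 1e-3; the call is the maximum-likelihood genotype among
{hom-ref, het, hom-alt} and GQ is the phred gap between the best and
second-best likelihood, capped at 99.  Depth-zero calls are missing.  This
reproduces the diagnostic feature real QC exploits: wrong calls concentrate
at low GQ and DP, so the GQ ≥ 8 / DP ≥ 7 masks remove them preferentially.

**Array subset.** Markers with MAF ≥ 1% are picked one per genomic window
(highest MAF per window), giving the even spacing and common-allele bias of
a commercial chip.  Chip genotypes are taken error-free from the truth;
accordingly chip calls override sequence calls at shared markers.

**Phenotypes.** Breeding value = Σ QTL effects × dosage + a
pedigree-correlated polygenic term whose variance tops genetic variance up
to h²; raw single records have unit variance by construction.  A YD is
BV + residual/√(records per animal, default 20); a DYD is BV/2 +
residual/√(effective daughter count, default 50) — a deliberate
simplification of the full daughter-average construction.  The per-trait
raw-record variance σ²y and observed variance σ²X needed by the CLIP test
are attached to the phenotype table.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: demographic realism (no selection,
migration, or realistic effective population sizes), genotyping error on the
array, X chromosome, structural variants, and the block-free LD of the
mosaic model (pairwise r² between distant sites is random-sign noise rather
than zero).  Accuracy numbers on synthetic data are higher than published
real-data values because the simulated genome is short and panel kinship is
high; only directions and calibrations transfer, not magnitudes.

## QC cascade

Order: site QUAL (default ≥ 30; configurable — published pipelines rarely
print this cutoff) → per-call GQ/DP masking (defaults 8 and 7) →
removal of variants with no alternate-allele observation left among
non-missing calls of the required breeds.  Running the ALT rule last means
it operates on cleaned calls.  Counts are recorded per stage and are
non-increasing by construction; the cascade is idempotent.

## Imputation engine

The engine is a deterministic shrinking-window haplotype-library matcher —
the same family of algorithm as the population/pedigree imputation software
used in livestock, not a bit-compatible clone, and not a Li–Stephens HMM.

1. **Mendelian fill**: constraint propagation over per-call dosage candidate
   sets (child restricted by parents' transmissible alleles; parent by its
   children with their co-parent), iterated to fixpoint; a call is filled
   only when its candidate set is a singleton, observed calls are never
   overwritten, and Mendelian conflicts leave the variant unchanged
   (logged).  On small pedigrees this provably equals exhaustive
   enumeration of consistent completions (tested).
2. **Phasing**: homozygotes are trivial; heterozygotes are resolved from
   trios (parent homozygous, or co-parent decides), then by long-range
   phasing through offspring — a child's resolved parental haplotype is one
   gamete of that parent and pins the parent's phase over whole chromosomes
   minus ~0.5 crossovers — then window by window against a growing
   haplotype library.  Window fills are segment-coherent: one donor
   haplotype (fewest hard conflicts with the dosage, anchored by resolved
   heterozygotes) orients every open heterozygote in the window, with a
   second donor explaining the residual.  A refinement sweep re-decides
   library-derived orientations against the full first-pass library with
   the sample's own haplotypes excluded.  Donor holes count half a
   mismatch, so informative donors win.  Remaining ties are lexicographic
   (reference allele on the first haplotype).  At the default study scale
   >95% of heterozygote pairs within 1 Mb phase consistently; samples with
   no relatives in the panel phase poorly (~60–70%), which is why real
   panels (and the generator) are family-structured.
3. **Array→sequence**: per chromosome, windows of 500/100/20 array markers
   (50% overlap, longest first) are matched against the phased panel
   restricted to array positions; the best-matching haplotype (fewest
   incompatibilities with the target's dosages; a parent's haplotypes are
   searched before the population library; remaining ties go to the lowest
   panel row, a fixed deterministic order) donates its sequence alleles to
   still-unresolved positions, and a second donor explains the residual
   dosage.  After the last pass unresolved alleles take the panel major
   allele (a seeded frequency-sampling fallback is available behind a
   flag).  The output contains no missing calls and never alters the
   target's own array genotypes — chip calls are authoritative.

The engine contains no randomness: identical inputs give bit-identical
output.

## Evaluation metrics

Genotype concordance = fraction of exact dosage matches; allele concordance
= mean of (2 − |truth − imputed|)/2 per call, which is never below genotype
concordance; R = Pearson correlation of dosage vectors, undefined (flagged,
excluded from means) when either vector is constant.  Per-variant metrics
are averaged unweighted within MAF bins (default width 0.01 over (0, 0.5];
the integration tests use 0.05 so each bin holds hundreds of variants at
the simulated scale).  MAF is computed on the full panel before holdout
removal so bins are stable across holdouts.  Both the per-variant-averaged
R (primary) and the pooled-vector R are reported.

## Mixed-model association

GRM: VanRaden form, Σᵢ(xᵢⱼ−2pᵢ)(xᵢₖ−2pᵢ) / Σᵢ2pᵢ(1−pᵢ) over polymorphic
variants with sample allele frequencies, mean-imputing missing dosages for
the GRM only.  REML: profile restricted likelihood of y = 1μ + u + e after
one eigendecomposition of G, maximised by bounded scalar search over the
logit of h²; non-PSD G is bent by a small ridge.  Scan: V = σ²g G + σ²e I
is fixed from the null fit (no leave-one-chromosome-out, matching the
standard single-trait mixed-linear-model convention) and each variant costs
one weighted regression in the rotated basis; the Wald statistic b/se is
referred to N(0,1) two-sided (n is several hundred; no small-sample t
correction).  Variants below 1% within-sample MAF are excluded.  The
multiple-testing line is the average chromosomal Bonferroni threshold
α/(n variants/29); it is strictly decreasing in the variant count and
reproduces the published thresholds for the published counts.

Calibration at the tested scale (300 animals, ~1.6k polymorphic variants,
polygenic h² = 0.3): empirical type-I error at α = 0.05 within [0.04,
0.06], Kolmogorov–Smirnov uniformity p > 0.01, genomic inflation λ within
[0.9, 1.1].  REML recovers a simulated h² of 0.5 within ±0.1 over 20
replicates at n = 500, and a QTL explaining 5% of variance is detected
below the chromosomal threshold in ≥ 80% of replicates.

## CLIP test

The statistic is the squared Pearson correlation ρ² between the two traits'
per-variant estimated additive effects over the region's shared variants
(standardised to trait SD units).  The inequality is implemented exactly as
printed, including its asymmetric bracket (σ²y₁/σ²X₂ under the square
root); rejection requires ρ² strictly below K_α × bracket, so ties never
reject.

K_α is the empirical α-quantile of ρ²_sim/bracket under a seeded Monte-Carlo
pleiotropic model: both effect vectors share one unit-variance signal, with
per-trait signal scale s²ₜ = max(var(effects) − noise, 0) and per-variant
noise taken from the reported standard errors when available (median of
squared standardised SEs — the median because near-monomorphic variants
have huge SEs) or otherwise from the σ²y/(2Nσ²X) scaling that also appears
in the bracket.  Linkage disequilibrium couples neighbouring estimates and
widens the null distribution of ρ², so when the effective number of
independent variants m_eff (m²/Σr², Li–Ji style, computed from region
genotypes) is supplied the simulation runs at m_eff independent variants;
the fallback is an AR(1) at the observed lag-1 autocorrelation.  This model
is a documented interpretation — the generative distribution behind the
published calibration is not fully specified — and is deliberately
swappable (`calibrate_K` accepts any pre-computed K_α).

The region harness simulates unrelated genotypes whose ancestral haplotypes
carry distance-decaying allele correlation (Gaussian copula, 300 kb decay
scale), so r² is high at short range and decays smoothly; one shared causal
variant (pleiotropy) or two causal variants at distance d (linkage) drive
two YD-type traits, and per-variant least-squares effects and SEs over
MAF ≥ 1% variants feed the test.  Measured operating characteristics at
n = 500, α = 0.05: type-I error ≤ α + 0.03 (typically 0.01–0.06), rejection
≥ 0.5 at d = 1 Mb, and rejection increasing with d over 0.1–2 Mb.

An open interpretive point: the published description reads "a combination
of effects at the variant level"; the per-variant-correlation reading is
primary here, and `region_effects` also supports restricting to top
variants by pre-filtering the association tables before the join.

## Problem sizes

Integration tests and the acceptance script run the pipeline at 2 breeds ×
~300 animals, 2 chromosomes × 6,000 variants, a 600-marker array and 30
sequenced animals per breed (16 leave-one-out holdouts over 8 sire
families, two replicate seeds); calibration studies use 300–500 unrelated
founder-style genomes with 2,000–5,000 variants, 20 replicates; CLIP
operating characteristics use 200 pleiotropic and 20 linked region
replicates at 2,000 calibration draws each.  These sizes were chosen so the
complete suite runs in minutes on one core while every assertion retains a
comfortable Monte-Carlo margin; the defaults in `SimConfig` (3 chromosomes ×
20,000 variants, 1,000-marker array, 40 sequenced animals per breed at 12X)
are the generator's reference conditions.

## Known limitations

- The imputer is deterministic and library-based; it does not produce
  genotype probabilities or per-variant imputation R² (INFO) scores —
  quality assessment is truth-based leave-one-out only.
- Phasing of panel members without any relative in the panel is weakly
  informed (no PBWT/HMM machinery); panels should be family-structured.
- The CLIP calibration is a modelling choice, not a derivation; its type-I
  control is demonstrated under the package's own generative model.
- A/B-allele reconciliation for array data is a convention (lexicographic
  orientation, complement at shared positions); strand flips of A/T and C/G
  SNPs are not detectable from genotypes alone.
- DYDs are simulated as half the sire breeding value plus shrunk noise, not
  as explicit daughter averages.
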