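# Methods

This note documents the statistical procedures, the synthetic-data model, the
numerical choices, and the known limitations of `growthgwas`.

## Phenotype model and BLUEs

Observations are long-format rows (genotype, experiment, carrier, day,
timestamp, trait, value, check flag, position code). Outlier cleaning removes,
within each (experiment, day, trait) stratum, values outside the closed
interval median ± 3 sample SD; strata with fewer than 3 observations are left
untouched. Manual exclusions (e.g. carriers with germination failures) are
applied before the threshold rule.

BLUEs are estimated per trait and day from a linear mixed model with genotype
fixed and, for image traits, random experiment (E), genotype×experiment
(GxE), check identity (C) and check×experiment (CxE) terms; end-point biomass
adds pot position (P) and P×E. Check lines enter both the fixed genotype
factor and the random check terms, whose design columns are zero for
non-check rows. Variance components are estimated by REML (statsmodels
`MixedLM` with variance components on a single grouping level); REML rather
than ML because BLUE/heritability workflows conventionally use it and it
removes the fixed-effect degrees-of-freedom bias. The BLUE is the estimated
marginal genotype mean (the coefficient of the genotype's indicator in the
no-intercept parameterisation), so values are comparable across days.

Degenerate designs are handled structurally rather than numerically: a random
term is dropped when it has fewer than two levels, when every level carries at
most one observation (confounded with the residual), or — for interaction
terms with experiment — when only one experiment is present. If no random
term survives, the model *is* ordinary least squares and the BLUE is the
genotype mean. Numerical failure or non-convergence falls back to genotype
means with a diagnostic flag. Genotypes observed in a single experiment are
estimable (fixed effect, no shrinkage) and flagged.

Broad-sense heritability refits the same model with genotype random and
computes H² = σ²_G/(σ²_G + σ²_e/n₀), n₀ being the number of experiments for
image traits and the number of plant replicates per genotype for end-point
biomass. A genotypic variance estimated at the zero boundary yields H² = 0
with a flag.

## Growth rates

RGR = (ln W₂ − ln W₁)/(t₂ − t₁) and ACR = (W₂ − W₁)/(t₂ − t₁) with the time
difference computed from the imaging timestamps in days at minute resolution,
which removes the bias of the daily imaging-order rotation. Records with a
non-positive endpoint under RGR are skipped and logged. Rate windows default
to non-overlapping spans of three measured days anchored at measured days;
the window list is fully configurable because no single sliding or
non-overlapping rule reproduces every published interval scheme from a
21-day design with one unmeasured day. Rate tables are themselves long-format
series (trait `<name>_RGR`/`<name>_ACR`, label `"d1-d2"`) and go through the
same BLUE machinery with the image-trait model.

## Association scans

The scan is a documented simplified variant of the iterative
fixed/random pseudo-QTN family of methods, anchored by an exact equivalence:
with a single iteration (or no eligible pseudo-QTNs) it *is* the
covariate-adjusted per-marker OLS t-test, verified against an independent
least-squares oracle to < 1e-8 in log10 P.

Per iteration: (1) every marker is tested by OLS of the BLUEs on its dosage
plus an intercept, the first 4 genotype principal components, and the current
pseudo-QTN dosages — computed once for all markers via the
Frisch–Waugh–Lovell projection; a pseudo-QTN is re-tested without itself in
the covariate set; (2) markers with P below the eligibility threshold
(default 1e-5) are deduplicated per genomic bin (best P per bin), with the
bin size chosen among {0.5, 5, 50} Mb by maximising the restricted likelihood
of y ~ covariates + u, u ~ N(0, σ² K), where K is the cross-product
similarity of the centred candidate dosages (profiled over the variance
ratio by bounded scalar optimisation on the log scale, eigendecomposition of
K reused across evaluations); (3) iterate until the pseudo-QTN set is
unchanged or 100 loops. Final statistics come from the last fixed-effects
scan, so the loop cap bounds the number of scans exactly. The procedure has
no random initialisation and is deterministic given its inputs.

Zero-variance markers (e.g. fully missing before imputation) are excluded
from testing with missing P. Missing dosages are imputed to the heterozygous
code 1 for scanning only; QC statistics always use pre-imputation data.
P-values are BH-adjusted within each trait × time-label scan (not pooled
across days, since per-day association counts are the object of interest);
significance uses adjusted P ≤ 0.1 — the inclusive comparison, so a value
exactly at the level counts.

PVE% per significant marker is the sequential (type-I) sum of squares from a
single linear model with significant-marker dosages entered in decreasing
raw-P order; the denominator is the total SS around the intercept (= Σ marker
SS + residual SS), so ΣPVE% ≤ 100 holds by construction. Collinear markers
receive only their incremental contribution (≈ 0) and are flagged. Entry
order matters for correlated markers — by design of sequential ANOVA.

## Dynamic QTL

Consecutiveness is evaluated on the ordered list of *measured* time labels: a
marker is retained if significant at ≥ k successive entries (k = 3 for
time-point traits, 2 for rate intervals). Unmeasured days are not in the
list, so days 13 and 15 are adjacent across the day-14 gap; a label with no
scan is dropped from the chain with a warning. Effect trajectories use the
plain covariate-adjusted single-marker model at every label — never the
iterative scan, whose covariate set varies per scan and would make effects
incomparable across days. A reversal requires two labels with opposite-signed
effects each exceeding 1 standard error in magnitude; the guard (configurable)
avoids flagging sign flips of near-zero estimates, at the cost of flagging
some noisy flat trajectories when residual noise is very small.

## LD and candidate intervals

r² is the squared Pearson correlation of dosage vectors over genotypes
non-missing at both markers (composite LD on unphased dosages; invariant to
allele-coding flips). Decay is fitted per subgenome by nonlinear least
squares of the Hill–Weir expectation

E[r²] = (10+C)/((2+C)(11+C)) · [1 + (3+C)(12+12C+C²)/(n(2+C)(11+C))],

C = ρ·distance, n = number of genotypes, pairs pooled over the subgenome's
chromosomes up to a 25-Mb cap; ρ is optimised on the log scale. The
half-decay distance solves fitted r²(d) = r²(0)/2 by bracketing. On fit
failure the empirical binned decay is reported with a warning.

The candidate interval around a focal marker is the maximal contiguous
marker run containing it in which every member has r² ≥ 0.6 *to the focal
marker* (not adjacent-pair r², matching how published block figures describe
the block as the focal marker plus correlated neighbours). The inclusive
threshold (≥, configurable) is used. A block with ≥ 2 members is extended to
the positions of the nearest markers immediately outside it on each side;
without a block, the interval is focal ± 100 kb clamped at 1 bp. At a
chromosome end with no outside marker, the interval is truncated at the
outermost block member ± the flank. Interval size is stop − start (the
convention that reproduces published interval arithmetic exactly). Genes
overlap by ≥ 1 bp, 1-based inclusive on both sides.

## Synthetic data

The generator emulates the study design the pipeline targets, not its scale:
477 genotypes in 3 admixed breeding pools genotyped at ~16k markers become,
by default, 400 genotypes × 2,000 markers (1,800 SNP + 200 CNV, the CNVs
almost all deletions) on 19 chromosomes (A01–A10 at 25 Mb, C01–C09 at
45 Mb), 21 measured days (6–13, 15–27; day 14 structurally absent), 3
experiments with 2 replicated check lines, and end-point fresh/dry weight.

*Genotypes.* Pool allele frequencies follow a Balding–Nichols model
(divergence 0.15) around common ancestral frequencies; each genotype draws
admixture proportions from a Dirichlet concentrated on its home pool
(admixture_alpha = 0.3; smaller = purer pools). Haplotypes are stationary
Gaussian AR processes along each chromosome with correlation exp(−ρ·d),
thresholded at the genotype's admixed frequency — monotone LD decay without
coalescent machinery. ρ defaults to ln2/(2·half-decay) with half-decays of
400 kb (A) and 3.9 Mb (C), the reported subgenome contrast for this crop;
the *fitted* Hill–Weir half-decays on simulated panels come out shorter than
these latent targets because admixture adds a distance-independent r²
baseline, but the ~10× A:C ratio — the feature the analyses depend on — is
preserved. 95% of genotypes are fully homozygous lines (two copies of one
haplotype), matching breeding material and keeping heterozygosity below the
QC threshold. CNV markers emit deletion/duplication calls (reciprocal events
at rate 0.01, which the encoder turns into missing values); 2% of all calls
are missing.

*Phenotypes.* Biovolume and leaf area grow exponentially (all effects and
Gaussian residuals on the log scale — an assumption of this generator,
configurable), plant height linearly, colour uniformity is flat and noisy.
Each observation = growth-law mean at the exact imaging time + genotype
genetic value + experiment + genotype×experiment + check effect + position
effect + residual. Genetic values are a polygenic genotype effect plus the
planted QTL: each QTL has a marker, an active day window, and an effect that
is constant, day-dependent, or sign-switching at a reversal day; when only a
target variance fraction f is given, the effect is back-computed as
b = sqrt(f/(1−f) · V/var(x)) with V the genotype-mean phenotypic variance,
so the realised explained fraction matches the target (±20% at n ≥ 300).
Imaging timestamps are minute-precise with a per-day stagger, so rate
denominators are never whole days. Fresh weight is a noisy monotone
(log-scale) transform of final-day biovolume; dry weight a scaled second
draw, giving the high FW–DW correlation typical of biomass data.

What the generator does *not* emulate: leaf-level morphology and image
artefacts, spatial field trends, selection/pedigree structure, LD from
structural variation, and heteroscedastic measurement error. Passing tests
demonstrate correct recovery under the stated generative model, not
robustness to every property of real glasshouse data.

## Problem sizes and numerical choices

Recovery studies run at desk scale, chosen so the full suite and the
reproduction script each finish in minutes on one CPU: 400 × 2,000 for scan
power (20 replicates) and null error control (40 replicate scans), 100
genotypes × 3 experiments for the 20 heritability fits, 150–300 genotypes
for trajectory/reversal recovery. Mixed-model convergence is REML via
L-BFGS (statsmodels defaults, 200 iterations); the pseudo-QTN REML score is
optimised with bounded golden-section on log λ ∈ [−10, 10], tolerance 1e-4.
Ties in pseudo-QTN bin selection resolve to the first maximum (smallest bin
size); candidate ordering within bins breaks ties by P, then chromosome,
then position, so scans are exactly reproducible. The CNV ±1 bp position
shift is +1 first, −1 on collision.

## Known limitations

- The scan is a faithful *variant*, not a reimplementation, of the cited
  iterative pseudo-QTN method; bit-compatibility with any external package is
  not claimed. Its anchors are the single-iteration OLS equivalence, FDR
  control under the null, and power on planted architectures.
- With one observation per genotype and experiment, GxE is confounded with
  the residual and is dropped; heritability then reflects the combined
  variance, as in any single-replicate multi-environment design.
- The reversal guard (1 SE) can flag trajectories whose true effect is zero
  when residual noise is tiny; raise the guard for near-noiseless data.
- The Hill–Weir fit assumes a homogeneous panel; admixture inflates long-range
  r² and shortens fitted half-decays (see above). Decay *contrasts* between
  subgenomes are robust; absolute half-decays should be read with care.
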