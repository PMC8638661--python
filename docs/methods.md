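# Methods

## Scope

`crossgp` implements within-cross genomic prediction for a biparental
selfing population: a generative simulator of the population design
(F2 lineages, F3 families, F4 bulks, F7 RILs by single-seed descent),
numeric integration of mixed dominant/codominant marker calls, ridge
mixed models (RR-BLUP / GBLUP) fitted by REML, differentially
penalized ridge regression (DiPR) over two marker-type kernels, and
the evaluation designs used to measure prediction accuracy within and
between generations.  Real headline accuracies from field data depend
on an external dataset; everything here is validated on synthetic
populations with known architecture plus closed-form oracles.

## Population simulator

**Genome and meiosis.**  The genome is `n_chromosomes` linkage groups
of `chrom_length` cM with `n_markers` loci placed uniformly at random
per chromosome.  Parents are fully inbred and opposite at every locus;
the F1 is heterozygous throughout.  Gametes follow Haldane's map
function — recombination between adjacent loci at distance *d* cM with
probability r = ½(1 − e^(−2d/100)), no interference, chromosomes
independent.  Haldane is the simplest standard choice; nothing
downstream is sensitive to the map function at the distances used.

**Population design.**  Each of the `n_f2` F2 plants founds a lineage.
`advance(..., "ssd", ...)` takes one selfed seed per line per
generation; `"self_bulk"` produces `sibs_per_family` selfed progeny on
the first step (an F3 family per lineage) and maintains the bulk
thereafter.  `make_ril_population` takes one F3 seed per lineage and,
when `n_ril` exceeds `n_f2` (defaults 227 > 194), adds the extra RILs
from lineages drawn uniformly **without** replacement, so each extra
falls in a distinct family; the apportionment is also injectable.
Residual heterozygotes at F7 (≈ (½)⁶ ≈ 1.6 %) are retained, not forced
homozygous, since forcing them would bias the encodings.

**Markers.**  Each locus is dominant with probability `prop_dominant`
(default 0.75 ≈ 301/401, the composition of a mixed DArT +
microsatellite/GBS panel).  A dominant locus's detectable phase —
whether the heterozygote is indistinguishable from AA or from BB — is
drawn once per locus and fixed across generations, matching
presence/absence assays being locus-specific.  `common_marker_overlap`
controls how much of the panel is shared between the F2 and RIL
genotyping generations.

**Traits.**  Breeding value is a sum of additive allele-substitution
effects at `n_qtl` random loci (effects ~ N(0, `qtl_effect_scale`²)),
optionally plus a major gene placed at the nearest mapped locus to a
stated (chromosome, cM) position — the simulator's analogue of a
segregating dwarfing gene.  Phenotype per environment/year adds an
environment main effect (shared by all lines, so it shifts but never
reorders them) and a residual.  The residual variance is calibrated
against the realized breeding-value variance so that
var(BV)/var(phenotype) = `h2` **at the analysis unit**, the per-line
mean across `n_environments`.  `env_var_fraction` splits the
non-genetic variance between environment main effect and residual.
`h2 = 0` produces a pure-noise trait (unit residual variance; the
genetic term is omitted because no finite residual can produce a zero
variance ratio), and `h2 = 0` combined with zero residual raises.
F4-bulk phenotypes (`unit="family"`) are family means of per-sib
values plus a shared plot error, split 50/50 between the two
components at the calibrated total.

**Randomness.**  One root seed spawns named `numpy` child streams
(genome, meiosis, markers, trait, masking) so stages are independently
reproducible; identical configurations give bit-identical outputs.

**What the generator does not emulate** — and hence what passing tests
do not show about field data: epistasis and dominance trait effects,
genotype×environment interaction, selection during advancement,
genotyping error (missingness is the only data pathology), marker
ascertainment bias, and segregation distortion.  Synthetic accuracies
calibrate the machinery, not the crop.

## Marker encoding and kinship

Codominant classes score AA: 1, AB: 0, BB: −1.  A dominant marker's
two distinguishable classes take half scores — +0.5 for the class
containing AA, −0.5 for the class containing BB — reflecting their
uncertainty, akin to an imputed marker.  Half scores enter centering
and kinship exactly like whole scores; no extra rescaling.

Imputation defaults to the deterministic per-marker observed mean.
The `iterative_nonparametric` option is a missForest-style loop (mean
initialization; each incomplete marker regressed on all others with a
random forest, sweeping least-to-most missing, until the change in
imputed values stops decreasing), finally rounded to the marker's
nearest legal code.  The forest size is a knob (default 100 trees;
1,000 reproduces the heavier published setting).  Imputation quality
is scored on artificially masked cells by class-error rate and a
chi-squared comparison of imputed vs true class spectra.

LD thinning is greedy keep-first in map order at r² > 0.90 against any
already-retained marker, within chromosome by default (genome-wide
scan available), monomorphic markers dropped first — deterministic
given input order.  The pipeline imputes before thinning by default;
the order is a flag.

Kinship: columns centered, K = W Wᵀ scaled to mean diagonal 1.  The
normalization is a design choice (not dictated by the method's
definition): it makes per-type matrices comparable in magnitude so the
DiPR weight w is interpretable, each type using its own marker count.
`combine(K_dom, K_cod, w) = w·K_dom + (1−w)·K_cod`.

## Mixed model

y = 1β + u + e, u ~ N(0, K σ²u), intercept-only fixed effects
(phenotypes are averaged across trial entries upstream, so no further
covariates).  The restricted likelihood is profiled to one dimension
in log λ (λ = σ²e/σ²u) via the spectrum of S(K+I)S, S the projection
off the intercept (the +I shift isolates the intercept null-space from
genuine zero eigenvalues of K), and maximized by bounded scalar search
over log λ ∈ [−10, 10] at tolerance 1e−8.  BLUPs use the dual form
u = K·α, α = (K_obs + λI)⁻¹(y − 1β̂); unphenotyped lines get GEBVs by
the same cross-kernel product without entering the likelihood.
Near-singular kernels (a centered kernel always has the 1-vector in
its null space) get 1e−8 added to the diagonal, logged.

`RRBLUP` fits the same model in marker coordinates.  Its crossproduct
kernel W Wᵀ is normalized to mean diagonal 1 exactly like `kinship`
output, so the two forms optimize the *same* one-dimensional REML
problem (including any boundary behaviour of λ) and agree on GEBVs to
numerical precision; marker effects are recovered as
a = Wᵀ(W Wᵀ + λ_m I)⁻¹(y − 1β̂) with λ_m = kernel_scale · λ.  The two
code paths share no intermediate results beyond the optimizer, which
is what makes their agreement a meaningful cross-check.

## DiPR

The weight grid runs 0.00–1.00 in 0.01 steps (101 values).  For each
w, the cross-validated accuracy of GBLUP on the combined kernel is
computed; CV partitions are generated once per scan and held fixed
across the whole grid, so the argmax reflects the weight rather than
partition noise — without this the selected w is noise-dominated.
Accuracies within 1e−8 of the maximum (the λ-optimizer's resolution)
count as tied, and ties resolve to the smallest w, preferring the
codominant-only model as the more informative marker type.  At w = 0
predictions equal codominant-only GBLUP exactly; at w = 1,
dominant-only.  The scan validates both input kernels once and then
runs a lean numpy path (every convex combination of two PSD kernels is
PSD), which matches the labeled GBLUP path to ~1e−8.

## Evaluation designs

**Within-generation MCCV**: "five-fold CV with 100 replications" is
implemented as 100 independent random 80/20 splits (Monte-Carlo CV's
standard meaning), not 100 rotations of a fixed 5-fold partition.
Accuracy per replicate is the Pearson correlation between observed
phenotype and GEBV on the held-out fifth; replicates with a constant
vector or fewer than three evaluable pairs are flagged and excluded.
Replicates aggregate as r̄ = tanh(mean(atanh(r))), Fisher's Z being
approximately normal where r is not; values at ±1 are clamped to
±(1 − 1e−12) first.  Negative replicate correlations are retained in
the aggregate (a floor-at-zero reporting option exists for display
conventions that print 0.00).

**Major-gene stratification**: lines are classed Tall/Dwarf from the
code sign at a designated marker; heterozygotes join the
dominant-phenotype class (default Dwarf, the dominant action of a
Dw6-style gene; configurable).  A stratum is evaluated only when its
training portion exceeds 30 lines, otherwise reported as
not-evaluated — never as zero.

**Between-generation lineage k-fold** (k ∈ {2, 3, 4, 5}): each of 100
replicates samples ⌈n_lineages/k⌉ F2 lineages without replacement —
the sampling unit is the lineage, since the design simulates
genotyping F2 plants — trains on their early-generation records, and
predicts every RIL.  Accuracy is reported separately for RILs of
sampled lineages (within-family) and unsampled ones (between-family);
the two sets partition the RILs each replicate.  Within-family
correlations pool all pairs rather than averaging per family (a
per-family option exists).  The phenotypic proxy — lineage-mean early
phenotype vs lineage-mean RIL phenotype — benchmarks selection on
early phenotype alone.

## Numerical and test-design choices

- Eigendecompositions are O(n³) in the line count; the acceptance
  checks therefore run at a few hundred lines and a few hundred
  markers, where every statistic is already stable.
- Mendelian-segregation checks sum per-locus 1:2:1 chi-squares over
  loci placed one-per-chromosome: linked loci share individuals, so
  pooling them would overdisperse the statistic and miscalibrate its
  p-value.
- The null-calibration quantity in the acceptance script averages
  MCCV aggregates over five independent pure-noise datasets, because a
  single dataset's chance correlation (sd ≈ 0.1 at n = 200) dominates
  its own 100-replicate aggregate.
- DiPR weight-recovery checks use populations whose chromosomes are
  typed wholesale (half dominant, half codominant) with QTL confined
  to one type's chromosomes, so the two kernels are informatively
  unlinked by construction.
- Fixed, documented seeds everywhere; identical inputs reproduce
  every table bit-for-bit.

## Limitations

Two kernels only (no >2-type DiPR, no continuous optimization of w —
grid only); no Bayesian-alphabet models, multi-trait or G×E kernels;
no allele-frequency-weighted or pedigree kinship variants; no
training-set optimization; plain delimited text I/O rather than
VCF/HapMap (mixed-type class calls with half scores are first-class in
a simple schema; an import shim would be an extension).
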