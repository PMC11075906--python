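# Methods

`cmqtl` implements a complete, testable pipeline for mapping cell-morphology
quantitative trait loci (cmQTL) in a Diversity-Outbred-style (DO) mouse
fibroblast screen: per-individual dose-response summarization of
high-content morphology features, batch adjustment, normalization, and
genome scanning over 8-founder haplotype dosages. Because the raw screen
data are not part of the package, a first-class synthetic-data generator
reproduces the study design with known ground truth, so every stage is
verified by parameter and QTL recovery rather than by fixture files.

## Synthetic DO population and screen

**Genomes.** Each individual carries two gamete tracks per chromosome, each
an 8-state Markov chain over the founder strains: uniform start, switch
probability `1 - exp(-rate * dcM)` per marker interval, new founder uniform
over the other seven. Founder dosages (0-2, summing to 2 at every locus)
are the indicator sum of the two gametes. This deliberately replaces the
36-diplotype hidden Markov model used for real array data: the mapping
stage consumes allele dosages, so diplotype phase carries no information
downstream. A `blur` parameter mixes hard dosages toward the uniform 1/8
profile to emulate haplotype-reconstruction uncertainty. The genetic map is
linear at 0.5 cM/Mbp (configurable); the default switch rate of 0.1 per cM
produces the segment-rich mosaics of a population many outbreeding
generations past its founders. Independent mosaics understate the sibling
structure of a real DO cohort, so pairwise relatedness varies less than in
real data; the heritability calibration tests therefore use a lower switch
rate (longer shared segments) to obtain realistic relatedness contrasts.

**Screen.** The simulated exposure design copies the study layout: eight
concentrations (0, 0.01, 0.1, 0.75, 1.0, 1.25, 2.0, 5.0 uM) down the rows
of 96-well plates, four technical replicate columns per cell line split
over a plate pair (12 columns per plate, 6 lines per pair — 226 lines fill
76 plates), and runs of 12 lines. Each line's latent dose-response curve is
a four-parameter log-logistic (LL.4) whose targeted parameter (log-EC50 by
default) is baseline + QTL + polygenic + sex/generation shifts + residual.
The QTL term (founder dosages x centered effects) is rescaled so its
realized variance is exactly `h2_qtl` of the latent variance; the polygenic
term is drawn from N(0, K) with K the realized kinship of the simulated
genomes and rescaled likewise. Well values evaluate the LL.4 curve at the
design doses plus Gaussian plate, run, and residual noise with standard
deviations expressed as fractions of the curve span (defaults 0.05, 0.03,
0.05). The residual default matches the 5%-of-span noise level at which the
dose-response recovery properties are stated; total latent variance
defaults to 0.09 (SD 0.3 on log-EC50, roughly a two-fold EC50 range across
the population). A ground-truth sidecar records every latent parameter and
variance component per individual.

## Dose-response stage

The LL.4 model `f(x) = c + (d - c) / (1 + exp(b (log x - log e)))` is fit
per individual x feature x replicate column (pooling is available but off
by default, matching one model per technical replicate column) by
Levenberg-Marquardt least squares on `(b, c, d, log e)` with an analytic
Jacobian. Zero-dose control wells are kept and evaluated as the analytic
limit of the curve (`d` for b > 0, `c` for b < 0), implemented by placing
log(0) far below the smallest positive log dose so the logistic saturates;
the control anchors the baseline asymptote. Self-starting values take the
asymptotes from the response extremes, `e` from the geometric mean of
positive doses, and `b` from a logit linearization; jittered restarts are
attempted only when the first optimization fails. Degenerate inputs
(constant responses, fewer than four distinct doses) yield a non-converged
flag, never an exception.

Nine dose-response parameters (DRPs) per fit serve as quantitative traits:
starting asymptote (zero-dose limit), maximum asymptote (opposite limit),
slope, and EC5/10/25/50/75/90 from the closed form
`ECp = e * (p / (100 - p))^(1/|b|)` — the dose at which the response has
moved p% of the asymptote span from the zero-dose baseline, following the
curve's own orientation. A fit whose EC50 extrapolates more than 10x
outside the tested dose range (configurable) carries no information about
the inflection and is treated as a missing replicate; this is the
package's concrete form of the replicate-level quality filter, since the
exact drop rules behind the published trait counts are not specified. The
table additionally carries log-EC50 as a derived mapping trait: EC50s are
near-lognormal across individuals, and the linear batch adjustment behaves
far better on the log scale (the rank-based normalization that follows is
monotone-invariant, so only the adjustment step is affected).

## Mixed models: variance components and batch adjustment

Both the per-feature variance-component analysis (factors: sex, run,
generation, individual, plate, and concentration as a categorical) and the
replicate summarization (`value ~ 1 + (1|individual) + (1|plate)` per DRP)
use one REML engine for crossed random intercepts. Estimation is EM on
Henderson's mixed-model equations — monotone in the REML likelihood and
robust for small crossed designs — followed by a direct Nelder-Mead
maximization over log variances, because EM alone slows badly near a zero
component; log variances are clipped at 1e-10 of the response variance so
the objective flattens at the boundary instead of chasing it. Components
below 1e-6 of the response variance are reported as exactly zero.
Single-level factors are dropped with a warning; a factor with one
observation per level (confounded with the residual) is flagged and fixed
at zero. Proportions divide each component by the sum of all components
plus the residual. The per-individual BLUPs of the replicate summarization
— with the plate intercept absorbed and discarded — are the batch-adjusted
phenotypes; run is absorbed into the residual there because the
summarization model names individual and plate only. Unbalanced replicate
patterns are handled by the REML machinery directly, never by imputation.

## Normalization and feature structure

Mapping traits are rankZ-transformed: ranks (ties averaged, deterministic)
mapped through the standard normal quantile of `(r - 0.5)/n`, missing
entries preserved. The `(r - 0.5)/n` offset is the convention paired with
this mapping stack; the offset is configurable. PCA operates on features
centered and scaled to unit variance (correlation structure); constant or
too-missing features are dropped with a warning and percent variance sums
to 100.

## QTL mapping

**Kinship.** `K_ij = (1/M) sum_m sum_f q_imf q_jmf` with `q = dosage/2`, so
K lies in [0, 1] and unrelated individuals expect 1/8. Leave-one-chromosome
-out (LOCO) matrices exclude the scanned chromosome's markers; the overall
matrix serves heritability estimation.

**Scans.** Per trait and chromosome, the null (covariates-only)
heritability is REML-estimated once through the kinship eigendecomposition
and held fixed across that chromosome's markers — the standard multiparent
scan-speed convention. Data are rotated into the eigenbasis, weighted by
`1/sqrt(h2 * lambda + 1 - h2)`, and each marker adds the eight founder
dosage columns to a weighted least-squares fit solved by batched normal
equations with a pseudoinverse (the dosage/intercept dependency and any
collinear founder columns resolve to the minimum-norm solution, so no
column needs dropping and reported effects are centered 8-vectors).
`LOD = (n/2) log10(RSS0/RSS1)` in the rotated space. Sex and generation
enter as dummy-coded covariates.

**Haplotype effects.** At a locus, founder effects are modeled as i.i.d.
random with variance ratio tau estimated by REML (bounded 1-D search on
log tau) after the same LOCO rotation, and solved from the mixed-model
equations; effects are centered, and a REML estimate collapsing to zero
variance returns the all-zero vector with a flag. tau -> infinity
reproduces centered least-squares contrasts; tau -> 0 full shrinkage.

**Peaks.** At most one peak per chromosome per trait (first marker wins
exact ties); the support interval spans the outermost markers with LOD
within 1.5 (configurable) of the peak — the drop value is a convention, as
the published intervals are not given an explicit definition. Positions are
1-based bp, intervals closed.

**Permutations and FDR.** Phenotype rows and their covariates are shuffled
jointly against the genotypes — kinship structure is deliberately ignored
under the null, a documented approximation — and the genome-wide maximum
LOD recorded per permutation. With intercept-only covariates and no kinship
the permuted scans share one design and batch into a single pass. The
experiment-wide genome-wide FDR applies one shared permutation null to all
traits: the threshold is the smallest observed per-trait maximum t with
`m * tail_null(t) / #{observed >= t} <= q`. The empirical tail resolves
only to 1/n_perm, so the null must be much larger than the number of traits
for the bound to hold (the study used 100,000 permutations for ~5,000
traits); the acceptance test uses 5,000 permutations for 200 traits.
Per-trait nulls are available by running `permutation_null` per trait.

**Variant association.** A variant's strain-distribution pattern (8-bit
founder bitstring, ABCDEFGH order) collapses founder dosages at the nearest
marker into a single allele dosage for a 1-df test; an SDP and its
complement give identical tests (dosage 2 - v), and monomorphic SDPs are
flagged with LOD 0.

## Downstream candidate support

Haplotype-effect vectors are compared to external eQTL effect vectors by
Pearson and Spearman correlation after verifying founder order. Genes are
flagged not-expressed when median TPM < 0.5 or at least half the samples
fall below that cutoff (the source material prints both .05 and .5 in
different places; 0.5 is adopted and configurable). The Mendelian-ratio
utility computes class percentages and a Pearson chi-square against an
expected ratio, e.g. 2:1 het:WT under recessive embryonic lethality.

## Problem sizes and reproducibility

All randomness flows from integer seeds through numpy Generators; pipeline
artifacts carry a config hash and seed in their CSV headers plus a JSON
manifest, and reruns with the same config are bit-identical. The test suite
runs the full recovery experiment at the study scale (226 lines, 5
chromosomes x 200 markers, 50 seeds), the power simulation at 1,000
replicates, permutation calibration with 2,000 permutations and 400 null
traits, and variance-component recovery over 200 simulations; these sizes
were chosen so the whole suite completes in minutes on one core while
keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- The generator draws independent founder mosaics: no pedigree, no sibling
  structure, no X-chromosome dosage compensation. Pairwise relatedness
  varies less than in a real DO cohort, which mainly widens heritability
  sampling error.
- One feature is simulated per screen; the correlated feature blocks of
  real high-content data (and hence the multiplicity structure across
  traits) are not emulated beyond what the shared-null FDR test constructs
  directly.
- Passing recovery tests demonstrate correctness of the estimators under
  the generator's assumptions (Gaussian noise, additive founder effects,
  correctly specified LL.4 curves); they do not certify performance on
  real screens, where segmentation artifacts and heavy-tailed well noise
  occur.
- The permutation scheme ignores relatedness under the null; with strong
  population structure the null is approximate.
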