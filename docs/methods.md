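# Methods

This note records the model, the defaults and the places where the
design was genuinely open, so results produced with the package can be
interpreted (and re-derived) without reading the source.

## Standard organization

A biallelic SNP genotype is an unordered nucleotide pair. We fix the
total order A < C < G < T (aliases 1–4) and call the higher-ranked
allele of each SNP "hi". The genotype is written hi-first and re-aliased
over {1, 2}: heterozygote → (2, 1), hi homozygote → (2, 2), lo
homozygote → (1, 1). The first member is the odd compartment, the second
the even compartment; a sample over M SNPs becomes a symbol sequence of
length 2M. Only the within-SNP ranking matters — any fixed total order
on nucleotides yields the same symbols — so the order is frozen and
documented rather than configurable.

Two consequences worth keeping in mind:

* Encoder-produced data always satisfies P(odd = 2) ≥ P(even = 2) at
  every SNP, because heterozygotes write their 2 into the odd column.
  The statistics modules do **not** assume this, since externally
  encoded tables (including the published worked example) can violate
  it, e.g. when compartments were ordered by acquisition.
* The two compartments carry at least as much information as the SNP
  genotype: H_o + H_e ≥ H_snp for every distribution (verified as a
  property test over a probability grid). This is why allele-level
  screening is more sensitive than SNP-level screening.

## Cleaning rules

SNPs whose two columns jointly contain more than `max_missing = 2`
missing symbols (i.e. more than one missing genotype) are dropped;
the remaining gaps are filled with the column's modal symbol. The mode
is computed over both cohorts pooled so imputation cannot leak phenotype
labels; an exact 50/50 tie imputes symbol 2 (deterministic, measure-zero
in real data, configurable). Missingness is a distinct marker end to
end — never a zero count inside a statistic.

## Odds ratios

The allele odds ratio at one compartment is
ω = [p_d/(1−p_d)] / [p_c/(1−p_c)]. When any frequency hits 0 or 1 the
implied 2×2 counts get the Haldane–Anscombe +0.5 correction (applied
only on zero cells) and the locus is flagged; flagged loci participate
in selection but can be audited downstream.

The SNP-level ratio Ω applies the same formula to q, the SNP-level
probability of the major-alias symbol. The source material does not pin
down q, so three definitions are implemented:

* `allele_mean` (default): q = (p_o + p_e)/2, the symbol-2 frequency
  averaged over the SNP's two compartments;
* `pair`: q = p22 + p21, the probability of carrying at least one major
  symbol, from observed genotype pair counts;
* `p22`: the major-homozygote probability.

`allele_mean` is the default because it is the only candidate that
reproduces the characteristic behavior of risk loci: a SNP whose risk
compartment sits near fixation in both cohorts (p ≈ 1 − ε) shows a large
ω ≈ ε_c/ε_d while Ω stays near unity, because q is dominated by the
ordinary partner compartment. Under `pair`, 1 − q collapses to a product
of small ε's and Ω tracks (or exceeds) ω, which is not how SNP-level
screening behaves on such loci. Pair probabilities themselves are
computed from observed genotype counts; the analytic independence
products p22 = p_o·p_e etc. are available separately for closed-form
tests (observed compartments are coupled by the encoding, so the two
differ on real data).

## Locus selection, modal word, scores

High-value loci are compartments with ω ≥ Λ (one-sided default; a
two-sided option keeps max(ω, 1/ω) ≥ Λ and records the disease-enriched
symbol). Selections are nested in Λ by construction. The default
Λ = 2.4 sits in the empirically insensitive plateau of the selected-set
size curve N(Λ); a utility reports such plateaus (relative change below
1% over a window of width 0.1 by default). Histograms of ω and Ω use
2000 equal-width bins spanning the observed range clipped at the 99.99th
percentile (raw extremes are retained in the result object).

The modal word takes the disease-cohort modal symbol at each selected
locus (tie → 2). A sample's score is its agreement count with the word,
so score + Hamming distance = L identically. Cohort scores are fit by
gaussians (sample mean, unbiased SD; σ = 0 is flagged, not fatal) and
the decision threshold Δ\* minimizes the expected misclassified count on
a 10⁴-point grid spanning both means ± 4σ. Grid search replaces the
ROC slope −1 tangency characterization because the tangency point
depends on cohort-size weighting and axis orientation; for n_d = n_c the
two coincide and that is checked as a diagnostic only. Classification is
score ≥ Δ\* → disease, ties to disease (conservative for screening).

## Indicator vector

Symbols 2/1 embed to ±1, giving squared Euclidean distance exactly
4 × Hamming distance (the factor is a named constant; an orthonormal
pair embedding with factor 2 can be swapped in). The indicator vector
maximizes J(v) = ⟨(x·v)²⟩_D − ⟨(x·v)²⟩_C subject to ‖v‖ = 1 — a
second-moment contrast whose stationarity condition is the symmetric
eigenproblem K v = λ v with K = DᵀD/n_d − CᵀC/n_c. Because v must lie in
the span of the n = n_d + n_c data rows, the L×L problem reduces to the
n×n problem W X Xᵀ a = λ a (W the signed cohort-weight diagonal),
v = Xᵀa — the method of snapshots, essential when L ≫ n.

Numerical choices: the snapshot matrix is non-symmetric (W is
indefinite, so no W^{1/2} similarity exists); the nonsymmetric n×n
problem is solved densely, the largest essentially-real eigenvalue is
taken, and the eigenpair residual must satisfy
‖WGa − λa‖ ≤ 1e−8·max(1, |λ|)·‖a‖. When L ≤ n the direct L×L symmetric
solve is used instead. A vanishing contrast (‖K‖_F ≈ 0, e.g. identical
cohorts) is detected before the eigensolve — the spectrum of a
numerically nilpotent matrix is noise — and reported as a warning with
λ = 0 rather than an error. The sign of v is fixed by
v·(mean(D) − mean(C)) ≥ 0.

One behavioral note: on ±1 data every diagonal entry of K is zero, so a
marginal frequency shift at a *single* locus is invisible to J; the
criterion responds to frequency shifts through cross-correlations among
many shifted loci (the regime selection produces) and to correlation
structure directly. The criterion is isolated behind `solve_indicator`
so an alternative functional can replace it without touching any other
module.

Pseudo-probabilities: v is rescaled by its largest |component| and
mapped to p\* = (1 + v′)/2 ∈ [0, 1]; a locus is retained when
max(p\*, 1 − p\*) > θ (default 0.5 — the level is not critical), with
word symbol 2 where v′ > 0. An RMS-scaled variant (v√L) is reported as a
diagnostic; those values can leave [0, 1], which is what makes them
pseudo-probabilities.

## Structure matrices

Intra-cohort pairwise Hamming distances on the selected loci, reordered
by ascending mean distance of each sequence to all others (self term
excluded — including it shifts every mean equally for fixed n, so the
ordering is unchanged; ties break by original index, making the
reordering idempotent). Score traces under this ordering are a display
device; removing points from a trace is always an explicit caller input,
never automatic. No clustering or sub-type calling is attempted.

## Validation procedures

* **Permutation trials**: labels shuffled with cohort sizes fixed — the
  one randomization that preserves every genotype statistic (a bootstrap
  mode exists behind a flag). The per-trial statistic is the
  symbol-matched overlap fraction with the reference classifier (locus
  AND symbol must agree; the three-alteration argument — symbol flip,
  major-locus drop-out, minor-locus entry, each preserving with
  probability 1/2 — implies symbol-matched overlap and expectation 1/8).
  The alteration model itself is also implemented as a direct simulation;
  real permutation overlaps agree with it only to within the
  trial-to-trial spread, as the model idealizes loci as independent fair
  coins.
* **Random baselines**: L loci drawn uniformly without replacement
  (expected locus overlap L/2M), symbols modal or random (random symbols
  halve the matched overlap when modes are equiprobable).
* **Split validation**: selection, word and Δ\* are fitted on the
  training split only; fitting them on all data first makes the test
  error meaningless for prediction, and the function warns when asked to
  do that.
* **Reduced-classifier leave-two-out**: per trial one case and one
  control are held out, the classifier is refit, loci are ranked by the
  disease-minus-control frequency of the classifier symbol, and the
  bottom n_bottom loci alone score the held-out pair (strict win
  required; ties are reported separately). The rate is tested against
  0.5 with an exact binomial sign test.
* **Subsample extrapolation**: mean selected-set size at cohort
  fractions (60…100%) is fit by L(n) = L_inf + β/n. The 1/n form is
  chosen because the excess selection at finite n is driven by frequency
  noise whose variance scales as 1/n, and a finite asymptote is required
  for the unbounded-data interpretation; the relative fit residual is
  reported.

All stochastic procedures take a seed and are bit-reproducible given
(seed, n_trials).

## Synthetic generator

The generator emulates the statistical shape of a large case/control
panel: defaults of 919 cases / 787 controls, per-compartment null
symbol-2 frequencies drawn from Beta(2, 2), a minority of planted risk
compartments whose disease frequency is solved from a target ω by
inverting the odds formula, per-genotype missingness at rate 1.4e−4
with optional high-missingness SNPs at 10% to exercise the cleaning
rules, and independent loci throughout (no linkage disequilibrium — an
explicit non-goal).

`genotypic` mode (default) draws each SNP's genotype category with
P(22) = p_e, P(21) = p_o − p_e, P(11) = 1 − p_o, which achieves the
target compartment marginals exactly while respecting the encoding
constraint p_o ≥ p_e; the constraint is enforced by clamping the
*unplanted* partner compartment to a common bound across both cohorts,
so planting one risk compartment never manufactures an association at
its partner. `independent` mode draws the compartments independently
and can violate the encoding constraint — useful for fixtures shaped
like externally encoded tables. The truth table returned alongside the
matrix carries the exact post-adjustment frequencies and true ω per
locus.

What passing tests on this generator do *not* show: robustness to
linkage disequilibrium, population stratification, relatedness,
genotyping batch effects, or informative missingness — none of which
the generator produces.

## Problem sizes used in the test suite

Unit tests run on studies of 100–300 samples and a few hundred SNPs;
the full-pipeline suite uses 900/800 cohorts with 5,000 SNPs and 200
planted risk compartments at ω = 4, where selection at Λ = 2.4 recovers
essentially all planted loci with ≈1 noise selection. These sizes make
every statistical check well-powered while the whole suite completes in
seconds.

## Known limitations

* The criterion functional, the v → pseudo-probability map, and the
  SNP-level q are reconstructions of under-determined definitions; each
  is isolated behind one interface and alternatives are configurable.
* One printed worked-example ratio (disease .9947 / control .9785)
  computes to 4.1238 from the printed four-decimal frequencies and hence
  rounds to 4.12, not the published 4.13 — consistent with the original
  having been computed from unrounded frequencies. The discrepancy is
  surfaced, not patched.
* Only the leading indicator component is extracted; phasing,
  multi-allelic variants, indels and covariate-adjusted association
  models are out of scope.
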