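# akernel

Allele-level extraction of a disease classifier from case/control SNP
genotype data.

Genome-wide association studies usually score each SNP as a unit. This
package implements an alternative pipeline for researchers who want to
treat disease as a weak signal spread over *many* loci: each biallelic
SNP genotype is re-encoded as an ordered pair of allele compartments
(the **standard organization**), every compartment is screened by its
disease/control odds ratio, and a classifier — a word of symbols over the
surviving "high-value" loci — is read off either as the disease-cohort
mode or from an eigen-optimized indicator vector. Validation utilities
(label-permutation trials, random baselines, train/test splits,
leave-two-out prediction with reduced classifiers, and subsample
extrapolation) quantify how much of the extracted classifier is real
signal and how much is finite-sample noise.

## The model in brief

For SNP *k* with alleles ordered under A &lt; C &lt; G &lt; T, the genotype is
written hi-allele first and aliased to symbols over {1, 2}: heterozygote
→ (2, 1), hi homozygote → (2, 2), lo homozygote → (1, 1). Columns 2k−1
and 2k are the *odd* and *even* compartments of SNP *k*. For a cohort,
p is the symbol-2 frequency at a compartment, and the **allele odds
ratio** between disease (d) and control (c) cohorts is

    ω = [p_d / (1 − p_d)] / [p_c / (1 − p_c)]

High-value loci are those with ω ≥ Λ (default Λ = 2.4). Over that locus
set N_Λ of size L:

* the **modal indicator** W is the word of disease-cohort modal symbols;
* a sample's **score** is its agreement count with W (equivalently
  L minus its Hamming distance from W);
* cohort score distributions are fit by gaussians N(μ_d, σ_d²),
  N(μ_c, σ_c²) and the decision threshold Δ\* minimizes the expected
  error [n_d(1 − T(Δ)) + n_c FP(Δ)] / (n_d + n_c);
* the **indicator vector** v maximizes the mean-squared-projection
  contrast ⟨(x·v)²⟩_D − ⟨(x·v)²⟩_C over unit vectors after embedding
  symbols 2/1 → ±1 (so squared Euclidean distance = 4 × Hamming
  distance). v is the leading eigenvector of K = DᵀD/n_d − CᵀC/n_c,
  solved in the n-dimensional span of the data rows (**method of
  snapshots**); its components rescale to pseudo-probabilities, and only
  "overprobable" loci (level θ) are retained in the refined classifier.

Everything is available both as plain functions and as scikit-learn
style estimators (`ModalClassifier`, `IndicatorClassifier`) that
compose with sklearn model selection.

## Worked example

```python
import numpy as np
import akernel as ak

# a synthetic study: 300 cases / 250 controls, 1000 SNPs, 40 allele
# compartments planted at true odds ratio 4
rng = np.random.default_rng(7)
risk = ak.synthetic.uniform_risk_loci(rng, 1000, 40, 4.0)
spec = ak.SyntheticSpec(n_cases=300, n_controls=250, n_snps=1000,
                        risk_loci=risk, seed=7, missing_rate=0.0)
m, truth = ak.generate(spec)

clf = ak.ModalClassifier(odds_threshold=2.4).fit(m)
print(clf.selection_.size)                      # 43
print(clf.fits_.mu_d, clf.fits_.mu_c)           # 34.1 vs 23.4
print(clf.delta_star_, clf.e_min_)              # 28.9, 0.028
print((clf.predict(m) != m.labels).mean())      # 0.025

rep = ak.permutation_trials(m, 2.4, n_trials=50, seed=17)
print(rep.mean)                                 # 0.000

curve = ak.subsample_extrapolation(m, 2.4, n_repeats=4, seed=17)
print(curve.mean_L[-1], curve.L_inf)            # 43.0 -> 38.4
```

Reading the output: screening at Λ = 2.4 keeps 43 allele loci (the 40
planted plus a few noise selections). Case scores cluster at μ_d = 34.1
agreements out of 43 against μ_c = 23.4 for controls; thresholding at
Δ\* = 28.9 misclassifies 2.5% of samples, close to the gaussian-predicted
minimum error of 2.8%. Randomizing the phenotype labels destroys the
classifier (mean symbol-matched overlap 0.000 over 50 trials), and the
subsample fit L(n) = L_inf + β/n extrapolates the 43 selected loci down
toward 38 as the noise selections that ride on finite-sample frequency
error are projected out.

The same pipeline runs from the shell:

```sh
akernel simulate --n-cases 300 --n-controls 250 --n-snps 1000 \
    --n-risk 40 --missing-rate 0 --seed 7 --out-prefix sim
akernel stats    --std sim.std.tsv --pheno sim.pheno.tsv --out-prefix stats
akernel classify --std sim.std.tsv --pheno sim.pheno.tsv --Lambda 2.4 --out-prefix model
akernel validate --std sim.std.tsv --pheno sim.pheno.tsv --mode permute \
    --trials 50 --seed 17 --out-prefix val
```

`akernel encode` converts VCF, PLINK .ped/.map or standard-form TSV
input (plus a sample→{disease,control} phenotype TSV), applies the
cleaning rules (drop SNPs with more than 2 missing symbols, modal-impute
the remainder) and writes the standard-form TSV the other subcommands
consume.

## Layout

| module | contents |
| --- | --- |
| `akernel.standard_form` | encoding, cleaning, VCF/PED/TSV readers |
| `akernel.locus_stats` | probabilities, entropies, ω and Ω, histograms |
| `akernel.modal` | locus selection, mode word, scores, ROC, `ModalClassifier` |
| `akernel.indicator` | embedding, snapshot eigenproblem, pseudo-probabilities, `IndicatorClassifier` |
| `akernel.structure` | Hamming structure matrices and reordering |
| `akernel.validation` | permutation/baseline/split/leave-two-out/subsample checks |
| `akernel.synthetic` | study-shaped generator with planted risk loci |
| `akernel.cli` | `akernel` command-line pipeline |

See `docs/methods.md` for the modeling choices, defaults and known
limitations.
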