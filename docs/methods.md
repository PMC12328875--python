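# Methods

This note documents the models and procedures implemented in `neoquant`,
their assumptions, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate.

## Neoantigen derivation

**Peptide enumeration.** For a missense variant at protein position *p* in a
protein of length *L*, every window of length *k* ∈ {8,…,14} containing *p*
is enumerated, clipped to protein bounds, together with the matching
wildtype window. The count per length is
`min(p, L−k+1) − max(1, p−k+1) + 1`; an interior position yields 77 pairs
over all lengths and a terminal position 7. Windows shorter than 8 are never
padded. Variants whose stated reference residue disagrees with the proteome
raise a consistency error rather than being silently re-anchored.

**Binding predictor contract.** Any deterministic map
`(peptide, allele) → (IC50 nM, EL %rank)` with positive finite outputs can
drive the pipeline. External netMHCpan-4.1-style tables are read in percent
rank units (EL ≤ 2 means the top 2 % of random natural peptides) and nM.
Conflicting duplicate rows are an error; missing pairs are skipped with a
warning.

**Classification.** A unique mutant peptide is a neoantigen if it passes
`IC50 ≤ 500 nM` **or** `EL rank ≤ 2` on at least one of the patient's
alleles. Uniqueness is per patient, across lengths, alleles and source
variants, and deduplication happens *after* per-allele thresholding. The
record keeps the minimum IC50 and EL rank over all patient alleles and
sub-flags at EL ≤ 0.5, IC50 ≤ 50 and IC50 < 34 (strict, as conventionally
printed) for feature counting.

**DAI.** The differential agretopicity index is the wildtype:mutant IC50
ratio — the only reading on which the conventional threshold of 10 is a
natural unitless cutoff. It is evaluated per binding allele and the record
carries the maximum over its binding alleles; a difference form
(`IC50_wt − IC50_mut`) is available for sensitivity analysis
(`dai_mode="diff"`).

**Recognition and dissimilarity scores.** Both use the same logistic
partition-function model on affine-gap Smith–Waterman scores
(BLOSUM62; a gap of length ℓ costs 11 + ℓ):

    Z = Σ_e exp(−k (a − s_e)),   R = Z / (1 + Z)

with defaults a = 26, k = 4.87 — the constants of the established
recognition-probability model this score family comes from; both are
config-exposed. The IEDB-style score is R against an epitope set; the
bundled epitope FASTA is **synthetic** (randomly generated stand-in, named
accordingly) and users supply their own curated set for real analyses.
Dissimilarity is `1 − R_self` against the self peptidome — all 8–14-mers of
the (by default) mutated genes' wildtype sequences; restricting to mutated
genes keeps the alignment workload proportional to the mutated fraction of
the proteome, and the full proteome can be passed instead. The score is
computed in log space so near-identical matches saturate to exactly 1
without overflow. The empty epitope set scores 0 by definition; an empty
self peptidome is an error (the self reference is mandatory).

The Smith–Waterman kernel is implemented three ways that must agree
exactly: a scalar DP (reference), a numpy-vectorised batch, and a
numba-JIT batch used when numba is importable. Tests pin all of them to
each other, to exhaustive alignment-path enumeration on short peptides, and
to biopython's independent `PairwiseAligner` under the identical scoring
scheme.

## Per-patient features

- `nssnv_load` — missense variants after VCF filtering and locus dedup.
- `hvsnv_load` — variants contributing ≥ 1 neoantigen ("high-value" SNVs).
- `neoantigen_load` — unique passing peptides.
- `neoantigen_frequency` — load per hvSNV by default. The per-nsSNV
  denominator is available via config, but the reference cohort's own
  summary statistics (load ≈ 1670, hvSNV ≈ 262, frequency ≈ 6.4) are
  mutually consistent only on the per-hvSNV scale, so that is the default.
- Threshold counts (EL ≤ 2 / ≤ 0.5, IC50 ≤ 500 / ≤ 50 / < 34), quality
  counts (DAI ≥ 10, dissimilarity ≥ 0.75, IEDB ≥ 0.9), promiscuity count and
  fraction with cross-gene / cross-group / within-group partition (by HLA
  gene and two-digit allele group), oncogene-derived count (against a
  user-supplied symbol list), TMB = nsSNV / exome Mb (default 34 Mb).
- TCR: inverse Simpson diversity `1/Σp²` and Simpson clonality `√Σp²` on
  template counts (the common immunosequencing convention; note
  `clonality² · diversity ≡ 1`). A normalised-Shannon alternative
  (`shannon_clonality`) is provided under a distinct name.

Promiscuity is counted per neoantigen (not per peptide–allele pair).

## Synthetic cohort simulator

No generative model of the real cohort exists; every distribution below is
a labelled stand-in chosen to reproduce published summary structure, and the
latent values actually used are stored in `truth` so estimators can be
checked against ground truth exactly.

- **Burden**: per-patient nsSNV counts are log-normal parameterised by
  median (default 800) and log-sd (1.1, giving a 25–5000-ish range at
  n ≈ 90). Mutated positions are uniform over gene bodies of a uniform
  random 20-letter proteome (no codon model — the analysis is peptide
  level), one variant per protein position.
- **HLA**: allele counts 3/4/5/6 with probabilities 2/11/38/49 %;
  homozygous loci are drawn explicitly so a 3-allele patient is homozygous
  at all three class-I genes. The default pool is 18 common alleles with
  rough European-ancestry frequencies.
- **Clinical covariates** are drawn independently of the features
  (marginals: 58 % male, 91 % smokers, 66 % adenocarcinoma, stage
  51/29/20 %, EGFR 10 %, KRAS 21 %) so parameter-recovery tests are clean;
  a confounded design is out of scope.
- **Latent features**: hvSNV is a noisy ≈ 0.33 fraction of the burden
  (hence the near-perfect rank correlation between the two), neoantigen
  load multiplies hvSNV by a noisy per-mutation yield centred at 6.4.
- **Survival**: recurrence times are exponential with rate
  `λ₀·exp(Σβx)` on mean-centred latent features (centring only moves the
  baseline, which Cox estimation never identifies anyway); death is an
  independent exponential; administrative censoring is uniform over a
  6–150-month follow-up window. TTR treats death as censoring at the death
  date; RFS counts recurrence-or-death — so the two endpoint columns share
  times and differ in event flags. Default effects: HR 0.7 per 1000
  neoantigens (protective) and HR 1.185 per unit frequency (adverse),
  matching the direction and scale of the reference analysis. A Weibull
  hazard was considered and rejected: the exponential admits closed-form
  checks and the analysis layer never assumes a hazard shape.
- **TCR**: clone weights ∝ rank^(−α) (α = 1.1) multinomially sampled, so
  repertoires are heavy-tailed and less diverse than uniform.

**Mock binding landscape.** The mock predictor is a deterministic pseudo
position-weight-matrix landscape, not a trained model. Every score
component is a sum of per-position residue weights drawn from hashed,
seed-keyed PWMs: one PWM per (allele, length) for allele specificity, one
shared allele-independent PWM (weight ρ = 0.65) that makes some peptides
intrinsically "presentable" and thereby produces promiscuous binders, and
one per-allele affinity PWM. The EL rank is the exact upper-tail Gaussian
percentile of the combined score, warped so `P(EL ≤ 2)` equals the
`strong_binder_frac` knob (default 0.013); IC50 is coupled through a
Gaussian copula (λ = 0.7) and mapped so `P(IC50 ≤ 500)` ≈ 0.0085. Because
all components are positional, a mutant scores like its wildtype window
except when the substitution hits a large-weight (anchor-like) position —
so DAI concentrates near 1 with a small tail of large values, as a real
landscape produces. With these defaults a simulated cohort shows:
neoantigens-per-hvSNV ≈ 5.4–6.1 (published ≈ 6.4; the simulator's
calibration check accepts ± 30 %), EL-arm fraction ≈ 68 % (73.5 %),
arm overlap ≈ 21 % (20.7 %), promiscuous fraction ≈ 17 % (19.2 %),
DAI ≥ 10 in ≈ 7 % (1.6 % — the mock's wildtype–mutant coupling is weaker
than a real predictor's, a known limitation). Known deviation from the
published structure: with an i.i.d.-per-peptide landscape, essentially
every mutation with 77 windows yields some binder, so hvSNV ≈ nsSNV instead
of ≈ 0.33·nsSNV; the 0.33 fraction is therefore imposed at the latent
level, and pipeline-recomputed features at demo scale are correlated with,
but not identical to, the latent features that drive the simulated hazards.
Passing tests on this simulator demonstrate the *statistical machinery* —
not that any real predictor behaves this way.

## Statistical layer

- **Kaplan–Meier** via lifelines (product-limit); **log-rank** implemented
  directly (`(O−E)²/V` with hypergeometric variance) because the cutoff
  scan evaluates it thousands of times; it is pinned to lifelines'
  implementation in tests.
- **Cox PH** via statsmodels `PHReg`, ties Efron by default with Breslow
  available. Optimisation is BFGS (gradient tolerance 1e-9, 100 iterations)
  on sd-standardised covariates — the optimiser diverges silently on raw
  scales of ~10³ — with coefficients rescaled afterwards to the declared
  reporting units (per-100 nsSNVs, per-1000 neoantigens, …, mirroring the
  conventional table layout). Estimates are pinned to a grid-search
  maximiser of an independently coded partial likelihood. Wald CIs at 95 %.
  Multivariable models enter one biomarker at a time alongside the clinical
  adjustment set (sex, histology, stage, smoking, EGFR, KRAS), plus a
  free-form covariate interface.
- **Optimal cutoff**: candidate cutpoints are midpoints of consecutive
  distinct marker values; splits leaving either group below 10 % of
  patients are rejected; the log-rank p is computed per candidate and the
  arg-min returned **uncorrected**, together with the full profile — the
  minimum-p approach is optimistic by construction and the output says so.
  Ties resolve to the smallest cutoff. Note that with strongly separated
  risk blocks the uncorrected minimum can legitimately fall on an
  unbalanced split inside a block; the group-size floor is the guard.
- **Nonparametric tests**: Spearman (tie-corrected, n ≥ 3 enforced),
  two-sided Mann–Whitney, Kruskal–Wallis — thin wrappers over scipy with
  arity checks.
- **3-year relapse model**: eligibility is a landmark rule — relapse before
  36 months (outcome 0) or event-free follow-up ≥ 36 months (outcome 1);
  patients censored earlier are excluded, so the eligible count equals
  (events before horizon) + (followed ≥ horizon event-free). Continuous
  features enter as `log(x+1)` so zero loads are admissible; adjustment for
  sex, stage (indicator-coded) and smoking. Maximum likelihood via
  statsmodels `Logit`; non-convergence or coefficient blow-up is flagged as
  separation and refit with a small ridge penalty (α = 1e-3), with the flag
  carried in the results. The 36-month horizon is config-exposed.
- **ROC/AUC**: empirical ROC over all thresholds, trapezoidal AUC (equal to
  the Mann–Whitney pair-counting statistic, asserted in tests), Youden
  J = max(sens + spec − 1) with ties broken at the lowest threshold, and
  'high'/'low' dichotomisation at the Youden cutoff for downstream survival
  correlation.
- **AUC comparison**: paired placement-value (DeLong-style) test, two-sided
  normal p; identical ROCs return p = 1 by convention. Only the paired form
  is implemented (the unpaired comparison has no use in this design).

## Problem sizes

The demo configuration (30 patients, burden median 25, 30 genes of 100–200
residues) exercises every stage — roughly 40 k peptide pairs, 400 k mock
predictions and 4 k scored neoantigens — in about 80 s on one CPU.
Parameter-recovery checks use 20 replicates of 300-patient cohorts at the
feature level (no peptide enumeration), and the burden calibration uses the
full published-scale defaults (n = 89, median 800). These sizes are the
package's chosen trade-off between statistical resolution and a
fast-feedback test suite.

## Known limitations

- The mock landscape is i.i.d. across peptides given its PWMs; real
  predictors share anchor motifs across related alleles (supertypes), so
  cross-allele structure here is cruder than reality, and its DAI tail is
  fatter than a real predictor's.
- No proteasomal cleavage, TAP transport, peptide–MHC stability or gene
  expression weighting — out of scope by design.
- Multi-transcript SnpEff annotations resolve to the *first* missense entry
  (SnpEff orders canonical/most-severe first); ANN fields do not reliably
  carry CDS lengths, so a longest-CDS rule is not implementable from the
  annotation alone.
- The minimum-p cutoff and the training (apparent) AUCs are optimistic;
  neither is corrected, matching the analysis style this package
  reimplements — downstream users should validate externally.
- Clinical covariates are simulated independently of molecular features, so
  adjusted and unadjusted synthetic analyses differ only by noise; the
  machinery supports confounded data, the simulator deliberately does not
  generate it.
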