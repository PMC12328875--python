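# neoquant

Neoantigen quantification and prognostic modelling for resected early-stage
non-small cell lung cancer (NSCLC).

After curative surgery, a large fraction of early-stage NSCLC patients
relapse, and immune surveillance of residual disease is thought to depend on
the tumour's MHC class-I neoantigens — mutant peptides created by
non-synonymous somatic single-nucleotide variants (nsSNVs) and presented on
the patient's HLA alleles. `neoquant` implements, as a tested and reusable
pipeline, the full path from annotated somatic variants to prognosis:

1. **Peptide enumeration** — every 8–14-mer window covering a missense
   variant, paired with its wildtype counterpart.
2. **Binding prediction** — a pluggable predictor contract
   `(peptide, allele) → (IC50 nM, EL %rank)`; supports external
   netMHCpan-4.1-style tables and ships a deterministic mock landscape.
3. **Neoantigen classification** — a unique mutant peptide is a neoantigen
   if on ≥ 1 patient allele `IC50 ≤ 500 nM` **or** `EL rank ≤ 2`.
4. **Quality metrics** — differential agretopicity index
   `DAI = IC50_wt / IC50_mut`, TCR-recognition (IEDB-style) score
   `R = Z/(1+Z)` with `Z = Σ_e exp(−k(a − s_e))` over Smith–Waterman scores
   against an epitope set, self-dissimilarity `1 − R_self`, HLA binding
   promiscuity (mono-allelic vs cross-group vs cross-gene), and
   oncogene-derived counts.
5. **Per-patient features** — nsSNV load, hvSNV load (mutations yielding
   ≥ 1 neoantigen), neoantigen load, neoantigen frequency (load per hvSNV),
   threshold/quality counts, TMB, and TCR repertoire indices
   (inverse Simpson diversity `1/Σp²`, Simpson clonality `√Σp²`).
6. **Statistics** — Kaplan–Meier / log-rank, uni- and multivariable Cox PH
   (HRs per stated unit, e.g. per 1000 neoantigens), minimum-p optimal-cutoff
   dichotomization, and a logistic model of 3-year relapse-free status with
   ROC/AUC, Youden cutoffs and paired AUC comparison.

The patient-level study data this analysis style was developed on are
access-restricted, so the package includes a first-class **synthetic cohort
simulator** reproducing the cohort's statistical structure (log-normal nsSNV
burdens with median 800, 3–6 HLA alleles per patient, clinical covariate
marginals, power-law TCR repertoires, and survival times with log-linear
hazard effects on known latent features). All statistical machinery is
validated against independent oracles and recovery of simulated truth; see
`docs/methods.md`.

## Worked example

```python
import pandas as pd
from neoquant import (SimulationConfig, simulate_cohort, enumerate_peptide_pairs,
                      MockBindingPredictor, build_neoantigen_records,
                      compute_patient_features, build_feature_table, CoxPHModel)

cfg = SimulationConfig(n_patients=12, seed=3, burden_median=40, burden_sigma=0.5,
                       n_genes=40, gene_length_range=(120, 300))
cohort = simulate_cohort(cfg)
predictor = MockBindingPredictor(seed=3)

vectors = []
for pid in cohort.patient_ids:
    pairs = [p for v in cohort.variants[pid]
             for p in enumerate_peptide_pairs(v, cohort.proteome)]
    records = build_neoantigen_records(pairs, cohort.hla[pid], predictor)
    vectors.append(compute_patient_features(pid, cohort.variants[pid], records,
                                            tcr_counts=cohort.tcr[pid]))
features = build_feature_table(vectors).set_index("patient_id")
print(features[["nssnv_load", "hvsnv_load", "neoantigen_load",
                "neoantigen_frequency"]].head(4))
```

```
            nssnv_load  hvsnv_load  neoantigen_load  neoantigen_frequency
patient_id
P001                55          55              325              5.909091
P002                51          51              268              5.254902
P003                77          76              426              5.605263
P004                88          86              487              5.662791
```

Each row is one simulated patient: e.g. P001 carries 55 missense mutations,
all 55 of which yield at least one predicted neoantigen (hvSNVs), for 325
unique neoantigenic peptides — 5.9 neoantigens per neoantigen-generating
mutation. Fitting a Cox model of time-to-recurrence on neoantigen load:

```python
clinical = pd.DataFrame({pid: {"ttr_time": r.ttr_time, "ttr_event": r.ttr_event}
                         for pid, r in cohort.survival.items()}).T
df = features.join(clinical)
res = CoxPHModel(df, "ttr_time", "ttr_event", ["neoantigen_load"],
                 unit_scales={"neoantigen_load": 1000}).fit()
print(res.summary().round(3))
```

```
                 unit   coef     HR  HR_lower95  HR_upper95      p
variable
neoantigen_load  1000 -0.312  0.732       0.003     174.541      0.911
```

The hazard ratio is reported per 1000-neoantigen increase; at n = 12 the
interval is (correctly) enormous — the parameter-recovery tests run the same
fit at n = 300 where the simulated HR of 0.7 is recovered.

## Command-line pipeline

```bash
neoquant all --outdir runs/demo --seed 7          # bundled demo config
neoquant simulate --config my.yaml --outdir runs/x --seed 1
neoquant survival --outdir runs/x                 # re-run one stage
```

Stages (`simulate`, `enumerate`, `predict`, `features`, `survival`,
`riskmodel`, `report`) exchange plain-text artifacts under the run directory
and record a `manifest.json` with the config snapshot, seed, per-stage
timings, counters and output checksums; identical seeds reproduce outputs
byte-for-byte. The bundled demo config finishes in under two minutes on one
CPU.

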