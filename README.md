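# melasig

Mutational-signature subtyping of cutaneous melanoma from somatic SNV
catalogs.

Cutaneous melanomas split into two biologically distinct groups: tumors
dominated by ultraviolet mutagenesis (high burden, C>T at dipyrimidines,
SBS7a/7b-like spectra) and a minority with little or no UV signal (low
burden, clock-like SBS1/5 spectra, worse prognosis). `melasig` implements
the full analysis that separates them:

1. **96-class context matrix** — somatic SNVs from MAF (GDC dialect) or
   VCF are classified on the pyrimidine strand into the 6 × 16 canonical
   trinucleotide substitution classes using a reference FASTA; samples
   with fewer than five SNVs are excluded.
2. **De novo signature extraction** — the samples × 96 count matrix V is
   factorized as V ≈ WH by multiplicative-update NMF minimizing the
   generalized Kullback–Leibler divergence (Brunet variant), with seeded
   multi-restart and rank-selection metrics (average sample cosine
   distance, average silhouette width over ranks 2–8). At rank 2 the
   factors are the clock-like **SigA** and UV-like **SigB** (identified by
   cosine similarity to SBS7a/7b).
3. **UV-high / UV-low clustering** — k-means (k = 2) on per-sample
   normalized exposures; the cluster with the greater mean SigB weight is
   UV-high.
4. **Signature refitting** — each spectrum is decomposed onto fixed
   reference signatures by non-negative least squares on proportion
   vectors, with iterative pruning of weights below 0.06 (the
   deconstructSigs convention).
5. **In-silico panel sequencing** — catalogs are restricted positionally
   to capture regions (BED); panel samples with ≥ 5 SNVs are called
   UV-high when their refit SigB weight exceeds 0.5.
6. **Survival comparison** — Kaplan–Meier curves, two-tailed log-rank
   test, Cox proportional hazards (Efron ties; unadjusted and adjusted
   for age, sex, stage and BRAF mutation class) and 1-year landmark
   analysis.

A fully synthetic cohort generator (`melasig.simulate`) produces toy
genomes, mutation catalogs drawn from known UV/clock signature mixtures
with cluster-structured burden, panel regions and survival outcomes with
a specified hazard ratio — so the entire pipeline is testable end to end
with exact ground truth and no downloads. The packaged reference
signatures (`melasig.references`) are *synthetic* COSMIC-like stand-ins;
point `read_signature_matrix` at a real COSMIC v3 TSV for production use.

## Worked example

```python
import numpy as np
from melasig import (CohortSpec, simulate_cohort, build_context_matrix,
                     filter_min_snv, nmf_multistart, identify_uv_signature,
                     kmeans_exposures, cosine_similarity, cox_fit, logrank_test)

bundle = simulate_cohort(CohortSpec(n_samples=120, seed=7))
matrix = filter_min_snv(build_context_matrix(bundle["catalog"], bundle["genome"]), 5)
result = nmf_multistart(matrix, rank=2, nrun=10, seed=7)
uv = identify_uv_signature(result)
print(f"cos(SigB, generating UV signature) = "
      f"{cosine_similarity(result.signatures[:, uv], bundle['signatures'].uv_like):.3f}")

clusters = kmeans_exposures(result, seed=0, uv_index=uv)
truth = bundle["truth"].loc[matrix.index, "cluster"].to_numpy()
print(f"cluster sizes: UV-high={np.sum(clusters.labels == 'UV-high')}, "
      f"UV-low={np.sum(clusters.labels == 'UV-low')}")
print(f"agreement with simulation truth: {(clusters.labels == truth).mean():.3f}")

clinical = bundle["clinical"].loc[matrix.index]
fit = cox_fit(clinical, ["cluster"])
lo, hi = fit.ci95["cluster"]
print(f"UV-low hazard ratio = {fit.hr['cluster']:.2f} (95% CI {lo:.2f}-{hi:.2f})")
```

prints

```
cos(SigB, generating UV signature) = 0.999
cluster sizes: UV-high=99, UV-low=21
agreement with simulation truth: 1.000
UV-low hazard ratio = 2.43 (95% CI 1.36-4.32)
```

i.e. on a 120-sample synthetic cohort the extracted SigB is essentially
the generating UV profile, every sample is assigned to its true cluster,
and the Cox model recovers the simulated prognostic disadvantage of the
UV-low group (generating hazard ratio 2.2, inside the confidence
interval).

## Command line

```bash
melasig simulate --n-samples 200 --seed 0 --out sim/
melasig extract  --maf sim/cohort.maf --genome sim/genome.fa \
                 --rank 2 --nrun 100 --seed 42 --out extract/
melasig refit    --matrix contexts.tsv --signatures cosmic_v3.tsv --out refit.tsv
melasig panel    --maf sim/cohort.maf --genome sim/genome.fa --bed sim/panel.bed \
                 --signatures extract/signatures.tsv --out panel/
melasig survival --clinical sim/clinical.tsv --out surv/
```

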