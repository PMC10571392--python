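# metasig

Analytical machinery for two-cohort case/control gut-metagenome studies,
built around end-stage renal disease (ESRD) and the chronic-kidney-disease
(CKD) severity spectrum — for microbiome researchers who have already
assembled and binned their metagenomes and need the downstream statistics
as tested, reusable code:

* **MAG catalog rules** — quality score `QS = completeness − 5 ×
  contamination`, MIMAG high/medium tiering, catalog filtering
  (completeness > 70%, contamination < 5%, QS > 60), within-sample bin
  merging (depth ± 10%, GC ± 2 points, identical species label),
  greedy dereplication at 95% nucleotide identity with highest-QS
  representatives, and taxon abundance roll-ups by summation.
* **Cross-cohort signature discovery** — per-cohort two-sided Wilcoxon
  rank-sum tests with pseudocounted fold changes, Fisher-combined p-values
  (χ², 4 df), and the two-criterion call: q < 0.2 and fold change > 1.2 in
  each cohort with coherent direction, plus combined q < 0.05; rank-linear
  adjustment for sex, age and BMI.
* **Genome-centric function** — a KEGG-style module-definition parser and
  completeness scorer, Fisher exact occurrence/completeness contrasts
  between enriched species sets, a versioned biosynthesis-capability rule
  table (SCFAs, secondary bile acids, uremic-toxin precursor enzymes), and
  gene-to-function abundance summation.
* **Toxin explainability** — random-forest regression of serum uremic
  toxins (IS, PCS, PAG, TMAO) on species abundances with leave-one-out
  cross-validated R², out-of-bag IncMSE importance, sequential top-k
  selection, and cross-cohort transfer.
* **Community statistics** — Bray–Curtis distances, PCoA, PERMANOVA
  (marginal/sequential, permutation and exhaustive modes), Tracy–Widom axis
  screening, alpha diversity, and the Mantel test.
* **Classification** — random-forest case/control models with DeLong 95%
  CIs, cross-cohort transfer, CKD-severity generalization, and
  signature-total severity trends.
* **Synthetic cohorts** — a first-class generator that plants differential
  species with a severity gradient, cohort-level compositional shifts,
  toxin signals with known variance fractions, and direction-coherent
  function matrices, so every stage can be scored against recoverable
  ground truth.

## Worked example

```python
from metasig import (SimulationConfig, simulate_all, discover_signatures,
                     bray_curtis, permanova)

cfg = SimulationConfig(seed=3)          # 2 cohorts, 300 species, 100/arm
data = simulate_all(cfg)

sig = discover_signatures(data["abundance"], data["metadata"])
called = sig[sig["call"] != "none"]
planted = set(data["truth"].differential_species)
print(len(called), "signatures called of", len(sig), "species")
print("sensitivity:",
      round(len(set(called.index) & planted) / len(planted), 3))
print("empirical FDR:",
      round(len(set(called.index) - planted) / len(called), 3))

dist = bray_curtis(data["abundance"])
(res,) = permanova(dist, data["metadata"]["group"], n_perm=199, seed=0)
print(f"PERMANOVA group: R2={100 * res.r2:.2f}% p={res.p:.4f}")
```

Output:

```
47 signatures called of 300 species
sensitivity: 0.94
empirical FDR: 0.0
PERMANOVA group: R2=0.95% p=0.0050
```

Of the 50 planted disease-associated species, 47 are recovered with zero
false calls, and disease status explains about one percent of the
community-level Bray–Curtis variance with the smallest attainable
permutation p — the same qualitative picture a real two-cohort case/control
gut-metagenome study reports.

The command line mirrors the library:

```bash
metasig simulate --seed 7 --out sim/
metasig signatures --abundance sim/abundance.tsv --metadata sim/metadata.tsv \
    --out signatures.tsv
metasig ordinate --abundance sim/abundance.tsv --metadata sim/metadata.tsv \
    --factors group,cohort --nperm 999 --seed 7 --out ord/
metasig run --config run.yaml   # full pipeline with a reproducible manifest
```

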