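# pdl1time

PD-L1 scoring, tumor-immune-microenvironment phenotyping, inter-algorithm
concordance and survival analysis for muscle-invasive bladder cancer (MIBC)
cohorts.

## The problem

PD-L1 testing gates access to immune-checkpoint inhibitors in urothelial
cancer, but the three drug-linked scoring algorithms dichotomize PD-L1 in
different ways and therefore select different "PD-L1 positive" patient
populations:

| algorithm | score | cut-off (inclusive) |
|---|---|---|
| CPS10 (pembrolizumab) | CPS = 100·(PD-L1⁺ TC + PD-L1⁺ IC) / viable TC, capped at 100 | CPS ≥ 10 |
| Ventana IC5% (atezolizumab) | % tumor area covered by PD-L1⁺ immune cells | IC ≥ 5% |
| TCarea25%/ICarea25% (durvalumab) | % PD-L1⁺ tumor cells OR % PD-L1⁺ immune-cell area | either ≥ 25% |

This package implements those algorithms on multi-assay readouts (SP142,
SP263, 22C3, 28-8), builds per-patient **consensus scores** (median across
assays; SP142 excluded from TC-dependent scores because of its reduced TC
sensitivity), clusters patients into four tumor immune phenotypes from
spatially resolved immune-marker densities, quantifies how well each
algorithm covers each phenotype, and models phenotype-linked survival.

The analytical core:

- **ICIS** (immune cell infiltration score): per patient, the mean of the
  Z-scores of log2-transformed median densities of 9 immune markers (CD3,
  CD8, FOXP3, CD56, CD68, CTLA-4, LAG3, PD-1, GZMB) in 2 regions (invasion
  front, tumor center).
- **Phenotyping**: WPGMA (weighted average-link) hierarchical clustering on
  Euclidean distances over the 18 density Z-features plus 4 Z-scored PD-L1
  consensus scores, cut at k = 4, labeled *Evasion* (high PD-L1 TC),
  *Inflamed: High* (high PD-L1 IC, high infiltration), *Inflamed: Low*
  (moderate infiltration, low PD-L1) and *Uninflamed*.
- **Concordance**: pairwise overall percentage agreement (OPA), the exact
  8-region Venn partition of the three statuses, phenotype-coverage tables,
  and a CD8/sTILs **rescue rule** (CD8 ≥ 201 cells/mm² OR sTILs ≥ 10%) that
  recovers inflamed tumors scored PD-L1-negative.
- **Survival**: Kaplan–Meier curves with 5-year rates at 60 months, k-group
  log-rank tests, reverse-KM median potential follow-up, and multivariable
  Cox proportional-hazards models adjusted for pT, pN, lymphovascular
  invasion, age, gender, margin status, adjuvant chemotherapy and grade.

Since no patient-level cohort is publicly deposited, the package ships a
**synthetic cohort generator** (four separable immune phenotypes, log-normal
core densities, assay noise with SP142 TC attenuation, phenotype-linked
exponential survival) and **fixtures** that reconstruct the published
cross-tabulated counts exactly.

## Worked example

```bash
pdl1time simulate --n 193 --seed 1 --out demo/
pdl1time run --densities demo/densities.csv --assays demo/assays.csv \
             --annotations demo/annotations.csv --out demo_out/
```

prints

```
n=193  positives: CPS10=57 VentanaIC5=47 TC/IC25=45 union=68
outputs written to demo_out
```

i.e. on this simulated 193-patient cohort, 57 patients are PD-L1 positive by
CPS10, 47 by Ventana IC5%, 45 by TCarea25%/ICarea25%, and 68 by at least one
algorithm. `demo_out/` then contains `consensus.csv`, `status.csv`,
`phenotypes.csv` (cluster id, phenotype label and ICIS per patient),
`venn.csv`, `concordance.json` and `survival_summary.json`, the last holding
per-phenotype 5-year DSS/DFS rates with log-rank p-values — for this seed,
5-year DSS of 0.87 for *Inflamed: High* versus 0.23/0.22 for *Evasion* /
*Uninflamed* (log-rank p ≈ 2.5·10⁻⁷), reproducing the prognostic spread the
phenotypes are designed to carry.

The same steps are available as library calls:

```python
from pdl1time import SimulationConfig, generate_cohort, run_pipeline

cohort = generate_cohort(SimulationConfig(n_patients=193, seed=1))
result = run_pipeline(cohort)
print(result.venn.algorithm_totals())   # {'cps10': 57, 'ventana_ic5': 47, 'tcic25': 45}
print(result.survival_summary["dss"]["five_year_rates"])
```

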