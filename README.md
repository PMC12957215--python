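# hepatlas

Stage-resolved immune analysis of chronic liver disease (CLD)
transcriptomics: a reusable Python implementation of the computations
behind a macrophage / T-cell atlas spanning healthy liver, MASH,
cirrhosis and hepatocellular carcinoma (HCC), for computational
biologists who want each analysis step as a tested, scriptable unit
rather than a one-off notebook.

## What it computes

* **Quality control & signature genes** — the standard single-cell
  filters (mitochondrial fraction < 10%, 200–4000 detected genes, genes
  in > 3 cells), one-vs-rest Wilcoxon differential expression with
  class-specific thresholds (macrophages: `p_adj < 0.01`, `pct1 > 0.5`,
  `pct2 < 0.5`, `avg_log2FC > 1`; T cells: `p_adj < 0.01`,
  `avg_log2FC > 0.5`), and entropy-difference specificity ranking
  `D = log2 K − H(p)` over the K cluster means.
* **Cell-state scores** — rank-based recovery-curve AUC of curated
  functional gene sets (M1/M2/angiogenesis/phagocytosis;
  naive/activation/cytotoxicity/exhaustion) per cell.
* **Cohort scores** — single-sample GSEA enrichment (ES) of a subtype
  signature, corrected for immune abundance (IS) and cytotoxic-T
  deviation (CA):
  `Mscore = ES / IS`, `Tscore = ES · CA / IS`.
* **Survival** — Kaplan–Meier / log-rank stratification at a score
  cutpoint with an age-adjusted Cox hazard ratio, plus a univariate Cox
  screen over signature genes with BH correction.
* **Composition** — per-stage cell-type proportions with
  bias-corrected and accelerated (BCa) bootstrap confidence intervals
  and stage contrasts.
* **FISH quantification** — per-channel segmentation, radius-based cell
  typing (macrophage markers within 20 μm diameter of a nucleus, T-cell
  markers within 10 μm), pairwise distances, nearest-tumor-cell
  distances and double-positive pair detection.
* **Synthetic data** — negative-binomial single-cell counts with
  planted markers, survival cohorts with a planted signature-burden
  hazard, and FISH scenes with exact geometry, so every stage can be
  validated against known ground truth.

## Worked example

Simulate a 300-sample cohort with a planted macrophage-signature burden
driving survival (hazard ratio 2 per SD of burden), score it, and test
the stratification:

```python
import numpy as np
from hepatlas import CohortSimConfig, GeneSet, simulate_cohort
from hepatlas.cohort import score_cohort
from hepatlas.survival import stratify_and_test

signature = tuple(f"g{i:05d}" for i in range(40))
cohort = simulate_cohort(CohortSimConfig(
    n_samples=300, signature_genes=signature,
    planted_hazard_ratio=2.0, seed=5))

rng = np.random.default_rng(0)
immune_panel = [GeneSet(f"imm{j}", [f"g{i:05d}" for i in
                rng.choice(np.arange(100, 2000), 30, replace=False)])
                for j in range(3)]
scores = score_cohort(cohort.expression,
                      GeneSet("SPP1_Mac", list(signature)), immune_panel)
res = stratify_and_test(cohort, scores["Mscore"], score_name="Mscore")
print(f"log-rank p = {res.logrank_p:.2e}, "
      f"age-adjusted HR (high vs low Mscore) = {res.hr:.2f}")
```

Output:

```
log-rank p = 5.87e-08, age-adjusted HR (high vs low Mscore) = 2.13
```

The high-Mscore half of the cohort dies at roughly twice the hazard of
the low half — the planted burden, recovered through the full
enrichment-scoring and survival machinery (the median-split group HR is
attenuated below the noiseless ≈3.0 because Mscore is a rank-based
proxy of the burden; see `docs/methods.md`).

The same stages are available from the shell:

```bash
hepatlas simulate --kind sc --out sim/ --seed 1
hepatlas qc --in sim/ --out qcd/
hepatlas markers --in qcd/ --out markers/
hepatlas fish-quant --scene scene.tiff --out quant/ --mac-diameter 20 --t-diameter 10
```

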