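# aadkit

Multi-modal tissue characterization for acute type-A aortic dissection.

When a dissected aorta is repaired, the resected wall contains three
distinct regions — the false lumen (FL), the dissection flap (FP) and the
true lumen (TL) — whose extracellular matrix and mechanics differ in ways
that matter for understanding how dissections progress. `aadkit`
implements, as a tested and reusable pipeline, the analysis chain used to
characterize such tissue from three complementary data streams:

- **REIMS / iKnife spectra** — ambient mass spectrometry of the surgical
  diathermy aerosol. Each cauterization produces a *burn event* (10–30 s of
  elevated total ion current at a 1 Hz scan rate); the pipeline detects
  events, converts each uneven burn into the canonical 35-scan
  pseudo-Gaussian TIC trace (burn spanning 12 scans, maximum at scan 18,
  total ion current conserved), applies leu-enkephalin lockmass correction,
  and bins the consensus spectrum over m/z 50–1200.
- **Histology** — Verhoeff–van Gieson (VVG) and Picrosirius Red (PSR)
  stained sections. Collagen is scored per pixel by the weighted index
  `R/50 − G/20 + B/30` (collagen hues score above the nominal threshold
  1.0), elastin by equally-weighted darkness `1 − (R+G+B)/765` thresholded
  at 0.5; percentage areas are pixel-count ratios against a blue-channel
  tissue mask, with PSR-based threshold calibration and threshold-variation
  error bars.
- **Biomechanics / biochemistry** — shear storage and loss moduli (G′, G″),
  collagen, elastin and GAG content, plus age and indexed aortic size.

On top sit the chemometrics and statistics of the study design:

- PCA on mean-centred, unit-scaled data;
- PLS-DA (one-hot classes, NIPALS PLS2) with stratified 80/20 train/test
  splits, component count chosen by 2-fold cross-validation on the training
  part, 50 repeats with averaged accuracy/precision/recall/F1, and feature
  refinement keeping m/z bins with VIP mean **and** median > 1
  (VIP_j = √(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a));
- FL sub-structure by Ward hierarchical clustering with multiscale
  bootstrap: per-node bootstrap probabilities BP_r at scales r ∈ 0.5–1.4
  are combined through the probit fit Φ⁻¹(1−BP_r) = v√r + c/√r into the
  approximately unbiased support AU = 1 − Φ(v−c); nodes with AU > 0.90
  count as genuine clusters;
- Kruskal–Wallis with Dunn post hoc z tests and Holm adjustment for
  three-group comparisons; Mann–Whitney U (exact by enumeration at small n)
  between identified FL clusters.

No patient data ships with the package. A first-class synthetic-data module
generates cohorts with known ground truth — 10 FL / 10 FP / 6 TL samples,
FL spectra drawn from three planted sub-templates, stained sections with
pixel-exact painted stain fractions — so every stage is testable end to end.

## Worked example

```sh
aadkit run-all --seed 17 --out demo_run
```

runs the full study analogue on synthetic data (about two minutes on one
CPU). With seed 17 it prints, among other things:

```
"reims_preprocess": { "events": [ {"trace_length": 35, "burn_span": 12,
                                   "peak_index": 18, "tic_conserved": true}, ... ] }
"pca":   { "explained_variance_ratio": [0.307, 0.213, 0.187], ... }
"plsda": { "mean_metrics": {"accuracy": 1.0, "precision": 1.0, ...},
           "n_selected_features": 279, "roc_auc_fl_vs_rest": 1.0 }
"fl_clustering": { "n_stable_clusters": 3,
                   "clusters": [["FL01","FL04","FL07","FL10"],
                                ["FL02","FL05","FL08"],
                                ["FL03","FL06","FL09"]] }
```

Reading: every synthetic burn event satisfied the canonical trace contract;
the synthetic class separation is strong enough that the repeated PLS-DA
evaluation is perfect (real surgical cohorts are far noisier); and Ward +
multiscale bootstrap recovered exactly the three planted FL sub-groups at
AU > 0.90 — `FL01/FL04/FL07/FL10` etc. are precisely the samples generated
from each latent sub-template. Per-stage tables (PCA scores, Dunn tests,
VIP profile, ROC points, cluster support, histology fractions and
Mann–Whitney comparisons) land in `demo_run/`.

Each stage is also available separately: `aadkit simulate`,
`aadkit reims-preprocess`, `aadkit histology`, `aadkit classify`,
`aadkit cluster`, `aadkit stats`. Library use mirrors the CLI:

```python
from aadkit import synthetic, cluster

sset, _ = synthetic.generate_spectrum_set(synthetic.CohortConfig(seed=17))
fl = sset.X[sset.tissue_type == "FL"]
dend, supports = cluster.multiscale_bootstrap(fl, n_boot=1000, seed=1)
print(cluster.stable_clusters(dend, supports).n_clusters)  # 3
```

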