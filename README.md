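# tdscreen

Transcriptional disease signature (TDS) drug screening for probe-count
assays of the NanoString nCounter type.

Phenotypic drug screens in small animal models need a scorable phenotype.
`tdscreen` uses a *gene-expression* phenotype: a weighted panel of genes
whose expression separates diseased from healthy individuals (e.g. a
transgenic melanoma fish line vs wild type). A candidate compound is scored
by whether it shifts that signature back toward the healthy state. The
package is for scientists running such screens: it normalizes probe counts,
builds and validates the signature panel, scores treatments, and calibrates
the significance thresholds — plus a synthetic-data generator with known
ground truth so the whole pipeline is testable end to end.

## The statistics at the core

For a treatment-vs-vehicle comparison, each signature gene *i* gets a state
x_i = +1 if its log2 fold change matches the reference disease direction
and −1 if it contradicts it. Under the null that both states are
equiprobable,

    Z = (N₊ − N₋) / √N            (weighted:  Z = Σ wᵢxᵢ / √(Σ wᵢ²))

is asymptotically standard normal; Z ≥ 2 reads as disease-activating and
Z ≤ −2 as disease-repressing. A rank-based Kolmogorov–Smirnov-style score
captures *how much* genes move: with signature genes ranked by treatment
log2FC and a tag set at positions V(1) < … < V(t) of n,

    a = max_j [ j/t − V(j)/n ],   b = max_j [ V(j)/n − (j−1)/t ],
    ks = a if a > b else −b

computed for the reference up-genes (ks_up) and down-genes (ks_down);
the drug score is S = ks_up − ks_down, set to 0 when both share a sign.
Thresholds (|Z| ≥ 2, |S| ≥ 0.27) are calibrated by scoring all
disease/healthy sample pairs ("must read as activated") against randomized
lists resampled from the pooled fold-change values ("must read as noise").

Panel construction: per-gene log2FC, Welch t with Benjamini–Hochberg FDR,
and ROC-AUC gates (|log2FC| ≥ 0.7, FDR ≤ 0.05, AUC ≥ 0.7), two-test
cross-validation, and AUC-based weights (2 for genes with AUC > 0.8 in both
tests, else the larger AUC). See `docs/methods.md` for the full model.

## Worked example

The repository ships a demo configuration that simulates a reduced study
(12 + 12 cohort plus a 10 + 10 repeat), normalizes it, builds the panel,
calibrates thresholds, and scores two simulated compounds:

```sh
tds run-all --config examples/demo.yaml --out-dir demo_out
```

From `demo_out/run_log.json` of that run:

* `panel_audit: {'n_candidates': 97, 'n_preliminary': 82, 'n_validated': 82,
  'n_weight_2': 62}` — 82 of the 97 simulated signature genes pass the
  statistical gates at this cohort size and survive cross-validation.
* `calibration: fp_rate_z 0.05, fn_rate_z 0.0, mean_disease_z 7.18,
  mean_null_z -0.19` — all 144 disease/healthy pairs score as activated,
  5% of the 200 randomized lists cross |Z| ≥ 2, and the reference /
  model-compound anchors are ±9.06.
* `score_full_reversal.json: z -8.718, n 82, n_plus 0, n_minus 82,
  s -1.012` — the simulated full-reversal compound flips every panel gene
  against the disease direction: a strong repressor call (Z ≤ −2,
  S ≤ −0.27).
* `score_inert.json: z 0.677, s 0.293` — the inert compound stays inside
  the Z threshold; its S illustrates why S is best read as an effect-size
  companion to Z (see the calibration notes in `docs/methods.md`).

Every stage is also a subcommand (`tds simulate / normalize / build-panel /
score / calibrate`) and a plain library call:

```python
import tdscreen as tds

cohort = tds.simulate_cohort(tds.SimulationConfig(seed=123))
normalized, factors = tds.normalize_pipeline(cohort.table, cohort.annotation)
panel = tds.panel_from_truth(cohort.truth.genes)  # oracle reference panel
result = tds.calibrate(normalized, cohort.annotation, cohort.sheet, panel,
                       n_null=400, seed=7)
print(result.summary()["fp_rate_z"], result.summary()["mean_disease_z"])
```

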