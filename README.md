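# combiscore

Sensitivity and synergy scoring for drug-combination screens built around
the cost-effective *cross design*: instead of a full factorial dose matrix,
only one row and one column — each anchored at the partner drug's IC50 —
are used to characterize a drug pair.

The package provides:

* **CSS** (combination sensitivity score): each cross arm is fitted with a
  four-parameter log-logistic curve on log10 concentration; the area under
  the curve is normalized against a 10% noise floor (`inh_min`) and
  reported on a 0–100 percent-inhibition scale. The two arms give CSS1 and
  CSS2, averaged into CSS, with a consistency QC filter on |CSS1 − CSS2|
  (default threshold 10).
* **S synergy scores** (`S_sum`, `S_max`, `S_mean`): CSS minus the sum /
  max / mean of the two normalized monotherapy AUCs, all on the same
  percent-inhibition scale.
* **Reference synergy models** on full dose-response matrices — HSA, Bliss,
  Loewe (summed-dose evaluation) and ZIP (curve-smoothed Bliss) — averaged
  over all combination cells, plus the consensus synergistic/antagonistic
  labelling (all four scores beyond ±5).
* **Featurization and a CV harness**: drug-pair features by bitwise OR of
  binary target/fingerprint profiles, SEA prediction filtering
  (z > 20, Tanimoto > 0.4, p < 0.01), and a repeated 70/30 + 10-fold
  cross-validation harness with pluggable scikit-learn regressors.
* **A synthetic simulator** that generates dose-response matrices with
  known monotherapy curves, an injectable Bliss/HSA/Loewe interaction of
  strength `delta`, and Gaussian replicate noise — so every scoring path is
  testable without external data.

## CLI

All subcommands read/write plain CSV and write a `*.manifest.json` next to
each output recording the tool version, configuration and input digests.

```bash
# simulate three replicate-noise blocks with injected synergy
combiscore simulate --blocks 3 --delta 0.1 --seed 7 -o sim.csv

# CSS per block (IC50 anchors estimated from monotherapy margins,
# or supplied via --ic50-table drug,cell_line,ic50)
combiscore css sim.csv --inh-min 0.10 --qc-threshold 10 -o css.csv

# full scoring: CSS + S scores + HSA/Bliss/Loewe/ZIP + consensus label
combiscore synergy sim.csv -o synergy.csv

# sensitivity-synergy prioritization at the 75th percentile of both axes
combiscore prioritize synergy.csv --quantile 0.75 --s-variant sum -o hits.csv

# CSS predictability from combined drug features
combiscore predict-css --features features.csv --css-table css_table.csv \
    --repeats 20 --seed 0 -o metrics.json
```

Input layout (long format, configurable column names via the library's
`FormatSpec`): `block_id, drug_row, drug_col, conc_r, conc_c, response,
cell_line, replicate`, with `response` either percent inhibition (default)
or percent viability (`--response-kind viability`; converted as
`100 - viability`). Zero concentrations encode the monotherapy margins.

## Library sketch

```python
import combiscore as cs

spec = cs.SimSpec(delta=0.15, noise_sd=0.066, n_replicates=4, seed=1)
matrix = cs.build_matrix(cs.simulate_matrix(spec))
result = cs.score_block(matrix)        # CSS, S scores, reference scores
print(result.css, result.s_sum, result.consensus)
```

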