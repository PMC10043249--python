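# planqa

Unsupervised anomaly detection for radiotherapy treatment-plan parameter
tables. A symmetric fully-connected autoencoder is trained on the mixed
one-hot/continuous encoding of per-field plan parameters (segments, SSD,
collimator jaws, gantry angle, monitor units); plans are scored by a
composite reconstruction error `L = BCE + λ·MSE` (BCE over one-hot
dimensions, MSE over continuous ones) and flagged by a threshold chosen so
that every known abnormal plan is caught (TPR == 1) with the lowest
achievable false-positive rate. Four classical detectors (LOF, HDBSCAN,
OC-SVM, PCA reconstruction error) are provided behind the same scoring
interface for comparison, together with a synthetic plan generator that
stands in for clinical data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (including a
~2-minute depth-6 benchmark training run).

## Library overview

| module                | purpose |
|-----------------------|---------|
| `planqa.schema`       | per-field plan feature schema, CSV/JSON loading, one-hot + min-max encoding with a binary/continuous column mask |
| `planqa.autoencoder`  | numpy MLP autoencoder (leaky ReLU, dropout, Adam), composite BCE+λ·MSE loss, per-plan error scores |
| `planqa.detection`    | TPR==1 / quantile thresholding, confusion metrics, ROC/AUC |
| `planqa.baselines`    | LOF, HDBSCAN, OC-SVM, PCA scores + grid search |
| `planqa.synthetic`    | protocol-driven normal-plan generator and anomaly injection |
| `planqa.experiments`  | depth sweep, λ sweep, baseline comparison |

```python
from planqa import (AEConfig, GenConfig, encode_table, fit_autoencoder,
                    generate_dataset, sample_errors, select_threshold_tpr1)

table, _ = generate_dataset(GenConfig(seed=0))      # 557 normal + 19 abnormal
data = encode_table(table)                          # 30 raw -> 58 encoded dims
result = fit_autoencoder(data, AEConfig(depth=6))
scores = sample_errors(result.model, data, 0.99)
threshold = select_threshold_tpr1(scores, table.label_array)
```

## CLI

```bash
planqa generate --seed 0 --out data/                 # plans.csv + manifest.yaml
planqa train --data data/plans.csv --seed 0 --out run/
planqa score --data data/plans.csv --model run/model.json --out run/
planqa threshold --scores run/scores.csv --policy tpr1 --out run/
planqa evaluate --scores run/scores.csv --out run/
planqa sweep-depth --out sweeps/                     # depth sweep, 10 repeats
planqa sweep-lambda --out sweeps/                    # λ ∈ {0.1, 0.5, 0.9, 0.99}
planqa compare --out cmp/                            # AE vs 4 grid-searched baselines
```

All subcommands accept `--config <yaml>` and `--seed`; tables are emitted
as CSV + JSON.

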