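# neurograph

Construction, connectivity analysis, and classification of functional
brain networks from ROI time series:

- **fc_network** — Pearson functional-connectivity matrices from per-subject
  ROI signal matrices, thresholded into binary adjacency matrices, assembled
  into graphs whose node features are the continuous correlation profiles.
- **graph_connectivity** — transitive closure via the Warshall Boolean
  recursion, per-graph connectedness, and cohort connectivity ratios
  (connected / unconnected counts per threshold).
- **dgcnn** — a deep graph convolutional classifier written in pure NumPy:
  four degree-normalized graph-conv layers with tanh, channel-wise
  concatenation into a SortPooling layer, a 1-D conv / max-pool / 1-D conv
  head with ReLU, dense layer, dropout 0.5, 2-way softmax; trained with
  binary cross-entropy and Adam, with hand-derived analytic gradients
  (verified against central finite differences).
- **evaluation** — confusion-matrix metrics (ACC/SEN/SPE/PRE/F1 in percent),
  ROC AUC (Mann-Whitney, ties at 1/2), stratified 90/10 holdout, stratified
  k-fold cross-validation, and leave-one-site-out evaluation.
- **synthetic_data** — multi-site two-group cohorts of ROI time series with
  a controlled, planted group difference in block correlation structure, so
  the whole pipeline is testable without access-restricted clinical data.
- **cli_io** — manifest/TSV cohort IO, YAML configs, checkpoints, logging,
  and the end-to-end pipeline.

## CLI

```sh
# generate a synthetic cohort (manifest.csv + per-subject signal TSVs)
neurograph simulate --out data/cohort --n-per-group 100 --n-rois 20 \
    --timepoints 200 --delta 0.3 --sites 4 --seed 0

# per-subject FC matrices, adjacency matrices, edge lists (0-based indices)
neurograph build-networks --manifest data/cohort/manifest.csv \
    --out data/networks --threshold 0.3

# connectivity counts/ratios per threshold
neurograph connectivity --manifest data/cohort/manifest.csv \
    --out connectivity.csv --thresholds 0.2,0.3,0.4

# train on a stratified 90/10 holdout
neurograph train --manifest data/cohort/manifest.csv --out run/ \
    --threshold 0.3 --learning-rate 0.001 --epochs 100 --batch-size 50 --seed 0

# cross-validated evaluation (kfold or loso)
neurograph evaluate --manifest data/cohort/manifest.csv --out metrics.csv \
    --protocol kfold --kfolds 10 --epochs 30 --seed 0

# end-to-end pipeline from a YAML config
neurograph run --config config.yaml
```

A pipeline YAML config mirrors `neurograph.cli_io.PipelineConfig`:

```yaml
manifest: data/cohort/manifest.csv
out_dir: run/
threshold: 0.3
protocol: kfold          # holdout | kfold | loso
kfolds: 10
split_seed: 0
connectivity_thresholds: [0.2, 0.3, 0.4]
dgcnn:
  conv_channels: [32, 32, 32, 1]
  learning_rate: 0.001
  epochs: 100
  batch_size: 50
  dropout_rate: 0.5
  seed: 0
```

Runs are deterministic given the seeds in the config; the emitted
`run_manifest.json` records the config, seeds, and a cohort fingerprint
sufficient to rerun an identical experiment.

## Data conventions

- Cohort manifest: CSV with columns `subject_id, path, label, site_id`;
  labels are `MDD`/`NC` (case-insensitive). Paths are relative to the
  manifest.
- Signal files: TSV, one row per ROI, one column per time point.
- All node indices in outputs are 0-based.
- Edges are defined by the signed correlation rule `corr >= threshold`
  (inclusive); pass `--absolute` to threshold on `|corr|` instead.
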