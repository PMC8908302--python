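# proxnet

Extraction of multiple latent social subnetworks from long-term wearable
proximity logs.

Timestamped device-detection records are binned into an epoch-by-dyad
contact matrix **Y** (rows: fixed wall-clock time bins, default 30
minutes; columns: unordered participant pairs).  **Y** is factorized as
**Y ≈ H U** under nonnegativity with the Frobenius objective
(Lee–Seung multiplicative updates): each factor couples a temporal
activity profile (column of **H**) with a weighted tie pattern over
dyads (row of **U**).  The rank is chosen from a table of per-rank
residual sums of squares and consensus-clustering cophenetic correlation
coefficients.  Each factor is rendered as an undirected weighted
participant graph; eigenvector centralities (max-normalized, then
log-transformed) feed a correlation analysis against reliability-scored
survey composites (PCA-loading item retention, Cronbach's α, McDonald's
ω).  A synthetic-data module plants known subnetworks (event-spike,
diurnal, weekday-hub schedules) so every stage is testable end to end
without access to real data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: epoch
accounting for the study window, NMF objective monotonicity and
reference-implementation equivalence, cophenetic correctness against a
from-scratch dendrogram oracle, centrality against dense
eigendecomposition, planted-subnetwork recovery on the packaged default
scenario, psychometric closed forms, and exact detection-log round
trips.

## CLI

```sh
# generate a synthetic dataset (detection log, roster, survey, truth)
proxnet simulate --seed 1 --out scratch/sim

# build Y and fit / select the rank
proxnet fit --config config.yaml --k 3 --out scratch/fit
proxnet fit --config config.yaml --k-range 2 6 --out scratch/fit

# graphs, centralities, descriptives, flagged correlation table
proxnet report --model scratch/fit/model --roster scratch/sim/roster.csv \
    --survey scratch/sim/survey.csv --out scratch/report
```

A YAML config supplies paths plus `epoch`, `nmf`, `centrality`,
`survey` and `scenario` sections; flags override config values and each
run writes a `manifest.json` with the seed and config hash.  Exit
codes: 0 success, 1 config error, 2 I/O error, 3 numerical failure.

Example config:

```yaml
paths:
  log: scratch/sim/detections.csv
  roster: scratch/sim/roster.csv
epoch:
  epoch_minutes: 30
nmf:
  k_range: [2, 6]
  n_starts: 10
  n_runs: 30
  seed: 1
```

## Layout

- `src/proxnet/io.py` — detection-log/roster reading, windowing,
  carry-day inclusion rule
- `src/proxnet/contacts.py` — epoch grid, dyad index, contact matrix,
  Matrix Market persistence
- `src/proxnet/nmf.py` — Frobenius NMF, multistart fits, consensus
  matrix, cophenetic coefficient, rank selection
- `src/proxnet/graphs.py` — per-factor graphs, eigenvector/log
  centralities, activity time series
- `src/proxnet/survey.py`, `src/proxnet/codebook.py` — scale scoring
  (PCA loadings, α, ω, composites), descriptives, flagged Pearson
  correlation tables
- `src/proxnet/simulate.py` — planted-truth generator, observation
  models, detection-log emission, recovery scoring, synthetic surveys
- `src/proxnet/cli.py` — `proxnet simulate|fit|report`
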