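# avehybrid

Unsupervised anomaly detection for biomedical and other real-valued
tabular data, built around a **hybrid autoencoder / variational
autoencoder (AVE)**: a deterministic encoder and a variational encoder
read the same input, their latents are fused (averaged by default), and a
single shared decoder reconstructs the row. The model is trained only on
normal samples; rows it reconstructs poorly are anomalies.

The training objective is

    total = MSE(x, x̂) + λ · KL(N(μ, e^σ) ‖ N(0, I)),   λ = 0.1

with the variational latent sampled by the reparameterization trick
`z₂ = μ + e^σ · ε`, `ε ~ N(0, I)`. At test time each row's anomaly score
is its mean squared reconstruction error, and a **dynamic threshold**
derived from an assumed contamination rate `c` (the dataset outlier
fraction divided by 3) flags the top `⌊N·c⌋` scores: sort the `N` test
errors ascending and place the threshold where the expected anomalies
begin.

The package ships the full experiment surface around the model: dataset
loaders (CSV, `.npz`, ODDS-convention `.mat`), the preprocessing chain
(stratified 60/40 split, MinMax scaling fitted on training rows, normal-
only filtering), branch ablations (`ae_only` / `vae_only`), a KL-weight ×
latent-fusion sensitivity grid, a label-noise robustness harness,
evaluation metrics (precision, TPR/FPR, ROC-AUC with 10-trial averaging),
and a synthetic benchmark generator with planted outliers.

## Worked example

```python
from avehybrid import AVEDetector, generate_synthetic

ds = generate_synthetic(n=2000, d=10, contamination=0.05,
                        mechanism="shifted_cluster", separation=8.0, seed=0)
res = AVEDetector(ds).fit(seed=0)
print(res.summary())
```

prints

```
AVE hybrid anomaly detector — fit summary
=============================================
dataset:        synthetic-shifted_cluster (n=2000, d=10)
branch/fusion:  hybrid / averaged
latent dim:     3   hidden: [64, 32]
kl weight:      0.1   reparam: paper
seed:           0
epochs run:     100 (best 99, early stop: False)
final val loss: 0.017319
contamination:  0.016667
threshold:      0.100782
test flagged:   13 of 800
precision:      1.0000
TPR / FPR:      0.3250 / 0.0000
ROC-AUC:        1.0000
confusion:      TP=13 FP=0 FN=27 TN=760
```

Reading this: the 2000-row synthetic benchmark has 100 planted outliers
(5%), so the contamination estimate is 0.05/3 ≈ 0.0167 and the threshold
flags ⌊800 × 0.0167⌋ = 13 of the 800 test rows. All 13 flagged rows are
true outliers (precision 1.0) and the error ranking separates the classes
perfectly (ROC-AUC 1.0); TPR is capped near c/f = 1/3 by the deliberately
conservative contamination rule, which trades recall for a low false-alarm
rate. `res.score()` exposes the per-row errors and predictions,
`res.save(path)` writes a versioned JSON checkpoint, and
`res.plot_history()` / `res.plot_errors()` draw the fit diagnostics.

The same pipeline is scriptable from the shell:

```bash
ave simulate --n 2000 --d 10 --contamination 0.05 --seed 1 --out toy.csv
ave train    --data toy.csv --seed 1 --out model.ckpt
ave score    --data toy.csv --model model.ckpt --seed 1 --out scores.csv
ave eval     --data toy.csv --trials 10 --seed 0 --out report.json
ave sweep    --data toy.csv --trials 3 --seed 0 --out sweep.csv
ave noise    --data toy.csv --trials 3 --seed 0 --out noise.csv
```

`ave sweep` produces the λ ∈ {0.01, 0.05, 0.1, 0.2, 0.5} × {averaged,
weighted, concatenated} sensitivity table and `ave noise` the
ρ ∈ {0, 0.05, 0.1} label-noise robustness table, each with overall-average
and Δ (column-range) footers.

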