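# tdgan — two-stage imputation of sparse clinical time series

Electronic health records yield multivariate physiological time series
(heart rate, blood pressure, lab values, …) in which most cells are missing:
sensors fail, measurements are ordered irregularly, whole encounters drop
out.  `tdgan` implements a two-stage imputer for such high-missing-rate
data, together with the classical baselines, masked evaluation metrics and
a synthetic benchmark generator, as a tested Python library with a CLI.

## The method

A record is a matrix `x ∈ R^{d×n}` (d features, n timestamps `t_i`) with a
binary mask `m` (1 = observed) and zero placeholders at missing cells.

**Stage 1 — adversarial fill with uncertainty.**  A generator
`x̂_t = G(x_t, m_t, (1−m_t)⊙z_t)` estimates every dimension of every
timestep from the observed vector, its mask and masked noise; observed
values then overwrite the estimates, `x̄_t = m_t⊙x_t + (1−m_t)⊙x̂_t`.  A
discriminator is trained to recover the mask from `x̄_t` (per-dimension
cross-entropy), while the generator is trained to fool it and to
reconstruct the observed cells (weight `α`).  Each timestep also receives
an uncertainty score

    u_t = sqrt( Σ_i ((x_t^i − x̂_t^i)(1−m_t^i))² / k ),   k = Σ_i m_t^i,

the RMS deviation of the generator over the missing-weighted dimensions.

**Stage 2 — time-decay recurrent correction.**  A recurrent network walks
each record in time order.  From the decayed hidden state
`ĥ_{t−1} = v^h_{t−1}⊙h_{t−1}` it regresses a history-based estimate
`x_t^r = W_r ĥ_{t−1} + b_r` and blends it with the stage-1 estimate through
the decay factor

    v_t = exp{ −max(0, W_u u_t + b_u) } ∈ (0, 1],
    c_t = v_t⊙x̄_t + (1−v_t)⊙x_t^r,

so confidently generated fills are trusted and uncertain ones are shaded
toward the temporal prediction.  The completed vector
`x_t^c = m_t⊙x_t + (1−m_t)⊙c_t` (observed cells always pass through) and
the mask feed a gated (GRU-style) hidden update; training minimizes the
mean absolute error of `c_t` against observed cells.  Both stages are
optimized with Adam (batch 128, learning rate 0.001).

Evaluation hides observed cells artificially and scores the fill on the
original measurement scale with masked RMSE and MAPE
(`100/n · Σ|y−y′|/|y|`), plus a pairwise-normalized AUC for downstream
classification scores.

## Worked example

```python
from tdgan import (SyntheticConfig, UganConfig, GrudConfig, UganGrudModel,
                   generate_truth, corrupt_dataset, run_impute)

cfg = SyntheticConfig(d=5, n=100, records=50, missing_rate=0.3, seed=1024)
truth = generate_truth(cfg)                      # correlated AR(1) records
corrupted, heldout = corrupt_dataset(truth, cfg.missing_rate, seed=1024)

model = UganGrudModel(corrupted,
                      ugan_config=UganConfig(n_iter=100),
                      grud_config=GrudConfig(epochs=100))
res = model.fit(seed=0)
print(res.summary())
report = res.evaluate(heldout)
print(f"held-out RMSE {report.rmse:.3f}, MAPE {report.mape:.2f}%")
```

prints

```
Two-stage time-series imputation results
============================================
variant: full
records                       : 50
features                      : 5
total cells                   : 25000
observed fraction             : 0.700
adversarial iterations        : 100
final D loss                  : 0.6300
final G loss                  : 0.7656
final observed-cell recon MSE : 0.06048
mean uncertainty              : 0.1020
corrector epochs              : 100
corrector hidden size         : 16
final corrector MAE           : 0.20320
held-out RMSE 1.359, MAPE 8.40%
```

The discriminator loss near `ln 2 ≈ 0.69` says generator and discriminator
are in balance; the mean uncertainty (on the normalized [−1, 1] scale) is
the signal driving the stage-2 decay.  The held-out RMSE refers to the
7 501 artificially hidden cells; the zero-fill baseline on the same cells
scores RMSE 14.3 and MAPE exactly 100%.

The same flow is available from a shell:

```sh
tdgan simulate --output bench --records 50 --features 5 --steps 100 \
      --missing-rate 0.3 --seed 1024
tdgan impute --input bench --output run --method ugan-grud --seed 0
tdgan ablate --input bench --output run --seeds 10
```

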