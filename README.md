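# rewardseek

Computational analyses for rodent reward-seeking experiments: operant
schedule simulation, fiber-photometry dopamine-signal processing,
single-unit encoding-pattern discovery, trial-tensor decomposition,
behavioral-economic demand modeling, Bayesian encoding-bias inference, and
behavioral endophenotyping.  Every stage runs end-to-end on synthetic data
with planted ground truth, so the whole pipeline is testable without any
recordings.

## Who this is for

Labs analyzing operant behavior (fixed-ratio, progressive-ratio, demand and
go/no-go tasks) together with nucleus-accumbens recordings — two-channel
fiber photometry of a dopamine sensor and/or single-unit electrophysiology —
and comparing treatment groups (e.g. a prenatal-exposure model vs controls).

## The models at the core

**Progressive ratio.** Response requirements escalate near-logarithmically,
`ratio(i) = round(5·e^(0.2·i)) − 5`, giving 1, 2, 4, 6, 9, 12, 15, 20, 25,
32, 40, 50, 62, 77, 95, 118 for trials 1–16; the session ends at the first
10-minute window without a reward, and the last completed ratio is the
breakpoint.

**Photometry.** The isosbestic channel (405 nm) is scaled and regressed
onto the dopamine-sensitive channel (470 nm) by OLS; ΔF/F is the residual
normalized by the fitted channel.  PSTHs are z-scored per trial against a
−4..−2 s pre-cue baseline; window metrics use the trapezoidal AUC over the
cue (0–2 s) and reward (2–7 s) windows; spontaneous transients are local
maxima with topographic prominence ≥ 1.

**Encoding patterns.** Each unit's firing is normalized to its session
mean, standardized across units per time bin, and smoothed with a Gaussian
kernel (8 bins, σ = 3).  Four features — number of transients, time to
first transient, mean cue activity, mean reward activity — feed k-means
with k grown iteratively until newly found patterns resemble existing ones;
units fitting no pattern are "nonencoding".

**Tensor component analysis.** Trials × units × peri-cue time tensors
(first 8 PR trials) are factorized as `X_utp ≈ Σ_r w_ur · b_tr · a_pr` by
alternating least squares; the rank is the smallest that converges across
independently initialized runs while reaching the reconstruction-error
floor.  Unit loadings `w_ur` support group comparisons and behavioral
prediction.

**Demand economics.** Consumption vs price follows the exponential model
of demand `log Q = log Q0 + k(e^(−α·Q0·price) − 1)`, with essential value
`EV = 1/(α·k^1.5·100)` and `Pmax = (1/(Q0·α·k^1.5))·(0.083k + 0.65)`, the
price at the peak of responding.

**Encoding-bias inference.** Whether treatment shifts a unit's probability
of membership in an encoding class is tested by Bayesian logistic
regression under a compound confluent hypergeometric prior (a = 0.5, b = 2,
s = 0) on the coefficient's g-mixture, reporting the posterior log-odds,
a 95% credible interval, and a Bayes factor with Jeffreys evidence labels.

## Worked example

```bash
python examples/05_demand_curves.py
```

```
 price  consumption
 180.0         0.47
  90.0         0.49
  45.0         0.62
  15.0         1.49
   5.0         6.93

Q0 = 51.1 rewards (true 50): hedonic set point
alpha = 0.00203 (true 0.002): price sensitivity
Pmax = 2.8 presses/reward: peak of responding, motivational drive
EV = 1.74: reinforcing efficiency across prices
R^2 (log space) = 0.988
```

Consumption generated at the descending food prices from known parameters
(Q0 = 50, α = 0.002, k = 2) with 10% lognormal noise is refit to within a
few percent; Pmax marks where responding peaks and demand turns elastic.
The other scripts in `examples/` cover each capability the same way —
`03_encoding_patterns.py` recovers k = 4 encoding patterns from 150
synthetic units, `04_tensor_assemblies.py` selects rank 4 and localizes a
planted group difference to one assembly, `08_full_pipeline.py` runs every
stage from a config with a provenance manifest.

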