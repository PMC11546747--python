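"""Fit the exponential model of demand and derive EV and Pmax.

Consumption at the descending food prices (180, 90, 45, 15, 5 presses per
pellet) is generated from known parameters with lognormal noise, then fit
by nonlinear least squares in log10 space:

    log10 Q = log10 Q0 + k (e^(-alpha Q0 price) - 1)
"""

from rewardseek import DemandGenSpec, fit_demand_curve, gen_demand_observations
from rewardseek.demand import derived_metrics

spec = DemandGenSpec(Q0_true=50.0, alpha_true=0.002, k_true=2.0, noise_sd=0.1, seed=4)
obs = gen_demand_observations(spec)
print(obs.round(2).to_string(index=False))

fit = fit_demand_curve(obs["price"], obs["consumption"], k_policy="fixed", k_value=2.0)
print(f"\nQ0 = {fit.Q0:.1f} rewards (true 50): hedonic set point")
print(f"alpha = {fit.alpha:.5f} (true 0.002): price sensitivity")
print(f"Pmax = {fit.Pmax:.1f} presses/reward: peak of responding, motivational drive")
print(f"EV = {fit.EV:.2f}: reinforcing efficiency across prices")
print(f"R^2 (log space) = {fit.r2:.3f}")
# Larger Pmax at equal Q0/alpha means the subject keeps responding at
# higher prices before demand turns elastic.
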