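"""CP tensor decomposition of a unit x trial x time tensor.

A 100 x 8 x 60 tensor is built from four planted cell assemblies (distinct
within-trial motifs, trial trends and unit loadings) at SNR 5.  Rank is
chosen by cross-run convergence; unit loadings are then compared between
planted CTRL and PCE groups.
"""

import numpy as np

from rewardseek import TensorGenSpec, compare_group_loadings, cp_als, gen_trial_tensor, select_rank

labels = np.array(["CTRL"] * 50 + ["PCE"] * 50)
spec = TensorGenSpec(
    U=100, T=8, P=60, r_true=4, snr=5.0, seed=1,
    group_labels=labels, group_loading_shift=np.array([0.4, 0.0, 0.0, 0.0]),
)
tensor, truth = gen_trial_tensor(spec)

sel = select_rank(tensor, candidates=list(range(1, 9)), runs_per_candidate=10, seed=1)
print(f"Selected rank: {sel.selected_r} (planted 4)")
print("Cross-run similarity by rank:",
      {r: round(s, 2) for r, s in sel.similarity.items()})

model = cp_als(tensor, sel.selected_r, n_restarts=5, seed=1)
print(f"Relative reconstruction error: {model.rel_error(tensor.X):.3f}")

for row in compare_group_loadings(model, labels):
    print(f"  component {row['component']}: "
          f"CTRL {row['mean_CTRL']:.2f}  PCE {row['mean_PCE']:.2f}  d={row['cohens_d']:+.2f}")
# The loading shift planted on one assembly appears as a large |d| on a
# single component; the rest stay near zero.
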