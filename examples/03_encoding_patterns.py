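"""Discover single-unit encoding patterns by iterative k-means.

150 synthetic units carry four planted peri-cue profiles (cue/reward x
activated/inhibited) plus 20% nonencoding units.  PSTHs are session-mean
normalized, z-scored across units and smoothed; four features per unit
(transient count, first-transient time, mean cue and reward activity)
enter k-means, with k grown until no new pattern emerges.
"""

from collections import Counter

from rewardseek import SpikeGenSpec, discover_encoding_patterns, gen_spike_session
from rewardseek.synth import pr_like_events

events = pr_like_events(30)
mix = {
    "cue_activated": 0.2,
    "cue_inhibited": 0.2,
    "reward_activated": 0.2,
    "reward_inhibited": 0.2,
    "nonencoding": 0.2,
}
session = gen_spike_session(SpikeGenSpec(n_units=150, profile_mix=mix, seed=1), events)

psths, features, model = discover_encoding_patterns(session, events, seed=1)

print(f"Encoding patterns found: k = {model.k} "
      f"(total clusters incl. nonencoding: {model.n_clusters_total})")
labels = Counter(model.label_of(i) for i in range(len(model.unit_ids)))
for label, n in sorted(labels.items()):
    print(f"  {label:18s} {n:3d} units")
print("Search history:", model.history)
# k counts distinct encoding patterns; the nonencoding label collects the
# flat cluster plus feature-space outliers.
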