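"""Use technical replicates and the mixed-model caller.

When every subject is run in triplicate, the within-subject spread of the
reference probes measures the assay noise.  The mixed model estimates the
null variability of a case-minus-control profile difference from
leave-one-out differences between control subjects and calls a probe altered
when its difference leaves the grand_mean +- z * SE band.
"""

import numpy as np

import mlpacall as m
from mlpacall.calling import MixedConfig

cfg = m.SimConfig(
    n_replicates=3,
    alteration_map={"P015": 1.5},  # single-copy gain in all case subjects
    seed=22,
)
exp, truth = m.simulate_experiment(cfg)
print("experiment:", exp.summary())

norm = m.normalize(exp, "sum.peaks.controls")
table = m.call_mixed_model(norm, MixedConfig(level=0.95))
fit = table.info["fit"]
print(f"\nnull model: grand mean (log scale) {fit.grand_mean:+.4f}, "
      f"subject-mean variance {fit.error_variance:.2e}, "
      f"replicate variance {fit.within_replicate_variance:.2e}")
lo, hi = fit.interval
print(f"no-change band on the dosage-ratio scale: ({np.exp(lo):.3f}, {np.exp(hi):.3f})")

score = m.evaluate_calls(table, truth)
gained = table.frame[(table.frame["probe_id"] == "P015") & (table.frame["call"] == 1)]
print(f"\nP015 called +1 in {len(gained)}/10 case subjects; "
      f"power {score.power:.2f}, type-I error {score.type_i_error:.3f}")
print("A 1.5x gain corresponds to 3 copies vs 2; with triplicates and 5% CV "
      "the mixed model detects it in essentially every case subject.")
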