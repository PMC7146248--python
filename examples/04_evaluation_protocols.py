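"""User-dependent vs user-independent evaluation.

Runs LOSO (leave-one-session-out, within each participant) and LOPO
(leave-one-participant-out) on a small synthetic cohort with the
right-forearm armband.  Expect LOSO to beat LOPO: the simulator gives each
participant idiosyncratic gains, an orientation bias, and an sEMG
electrode rotation, so models transfer imperfectly between users —
the user-dependent vs user-independent gap.
"""

import numpy as np

import scrubstep as ss
from scrubstep.evaluate import FeatureCache, group_by_participant

cohort = ss.generate_cohort(
    ss.SimulationConfig.desk_scale(n_participants=3, sessions_per_condition=1,
                                   seed=5))
cache = ss.FeatureCache()
config = ss.PipelineConfig.desk_scale(seed=0)

loso = {
    pid: ss.loso_cv(sessions, config, cache).mean_accuracy
    for pid, sessions in group_by_participant(cohort).items()
}
print("LOSO (user-dependent) per participant:")
for pid, acc in loso.items():
    print(f"  {pid}: {acc:.3f}")
print(f"  mean: {np.mean(list(loso.values())):.3f}")

lopo = ss.lopo_cv(cohort, config, cache)
print("\nLOPO (user-independent) per participant:")
for pid, acc in lopo.per_unit.items():
    print(f"  {pid}: {acc:.3f}")
print(f"  mean: {lopo.mean_accuracy:.3f} (pooled {lopo.pooled_accuracy:.3f})")
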