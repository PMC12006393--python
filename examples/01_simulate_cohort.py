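"""Generate a paired oocyte/granulosa COC cohort and inspect its design.

The cohort covers four condition groups (naturally ovulated young NY,
superovulated young SY, naturally ovulated old NO, superovulated old SO)
with mouse-level replication and one oocyte sample plus one granulosa bulk
per COC. The returned ground truth records every planted effect.
"""

import cocpipe as cp

cfg = cp.SimConfig(seed=1)
cohort, truth = cp.generate_paired_cohort(cfg)

print(f"genes: {cohort.oc_counts.shape[0]}, COCs: {cohort.oc_counts.shape[1]}")
print(cohort.meta.groupby(["condition", "cell_type"]).size().unstack())
print("\nlatent subgroups of superovulated COCs:")
print(truth.subgroup.value_counts())
print(f"\nplanted DE genes: superovulation {int(truth.de_flags['super'].sum())}, "
      f"aging {int(truth.de_flags['aging'].sum())}")
print(f"mean library size: {cohort.oc_counts.values.sum(axis=0).mean():,.0f} reads")
# Each SY/SO COC belongs to S_N (30% of the superovulation shift, resembling
# natural ovulation) or S (the full shift); old COCs receive only 50% of the
# superovulation response (the planted aging x superovulation interaction).
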