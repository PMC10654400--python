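"""Generate a synthetic surgical cohort and summarize its structure.

The simulator emulates a perioperative EHR extract: demographics, one
procedure (CPT) code plus Zipf-distributed comorbidity (ICD-10-like)
codes, and repeated daily pain observations on postoperative days 0-4,
censored by hospital discharge. Here we plant one comorbidity code that
adds +2 NRS points on every day, so downstream examples can recover it.
"""

import numpy as np

import popset

cfg = popset.SimConfig(
    n_patients=1000,
    effect_codes={"ICD-0001": (2, 2, 2, 2, 2)},
    seed=42,
)
records, truth = popset.generate_cohort(cfg)
kept, excluded = popset.apply_exclusions(records)

print(f"simulated {len(records)} patients; kept {len(kept)} after exclusions")
reasons = {}
for _, r in excluded:
    reasons[r] = reasons.get(r, 0) + 1
print(f"exclusion reasons: {reasons}")

outcomes = [popset.build_outcomes(r) for r in kept]
for d in range(5):
    vals = [o.max_pain[d] for o in outcomes if o.available[d]]
    print(f"day {d}: n={len(vals):4d}  mean max pain={np.mean(vals):.2f}  "
          f"moderate(>4)={np.mean([v > 4 for v in vals]):.0%}")

carriers = truth.carriers["ICD-0001"]
print(f"\nplanted code ICD-0001 carried by {carriers.mean():.0%} of patients;")
print("mean latent day-0 pain: carriers "
      f"{truth.latent_pain[carriers, 0].mean():.2f} vs non-carriers "
      f"{truth.latent_pain[~carriers, 0].mean():.2f} "
      "(the +2 NRS planted effect, shrunk slightly by clamping to [0,10])")
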