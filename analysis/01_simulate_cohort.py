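#!/usr/bin/env python
"""Simulate the study cohort and write it to results/cohort/.

Generates 1000 mother-newborn dyads across 11 field centers with the
default covariate/outcome moments, a 60-metabolite panel (6 communities)
at fasting and 1 h, pooled-QC injections, and the generating truth.
Prints the marginal summaries a reader would check first.
"""
import sys

from metnetmap import CohortConfig
from metnetmap.pipeline import write_cohort
from metnetmap.synthetic import generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2023

cfg = CohortConfig(seed=SEED)
cov, fasting, one_hour, qc, outcomes, truth = generate_cohort(cfg)
write_cohort("results/cohort", cov, fasting, one_hour, qc, outcomes, truth)

print(f"cohort: {len(cov)} samples, {cfg.n_metabolites} metabolites, seed {SEED}")
print(f"ancestry counts:\n{cov['ancestry'].value_counts().to_string()}")
for o in outcomes:
    print(f"{o}: mean {outcomes[o].mean():.1f}, sd {outcomes[o].std(ddof=1):.1f}")
frac = fasting.missing_fraction()
print(f"fasting missingness: {int((frac > 0).sum())} metabolites censored, "
      f"max fraction {frac.max():.3f}")
print(f"true graph: {int(truth.true_support.to_numpy().sum()) // 2} edges, "
      f"{truth.true_communities.nunique()} communities")
print(f"implied outcome R^2: "
      + ", ".join(f"{k}={v:.2f}" for k, v in truth.outcome_r2.items()))
print("written: results/cohort/")
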