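#!/usr/bin/env python
"""Metabolome-wide association of maternal metabolites with newborn outcomes.

For each sample time and outcome, fits Model 1 (baseline covariates) and
Model 2 (plus maternal BMI and state-matched glucose) per metabolite within
ancestry strata, pools by inverse variance, adjusts by Benjamini-Hochberg,
and writes one side-by-side table per outcome x time. Prints the top
associations and the Model-1 -> Model-2 attenuation pattern.
"""
from pathlib import Path

from metnetmap.association import associate, association_table
from metnetmap.config import OUTCOMES, ModelSpec
from metnetmap.pipeline import read_tables
from metnetmap.preprocess import filter_missingness, preprocess_matrix

cov, fasting, one_hour, qc, outcomes = read_tables("results/cohort")
out_dir = Path("results/association")
out_dir.mkdir(parents=True, exist_ok=True)

for m in (fasting, one_hour):
    mat, _ = preprocess_matrix(m, qc)
    assoc_set = filter_missingness(mat, 0.10)
    for outcome in OUTCOMES:
        results = []
        for model in (1, 2):
            spec = ModelSpec(model=model, outcome=outcome, sample_time=m.sample_time)
            results.extend(associate(assoc_set, cov, outcomes, spec))
        table = association_table(results)
        table.to_csv(out_dir / f"association_{outcome}_{m.sample_time}.csv",
                     index=False)
        sig2 = table[table["model2_significant"]]
        top = table.reindex(table["model2_p"].abs().sort_values().index).head(3)
        print(f"{m.sample_time}/{outcome}: {len(table)} metabolites tested, "
              f"{len(sig2)} FDR-significant in Model 2")
        for _, r in top.iterrows():
            print(f"    {r['metabolite']}: M1 {r['model1_formatted']} | "
                  f"M2 {r['model2_formatted']}")
print("written: results/association/")
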