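"""Per-person PP3/BP4 clinical-evidence yield by ancestry.

Maps each predictor's scores to ACMG/AMP evidence points with the example
calibration tables, counts the evidence categories over every individual's
heterozygous missense sites, averages the counts across the three
predictors, and summarizes per ancestry — the scaled-down analog of an
evidence-yield-per-genome figure.
"""

from pathlib import Path

import pandas as pd

from vepfair import burden as bu
from vepfair import evidence as ev
from vepfair import synthetic as sy
from vepfair.cli import default_calibration_path

ROOT = Path(__file__).resolve().parents[1]
SEED = 2026

cohort = sy.generate_cohort(sy.demo_spec(seed=SEED))
tables = ev.load_calibration_tables(default_calibration_path())
preds = sorted(cohort.spec.score_models)
site_points = {
    p: ev.score_array_to_points(cohort.variants[f"score_{p}"].to_numpy(float), tables[p])
    for p in preds
}

all_rows = []
for anc in cohort.ancestry_names:
    rows = bu.per_individual_burden(cohort.genotypes[anc], cohort.variants, anc)
    bu.evidence_yield_per_individual(rows, site_points)
    for b in rows:
        b.evidence_yield["averaged"] = bu.average_over_predictors(b.evidence_yield, preds)
    all_rows.extend(rows)

per_ind = bu.burdens_to_frame(all_rows)
long = per_ind.melt(
    id_vars=["ancestry"],
    value_vars=[c for c in per_ind.columns if c.startswith("yield_averaged_")],
    var_name="category", value_name="count",
)
long["category"] = long["category"].str.removeprefix("yield_averaged_")
summary = (
    long.groupby(["ancestry", "category"])["count"].mean().rename("mean_per_person")
    .reset_index()
)

out = ROOT / "results"
out.mkdir(exist_ok=True)
summary.to_csv(out / "evidence_yield_summary.tsv", sep="\t", index=False)

print("mean variants per person by evidence category (averaged over "
      f"{len(preds)} predictors):")
print(summary.pivot(index="category", columns="ancestry", values="mean_per_person")
      .round(3).to_string())
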