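"""Generate the demonstration cohort used by the downstream analyses.

Three ancestries with unequal sample sizes, site counts, and rare-AF laws
(EUR deepest-sampled and rarest-shifted), three predictors with
AF-declining discrimination, AF-dependent pathogenicity, and per-person
genotypes.  The full cohort (variant table, genotype matrices, generator
truth) is written to scratch/demo_cohort/; a small summary goes to
results/.
"""

import json
from pathlib import Path

from vepfair import synthetic as sy

ROOT = Path(__file__).resolve().parents[1]
SEED = 2026

spec = sy.demo_spec(seed=SEED)
cohort = sy.generate_cohort(spec)
paths = sy.write_cohort(cohort, ROOT / "scratch" / "demo_cohort")

out = ROOT / "results"
out.mkdir(exist_ok=True)
summary = {
    "seed": SEED,
    "n_sites_total": spec.n_sites_total,
    "shared_site_fraction": spec.shared_site_fraction,
    "ancestries": {
        a.name: {"n_individuals": a.n_individuals, "n_sites_present": a.n_sites_present,
                 "af_alpha": a.af_law.alpha}
        for a in spec.ancestries
    },
    "n_pathogenic": int(cohort.truth.labels.sum()),
    "expected_het_burden": cohort.truth.expected_het_burden,
}
(out / "cohort_summary.json").write_text(json.dumps(summary, indent=2))

print(f"simulated {spec.n_sites_total} sites, "
      f"{sum(a.n_individuals for a in spec.ancestries)} individuals "
      f"-> {paths['variants'].parent}")
print(f"pathogenic sites: {summary['n_pathogenic']}")
for name, burden in cohort.truth.expected_het_burden.items():
    print(f"expected het sites per person [{name}]: {burden:.2f}")
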