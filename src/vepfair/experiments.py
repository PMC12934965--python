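"""Replicated simulation experiments over the synthetic generator.

These functions define the study conditions used by the analysis scripts,
the test suite, and scripts/acceptance.py, so all three run the identical
configurations:

* a brute-force pairwise AUC oracle and its agreement check;
* closed-form binormal AUC recovery (empirical AUC vs Phi(d / (sigma sqrt 2)));
* heterozygous-burden recovery against sum 2p(1-p);
* the null experiment — two ancestries with identical AF laws and score
  models, measuring the raw bootstrap rejection rate (type-I error);
* the Simpson experiment — per-bin AUCs identical across ancestries
  (theoretical 0.95 / 0.85 / 0.75 by a declining separation law) but the
  reference ancestry's AF mixture shifted toward rarer variants, measuring
  how often the aggregate comparison is significant while the binned
  comparisons are not.

The null and Simpson cohorts use a flat label model (balanced classes) so
the per-bin AUCs are exactly the designed values; the demo cohort used in
the worked examples keeps the AF-dependent label model.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

from . import fairness as fa
from . import synthetic as sy

__all__ = [
    "exhaustive_auc",
    "auc_oracle_check",
    "binormal_recovery",
    "het_burden_recovery",
    "null_spec",
    "simpson_spec",
    "run_null_experiment",
    "run_simpson_experiment",
]

_SQRT2 = math.sqrt(2.0)

# separations giving theoretical bin AUCs 0.95 / 0.85 / 0.75 at sigma = 1
_D_BY_BIN = tuple(float(_SQRT2 * norm.ppf(a)) for a in (0.95, 0.85, 0.75))
_EXPERIMENT_EDGES = (1e-4, 1e-3)  # 3 bins over (0, 0.01)


# ---------------------------------------------------------------------------
# AUC oracle
# ---------------------------------------------------------------------------


def exhaustive_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Brute-force Mann-Whitney AUC by enumerating every (pos, neg) pair.

    Independent oracle for :func:`vepfair.fairness.compute_auc`; O(n^2), for
    small instances only.
    """
    wins = ties = 0
    for p in np.asarray(pos, dtype=float):
        for n in np.asarray(neg, dtype=float):
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def auc_oracle_check(n_instances: int = 1000, max_class: int = 8, seed: int = 0) -> float:
    """Fraction of random small instances where compute_auc agrees exactly
    with the exhaustive pairwise count (ties included via a coarse score
    grid)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n_pos = int(rng.integers(1, max_class + 1))
        n_neg = int(rng.integers(1, max_class + 1))
        # quantized scores force frequent ties
        pos = np.round(rng.random(n_pos), 1)
        neg = np.round(rng.random(n_neg), 1)
        if math.isclose(
            fa.compute_auc(pos, neg), exhaustive_auc(pos, neg), abs_tol=1e-12
        ):
            agree += 1
    return agree / n_instances


# ---------------------------------------------------------------------------
# Closed-form recoveries
# ---------------------------------------------------------------------------


def binormal_recovery(
    d_over_sigma: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    n_per_class: int = 2000,
    seed: int = 0,
) -> list[dict]:
    """Empirical AUC on a single synthetic bin vs the binormal closed form.

    For each ratio d/sigma, draws n benign ~ N(0, 1) and n pathogenic
    ~ N(d, 1) latent scores through the generator's score model (squashed to
    [0, 1]; the squashing is monotone so AUC is unchanged) and reports the
    empirical AUC, the theory value Phi(d / sqrt 2), and the 99% CI.
    """
    out = []
    children = np.random.SeedSequence(seed).spawn(len(d_over_sigma))
    for d, child in zip(d_over_sigma, children):
        rng = np.random.default_rng(child)
        model = sy.ScoreModel(separation=sy.SeparationLaw((), (d,)), sigma=1.0)
        labels = np.repeat([False, True], n_per_class)
        afs = np.full(labels.size, 1e-4)
        scores = sy.simulate_scores(labels, afs, model, rng)
        auc = fa.compute_auc(scores[labels], scores[~labels])
        theory = float(norm.cdf(d / _SQRT2))
        lo, hi = fa.binormal_auc_ci(theory, n_per_class, n_per_class, level=0.99)
        out.append(
            {
                "d_over_sigma": d,
                "auc": auc,
                "theory": theory,
                "ci99_lo": lo,
                "ci99_hi": hi,
                "inside": bool(lo <= auc <= hi),
                "n_per_class": n_per_class,
            }
        )
    return out


def het_burden_recovery(
    n_individuals: int = 5000, n_sites: int = 1000, seed: int = 0
) -> dict:
    """Simulated mean per-person het count vs the closed form sum 2p(1-p).

    One ancestry, AFs from the default log-uniform rare law; returns the
    simulated mean, the theoretical expectation for the realized AF vector,
    the analytic SE of the mean, and the z-deviation.
    """
    spec = sy.CohortSpec(
        ancestries=(
            sy.AncestrySpec("EUR", n_individuals=n_individuals, n_sites_present=n_sites),
        ),
        n_sites_total=n_sites,
        seed=seed,
    )
    cohort = sy.generate_cohort(spec)
    afs = cohort.af_vector("EUR")
    expected = sy.theoretical_het_burden(afs)
    se = sy.het_burden_se_of_mean(afs, n_individuals)
    het_counts = (cohort.genotypes["EUR"] == 1).sum(axis=1)
    mean = float(het_counts.mean())
    return {
        "mean_het_per_person": mean,
        "expected": expected,
        "se_of_mean": se,
        "z": (mean - expected) / se,
        "n_individuals": n_individuals,
        "n_sites": n_sites,
    }


# ---------------------------------------------------------------------------
# Null and Simpson experiments
# ---------------------------------------------------------------------------


def _two_ancestry_spec(
    seed: int, n_variants: int, alpha_ref: float, alpha_other: float
) -> sy.CohortSpec:
    ancestries = tuple(
        sy.AncestrySpec(name, 1, n_variants, sy.AFLaw(alpha=a, af_min=1e-5, af_max=0.01))
        for name, a in (("EUR", alpha_ref), ("AFR", alpha_other))
    )
    model = sy.ScoreModel(separation=sy.SeparationLaw(_EXPERIMENT_EDGES, _D_BY_BIN))
    return sy.CohortSpec(
        ancestries=ancestries,
        n_sites_total=2 * n_variants,
        shared_site_fraction=0.0,
        label_model=sy.LabelModel(0.0, 0.0),  # balanced classes
        score_models={"pred": model},
        missense_fraction=1.0,
        seed=seed,
    )


def null_spec(seed: int, n_variants: int = 1000) -> sy.CohortSpec:
    """Two ancestries, identical AF laws (log-uniform) and score models."""
    return _two_ancestry_spec(seed, n_variants, alpha_ref=1.0, alpha_other=1.0)


def simpson_spec(seed: int, n_variants: int = 5000) -> sy.CohortSpec:
    """Equal per-bin score models; EUR's AF mixture shifted toward rare.

    alpha 1.5 vs 0.5 puts ~71% of EUR variants below AF 1e-4 but ~93% of the
    comparison ancestry's above 1e-3, while the per-bin theoretical AUCs
    (0.95 / 0.85 / 0.75) are identical across ancestries by construction —
    the seed of the aggregate-vs-binned reversal.
    """
    return _two_ancestry_spec(seed, n_variants, alpha_ref=1.5, alpha_other=0.5)


def _run_replicates(
    spec_fn, n_replicates: int, B: int, seed: int
) -> list[fa.FairnessResult]:
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    results = []
    for child in children:
        rep_seed = int(child.generate_state(2)[0] % (2**31))
        eval_seed = int(child.generate_state(2)[1] % (2**31))
        cohort = sy.generate_cohort(spec_fn(rep_seed), genotypes=False)
        cfg = fa.EvalConfig(predictors=("pred",), reference="EUR", B=B, seed=eval_seed)
        results.append(fa.evaluate(cohort.variants, fa.AFBinning(_EXPERIMENT_EDGES), cfg))
    return results


def run_null_experiment(
    n_replicates: int = 500, n_variants: int = 1000, B: int = 200,
    alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Raw rejection rate over all comparison cells under the null."""
    results = _run_replicates(lambda s: null_spec(s, n_variants), n_replicates, B, seed)
    pvals = [
        c.p_vs_reference
        for r in results
        for c in r.cells
        if c.ancestry != "EUR" and not np.isnan(c.p_vs_reference)
    ]
    pvals = np.asarray(pvals)
    return {
        "rejection_rate": float((pvals < alpha).mean()),
        "n_pvalues": int(pvals.size),
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def run_simpson_experiment(
    n_replicates: int = 100, n_variants: int = 5000, B: int = 200, seed: int = 0
) -> dict:
    """Detection rate of the aggregate-significant / binned-null reversal."""
    results = _run_replicates(lambda s: simpson_spec(s, n_variants), n_replicates, B, seed)
    detected = agg_sig = 0
    bin_sig = bin_total = 0
    for r in results:
        detected += int(any(r.simpson_flags.values()))
        for c in r.cells:
            if c.ancestry == "EUR" or np.isnan(c.p_vs_reference):
                continue
            if c.bin == fa.ALL_BIN:
                agg_sig += int(c.significant_bonferroni)
            else:
                bin_total += 1
                bin_sig += int(c.significant_bonferroni)
    return {
        "detection_rate": detected / n_replicates,
        "aggregate_significant_fraction": agg_sig / n_replicates,
        "binned_significant_fraction": bin_sig / bin_total if bin_total else float("nan"),
        "n_replicates": n_replicates,
        "n_variants_per_ancestry": n_variants,
        "B": B,
    }
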