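"""Generator: AF law, labels, scores, genotypes, and closed-form truth."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import ndtr

from vepfair import synthetic as sy
from vepfair.errors import ConfigurationError, DataError


def test_powerlaw_mean_log10_matches_numerical_integration():
    """AFLaw.mean_log10 against direct quadrature of log10(x) x^-a / Z."""
    for alpha in (0.5, 1.0, 1.7):
        law = sy.AFLaw(alpha=alpha, af_min=1e-5, af_max=1e-2)
        z, _ = quad(lambda x: x**-alpha, law.af_min, law.af_max)
        num, _ = quad(lambda x: math.log10(x) * x**-alpha, law.af_min, law.af_max)
        assert law.mean_log10() == pytest.approx(num / z, rel=1e-9)


def test_powerlaw_empirical_mean_within_3se(rng):
    """Empirical mean of log10 AF vs the analytic truncated-law mean,
    50,000 draws of the log-uniform (alpha=1) law."""
    law = sy.AFLaw(alpha=1.0, af_min=1e-5, af_max=1e-2)
    x = np.log10(law.sample(50_000, rng))
    se = x.std(ddof=1) / math.sqrt(x.size)
    assert abs(x.mean() - law.mean_log10()) < 3 * se


def test_powerlaw_degenerate_interval_is_point_mass(rng):
    law = sy.AFLaw(alpha=1.0, af_min=0.005 - 1e-12, af_max=0.005)
    assert sy.AFLaw(alpha=1.0, af_min=1e-5, af_max=0.01)  # sanity: valid default
    np.testing.assert_allclose(law.sample(100, rng), 0.005, rtol=1e-6)


@pytest.mark.parametrize(
    "kwargs", [dict(af_min=0.0), dict(af_min=0.02, af_max=0.01), dict(alpha=-1.0),
               dict(af_max=0.5)]
)
def test_invalid_af_law_names_the_field(kwargs):
    with pytest.raises(ConfigurationError, match="af_law"):
        sy.AFLaw(**{**dict(alpha=1.0, af_min=1e-5, af_max=0.01), **kwargs})


def test_no_sharing_means_disjoint_presence():
    spec = sy.CohortSpec(
        ancestries=(
            sy.AncestrySpec("A", 1, 60), sy.AncestrySpec("B", 1, 40),
        ),
        n_sites_total=100, shared_site_fraction=0.0, seed=5,
    )
    afs = sy.sample_site_frequencies(spec, np.random.default_rng(0))
    both = (afs["A"] > 0) & (afs["B"] > 0)
    assert not both.any()
    assert (afs["A"] > 0).sum() == 60 and (afs["B"] > 0).sum() == 40


def test_shared_fraction_is_exact():
    spec = sy.CohortSpec(
        ancestries=(sy.AncestrySpec("A", 1, 70), sy.AncestrySpec("B", 1, 80)),
        n_sites_total=100, shared_site_fraction=0.5, seed=5,
    )
    afs = sy.sample_site_frequencies(spec, np.random.default_rng(0))
    shared = ((afs["A"] > 0) & (afs["B"] > 0)).sum()
    assert shared == 50


def test_site_accounting_mismatch_raises():
    spec = sy.CohortSpec(
        ancestries=(sy.AncestrySpec("A", 1, 70), sy.AncestrySpec("B", 1, 70)),
        n_sites_total=100, shared_site_fraction=0.5, seed=5,
    )
    with pytest.raises(ConfigurationError, match="site accounting"):
        spec.validate_site_accounting()


def test_label_probabilities_closed_form(rng):
    # flat model: probability 1/2 regardless of AF
    flat = sy.LabelModel(0.0, 0.0)
    afs = np.array([1e-5, 1e-3, 1e-2])
    np.testing.assert_allclose(flat.prob_pathogenic(afs), 0.5)
    # a=-4, b=-1 at AF 1e-4: logistic(-4 + 4) = 0.5
    m = sy.LabelModel(-4.0, -1.0)
    assert m.prob_pathogenic(np.array([1e-4]))[0] == pytest.approx(0.5)
    labels = sy.assign_labels(np.full(20_000, 1e-4), m, rng)
    assert labels.mean() == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(20_000))


def test_label_fraction_decreases_with_af_when_slope_negative():
    spec = sy.CohortSpec(
        ancestries=(sy.AncestrySpec("A", 1, 50_000),),
        n_sites_total=50_000,
        label_model=sy.LabelModel(-3.5, -0.8),
        missense_fraction=1.0, seed=11,
    )
    cohort = sy.generate_cohort(spec, genotypes=False)
    af = cohort.truth.basis_af
    path = cohort.truth.labels
    deciles = np.quantile(af, np.linspace(0, 1, 11))
    idx = np.clip(np.searchsorted(deciles[1:-1], af, side="right"), 0, 9)
    fractions = [path[idx == d].mean() for d in range(10)]
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


def test_scores_with_zero_separation_have_null_auc(rng):
    from vepfair.fairness import compute_auc

    model = sy.ScoreModel(separation=sy.SeparationLaw((), (0.0,)))
    labels = np.arange(8000) % 2 == 0
    scores = sy.simulate_scores(labels, np.full(8000, 1e-3), model, rng)
    auc = compute_auc(scores[labels], scores[~labels])
    assert auc == pytest.approx(0.5, abs=0.025)
    assert model.theoretical_auc(np.array([1e-3]))[0] == 0.5


def test_theoretical_auc_at_d_sigma_sqrt2_is_phi1():
    model = sy.ScoreModel(separation=sy.SeparationLaw((), (math.sqrt(2.0),)), sigma=1.0)
    assert model.theoretical_auc(np.array([1e-3]))[0] == pytest.approx(ndtr(1.0), abs=1e-12)


def test_bin_auc_sequence_strictly_decreasing():
    law = sy.SeparationLaw((1e-4, 1e-3), (2.0, 1.2, 0.5))
    model = sy.ScoreModel(separation=law)
    mids = np.array([3e-5, 3e-4, 3e-3])
    aucs = model.theoretical_auc(mids)
    assert np.all(np.diff(aucs) < 0)


def test_separation_law_must_be_nonincreasing():
    with pytest.raises(ConfigurationError, match="nonincreasing"):
        sy.SeparationLaw((1e-4,), (0.5, 1.0))


def test_sigma_must_be_positive():
    with pytest.raises(ConfigurationError, match="sigma"):
        sy.ScoreModel(sigma=0.0)


def test_squashing_preserves_auc(rng):
    """The logistic squashing is monotone: AUC on squashed scores equals
    AUC on the latent normals."""
    from vepfair.fairness import compute_auc

    model = sy.ScoreModel(separation=sy.SeparationLaw((), (1.0,)), sigma=1.0)
    labels = np.arange(4000) % 2 == 0
    afs = np.full(4000, 1e-3)
    latent = model.mu_benign + model.d(afs) * labels + rng.normal(0, 1, 4000)
    a_latent = compute_auc(latent[labels], latent[~labels])
    a_squash = compute_auc(model.squash(latent)[labels], model.squash(latent)[~labels])
    assert a_latent == pytest.approx(a_squash, abs=1e-12)


def test_genotypes_zero_af_all_reference(rng):
    g = sy.sample_genotypes(np.zeros(10), 5, rng)
    assert g.shape == (5, 10) and not g.any()


def test_genotype_af_out_of_range_raises(rng):
    with pytest.raises(DataError):
        sy.sample_genotypes(np.array([0.5, 1.2]), 3, rng)


def test_theoretical_het_burden_closed_form():
    assert sy.theoretical_het_burden(np.array([])) == 0.0
    assert sy.theoretical_het_burden(np.array([0.005])) == pytest.approx(0.00995)
    assert sy.theoretical_het_burden(np.full(1000, 0.005)) == pytest.approx(9.95)


def test_mean_het_count_within_3se(rng):
    """10,000 individuals x 1,000 sites at p=0.005: mean per-person het
    count vs 9.95, binomial SE."""
    afs = np.full(1000, 0.005)
    g = sy.sample_genotypes(afs, 10_000, rng)
    mean = (g == 1).sum(axis=1).mean()
    se = sy.het_burden_se_of_mean(afs, 10_000)
    assert abs(mean - 9.95) < 3 * se


def test_generate_cohort_deterministic():
    a = sy.generate_cohort(sy.demo_spec(seed=7))
    b = sy.generate_cohort(sy.demo_spec(seed=7))
    assert a.variants.equals(b.variants)
    for name in a.genotypes:
        np.testing.assert_array_equal(a.genotypes[name], b.genotypes[name])
    c = sy.generate_cohort(sy.demo_spec(seed=8))
    assert not a.variants.equals(c.variants)


def test_single_site_cohort_shapes():
    spec = sy.CohortSpec(
        ancestries=(sy.AncestrySpec("A", 4, 1),), n_sites_total=1, seed=0,
    )
    cohort = sy.generate_cohort(spec)
    assert len(cohort.variants) == 1
    assert cohort.genotypes["A"].shape == (4, 1)


def test_truth_auc_is_half_where_separation_zero():
    spec = sy.CohortSpec(
        ancestries=(sy.AncestrySpec("A", 1, 100),),
        n_sites_total=100,
        score_models={"p": sy.ScoreModel(separation=sy.SeparationLaw((), (0.0,)))},
        seed=0,
    )
    cohort = sy.generate_cohort(spec, genotypes=False)
    assert all(row["auc"] == 0.5 for row in cohort.truth.theoretical_auc_by_bin["p"])


def test_equal_models_equal_bin_truth_but_aggregate_auc_differs():
    """The conditional-fairness construction: identical score/label models
    across ancestries give identical per-bin theoretical AUCs, yet the
    aggregate AUC differs when the AF mixtures differ."""
    from vepfair.experiments import simpson_spec
    from vepfair.fairness import compute_auc

    cohort = sy.generate_cohort(simpson_spec(3, n_variants=4000), genotypes=False)
    frame = cohort.variants
    scores = frame["score_pred"].to_numpy()
    labels = (frame["label"] == "pathogenic").to_numpy()
    aucs = {}
    for anc in ("EUR", "AFR"):
        m = frame[f"af_{anc}"].notna().to_numpy()
        aucs[anc] = compute_auc(scores[m & labels], scores[m & ~labels])
    assert aucs["EUR"] - aucs["AFR"] > 0.05  # mixture-driven aggregate gap


def test_het_burden_ordering_follows_af_law():
    """More segregating sites with a common-shifted AF law means a larger
    mean het burden."""
    spec = sy.CohortSpec(
        ancestries=(
            sy.AncestrySpec("LOW", 400, 500, sy.AFLaw(alpha=1.5, af_min=1e-5, af_max=0.01)),
            sy.AncestrySpec("HIGH", 400, 1500, sy.AFLaw(alpha=0.5, af_min=1e-5, af_max=0.01)),
        ),
        n_sites_total=2000, shared_site_fraction=0.0, seed=13,
    )
    cohort = sy.generate_cohort(spec)
    mean_low = (cohort.genotypes["LOW"] == 1).sum(axis=1).mean()
    mean_high = (cohort.genotypes["HIGH"] == 1).sum(axis=1).mean()
    assert mean_high > mean_low
    assert (
        cohort.truth.expected_het_burden["HIGH"] > cohort.truth.expected_het_burden["LOW"]
    )
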