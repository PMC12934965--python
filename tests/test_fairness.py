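"""AUC, binning, stratified bootstrap, empirical p, and Simpson detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vepfair import fairness as fa
from vepfair.errors import ConfigurationError, DataError
from vepfair.experiments import exhaustive_auc, simpson_spec
from vepfair import synthetic as sy


# ---------------------------------------------------------------------------
# compute_auc
# ---------------------------------------------------------------------------


def test_auc_worked_example():
    # 4 pairs: 3 wins, 1 loss
    assert fa.compute_auc([0.9, 0.8], [0.7, 0.85]) == pytest.approx(0.75)


def test_auc_all_ties_is_half():
    assert fa.compute_auc([0.5], [0.5]) == pytest.approx(0.5)


def test_auc_perfect_separation():
    assert fa.compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0


def test_auc_empty_class_is_missing():
    assert math.isnan(fa.compute_auc([], [0.5]))
    assert math.isnan(fa.compute_auc([0.5], []))


score = st.integers(0, 10).map(lambda k: k / 10)  # coarse grid forces ties


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    pos=st.lists(score, min_size=1, max_size=8),
    neg=st.lists(score, min_size=1, max_size=8),
)
def test_auc_equals_exhaustive_pairwise_count(pos, neg):
    assert fa.compute_auc(pos, neg) == pytest.approx(exhaustive_auc(pos, neg), abs=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    pos=st.lists(score, min_size=1, max_size=8),
    neg=st.lists(score, min_size=1, max_size=8),
)
def test_auc_complement_symmetry(pos, neg):
    assert fa.compute_auc(pos, neg) + fa.compute_auc(neg, pos) == pytest.approx(1.0)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = np.round(rng.random(500), 2)
    labels = rng.random(500) < 0.4
    ours = fa.compute_auc(scores[labels], scores[~labels])
    assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def test_bin_assignment_half_open_convention():
    b = fa.AFBinning((1e-4, 1e-3))
    # AF exactly at an edge goes to the upper bin
    assert b.assign(np.array([1e-4]))[0] == 1
    assert b.assign(np.array([5e-5]))[0] == 0
    assert b.assign(np.array([0.005]))[0] == 2


def test_bins_partition_the_subset():
    rng = np.random.default_rng(4)
    af = 10 ** rng.uniform(-5, -2.001, 300)
    frame = pd.DataFrame({"af_EUR": af})
    out = fa.bin_variants(frame, fa.AFBinning((1e-4, 1e-3)), "EUR")
    binned = np.concatenate([out[b] for b in fa.AFBinning((1e-4, 1e-3)).bin_ids])
    assert sorted(binned) == list(range(300))
    assert len(out[fa.ALL_BIN]) == 300


def test_binning_rejects_out_of_range_af():
    with pytest.raises(DataError, match="rarity"):
        fa.AFBinning((1e-4,)).assign(np.array([0.02]))


def test_binning_config_validation():
    with pytest.raises(ConfigurationError):
        fa.AFBinning(())
    with pytest.raises(ConfigurationError):
        fa.AFBinning((1e-3, 1e-4))
    with pytest.raises(ConfigurationError):
        fa.AFBinning((0.5,))


# ---------------------------------------------------------------------------
# bootstrap and p-values
# ---------------------------------------------------------------------------


def test_bootstrap_single_pair_enumeration(rng):
    """1 pos + 1 neg with distinct scores: each resample is one of four
    equally likely draws; AUC is missing when a class vanishes, else 0/1."""
    aucs, _ = fa.bootstrap_auc(np.array([0.9, 0.1]), np.array([True, False]), 400, rng)
    missing = np.isnan(aucs)
    assert set(np.unique(aucs[~missing])) <= {0.0, 1.0}
    # a class vanishes in 2 of 4 equally likely resamples
    assert 0.35 < missing.mean() < 0.65


def test_bootstrap_deterministic_given_seed():
    sets = {("A", "b1"): (np.arange(20.0), np.arange(20) % 2 == 0)}
    a = fa.stratified_bootstrap(sets, 50, np.random.default_rng(9))
    b = fa.stratified_bootstrap(sets, 50, np.random.default_rng(9))
    np.testing.assert_array_equal(a[("A", "b1")], b[("A", "b1")])


def test_bootstrap_mean_consistent_with_point_auc(rng):
    """Large balanced stratum, B=2,000: bootstrap AUC mean within 3
    bootstrap SEs of the point estimate."""
    n = 1000
    labels = np.arange(n) % 2 == 0
    scores = rng.normal(0, 1, n) + labels
    point = fa.compute_auc(scores[labels], scores[~labels])
    boot, _ = fa.bootstrap_auc(scores, labels, 2000, rng)
    se = boot.std(ddof=1) / math.sqrt(boot.size)
    assert abs(boot.mean() - point) < 3 * se


def test_empirical_pvalue_definitional_cases():
    ref = np.zeros(1000)
    other = np.zeros(1000)
    other[:37] = 1.0  # other exceeds ref in 37 iterations
    assert fa.empirical_pvalue(ref, other) == pytest.approx(0.037)
    assert fa.empirical_pvalue(ref, ref) == 0.0          # strict inequality
    assert fa.empirical_pvalue(np.zeros(1000), np.ones(1000)) == 1.0


def test_empirical_pvalue_drops_missing_iterations():
    ref = np.array([0.5, np.nan, 0.5, 0.5])
    other = np.array([0.6, 0.6, np.nan, 0.4])
    assert fa.empirical_pvalue(ref, other) == pytest.approx(0.5)
    assert math.isnan(fa.empirical_pvalue(np.full(3, np.nan), np.ones(3)))


def test_empirical_pvalue_add_one_mode():
    ref = np.zeros(100)
    other = np.zeros(100)
    assert fa.empirical_pvalue(ref, other, add_one=True) == pytest.approx(1 / 101)


@pytest.mark.parametrize(
    "p,family,raw,bonf",
    [(0.04, 19, True, False), (0.001, 19, True, True), (0.04, 1, True, True),
     (0.2, 19, False, False)],
)
def test_bonferroni_flags(p, family, raw, bonf):
    assert fa.bonferroni_flags(p, family) == (raw, bonf)


# ---------------------------------------------------------------------------
# evaluate / detect_simpson
# ---------------------------------------------------------------------------


def _make_result(agg_p, bin_ps, family=4):
    binning = fa.AFBinning((1e-4, 1e-3))
    cells = []
    for anc in ("EUR", "AFR"):
        for bin_id, p in zip([*binning.bin_ids, fa.ALL_BIN], [*bin_ps, agg_p]):
            c = fa.FairnessCell("pred", anc, bin_id, 0, 0.01, 50, 50, 0.8)
            if anc != "EUR":
                c.p_vs_reference = p
                c.significant_raw, c.significant_bonferroni = fa.bonferroni_flags(p, family)
            cells.append(c)
    return fa.FairnessResult(cells, "EUR", binning, 200, 0.05, {"pred": family})


def test_detect_simpson_definitional_cases():
    flagged = fa.detect_simpson(_make_result(0.001, [0.4, 0.5, 0.6]))
    assert flagged[("pred", "AFR")] is True
    both = fa.detect_simpson(_make_result(0.001, [0.001, 0.5, 0.6]))
    assert both[("pred", "AFR")] is False
    nothing = fa.detect_simpson(_make_result(0.4, [0.4, 0.5, 0.6]))
    assert nothing[("pred", "AFR")] is False


def test_evaluate_single_ancestry_has_no_pvalues():
    cohort = sy.generate_cohort(
        sy.CohortSpec(
            ancestries=(sy.AncestrySpec("EUR", 1, 400),), n_sites_total=400,
            label_model=sy.LabelModel(0, 0), missense_fraction=1.0,
            score_models={"p": sy.ScoreModel(separation=sy.SeparationLaw((), (1.0,)))},
            seed=3,
        ),
        genotypes=False,
    )
    res = fa.evaluate(
        cohort.variants, fa.AFBinning((1e-4, 1e-3)),
        fa.EvalConfig(predictors=("p",), reference="EUR", B=50, seed=3),
    )
    assert all(math.isnan(c.p_vs_reference) for c in res.cells)
    assert not any(res.simpson_flags.values())


def test_evaluate_missing_reference_raises(demo_cohort):
    with pytest.raises(ConfigurationError, match="reference ancestry"):
        fa.evaluate(
            demo_cohort.variants, fa.AFBinning((1e-4,)),
            fa.EvalConfig(predictors=("revel_like",), reference="NOPE", B=10),
        )


def test_evaluate_gate_reports_reason(demo_cohort):
    res = fa.evaluate(
        demo_cohort.variants, fa.AFBinning((1e-4, 1e-3)),
        fa.EvalConfig(predictors=("revel_like",), reference="EUR", B=20,
                      min_pos=10_000, min_neg=10_000, seed=0),
    )
    assert all(math.isnan(c.auc) for c in res.cells)
    assert all("below gate" in c.reason for c in res.cells)


def test_evaluate_deterministic_and_exclusions(demo_cohort):
    frame = demo_cohort.variants
    cfg = dict(predictors=("revel_like",), reference="EUR", B=50, seed=5)
    r1 = fa.evaluate(frame, fa.AFBinning((1e-4, 1e-3)), fa.EvalConfig(**cfg))
    r2 = fa.evaluate(frame, fa.AFBinning((1e-4, 1e-3)), fa.EvalConfig(**cfg))
    pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())
    # excluding some training variants changes the class counts
    excl = frozenset(frame["variant_id"].iloc[:300])
    r3 = fa.evaluate(
        frame, fa.AFBinning((1e-4, 1e-3)),
        fa.EvalConfig(exclusions={"revel_like": excl}, **cfg),
    )
    n1 = r1.to_frame()[["n_pos", "n_neg"]].to_numpy().sum()
    n3 = r3.to_frame()[["n_pos", "n_neg"]].to_numpy().sum()
    assert n3 < n1


def test_estimated_bin_aucs_decrease_with_af():
    """With a declining separation law, estimated bin AUCs are
    nonincreasing in AF (large strata)."""
    cohort = sy.generate_cohort(simpson_spec(21, n_variants=8000), genotypes=False)
    res = fa.evaluate(
        cohort.variants, fa.AFBinning((1e-4, 1e-3)),
        fa.EvalConfig(predictors=("pred",), reference="EUR", B=10, seed=21),
    )
    for anc in ("EUR", "AFR"):
        aucs = [res.cell("pred", anc, b).auc
                for b in fa.AFBinning((1e-4, 1e-3)).bin_ids]
        aucs = [a for a in aucs if not math.isnan(a)]
        assert all(a >= b for a, b in zip(aucs, aucs[1:]))


def test_evaluate_simpson_cohort_flags_reversal():
    cohort = sy.generate_cohort(simpson_spec(17), genotypes=False)
    res = fa.evaluate(
        cohort.variants, fa.AFBinning((1e-4, 1e-3)),
        fa.EvalConfig(predictors=("pred",), reference="EUR", B=200, seed=17),
    )
    agg = res.cell("pred", "AFR", fa.ALL_BIN)
    assert agg.significant_bonferroni
    assert res.simpson_flags[("pred", "AFR")]
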