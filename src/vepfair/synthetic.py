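"""Synthetic cohort generator with closed-form ground truth.

Real per-genome data of the kind this pipeline analyses (biobank exomes
joined to gnomAD per-ancestry allele frequencies and ClinVar/HGMD labels)
are access-controlled.  This module generates cohorts that reproduce the
statistical structure the downstream analysis assumes, each feature with a
closed-form expectation so that every pipeline stage can be tested against
theory:

* per-ancestry rare-variant allele frequencies from a truncated power law
  (rarer variants are more numerous), with unequal numbers of segregating
  sites and unequal sample sizes across ancestries;
* pathogenicity probability decreasing with allele frequency via a logistic
  model on log10 AF;
* predictor scores from a binormal model whose class separation d(AF) is a
  nonincreasing step function of AF, so that bin-wise discrimination
  (AUC = Phi(d / (sigma * sqrt(2)))) declines as variants become common;
* evolutionary-conservation scores correlated with the true label;
* per-individual genotypes drawn Binomial(2, p) per site, giving an
  expected heterozygous burden of sum_v 2 p_v (1 - p_v) per person.

All randomness flows from a single master seed; each generation stage
consumes an independently spawned substream, so adding a stage never
perturbs the draws of earlier stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .errors import ConfigurationError, DataError

__all__ = [
    "AFLaw",
    "AncestrySpec",
    "LabelModel",
    "SeparationLaw",
    "ScoreModel",
    "ConservationModel",
    "CohortSpec",
    "CohortTruth",
    "SyntheticCohort",
    "sample_site_frequencies",
    "assign_labels",
    "simulate_scores",
    "sample_genotypes",
    "theoretical_het_burden",
    "generate_cohort",
    "demo_spec",
    "write_cohort",
]

_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Specification dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AFLaw:
    """Truncated power-law allele-frequency distribution.

    Density proportional to ``x ** -alpha`` on ``[af_min, af_max]``.
    ``alpha = 1`` gives the log-uniform (reciprocal) law, a neutral-SFS-like
    default in which every decade of frequency holds equal mass.
    """

    alpha: float = 1.0
    af_min: float = 1e-5
    af_max: float = 0.01

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ConfigurationError(f"af_law.alpha must be > 0, got {self.alpha}")
        if not 0 < self.af_min < self.af_max:
            raise ConfigurationError(
                f"af_law requires 0 < af_min < af_max, got [{self.af_min}, {self.af_max}]"
            )
        if self.af_max > 0.01:
            raise ConfigurationError(
                f"af_law.af_max must be <= 0.01 (the rarity cutoff), got {self.af_max}"
            )

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling from the truncated power law."""
        u = rng.random(size)
        lo, hi, a = self.af_min, self.af_max, self.alpha
        if abs(a - 1.0) < 1e-12:
            return lo * (hi / lo) ** u
        e = 1.0 - a
        return (lo**e + u * (hi**e - lo**e)) ** (1.0 / e)

    def mean_log10(self) -> float:
        """Analytic mean of log10(AF) under the law (for calibration checks)."""
        lo, hi, a = self.af_min, self.af_max, self.alpha
        if abs(a - 1.0) < 1e-12:
            # log-uniform: log10 AF ~ Uniform(log10 lo, log10 hi)
            return 0.5 * (math.log10(lo) + math.log10(hi))
        e = 1.0 - a
        z = (hi**e - lo**e) / e
        # integral of ln(x) x^-a dx = [x^e (e ln x - 1)] / e^2
        num = (hi**e * (e * math.log(hi) - 1) - lo**e * (e * math.log(lo) - 1)) / e**2
        return num / z / math.log(10.0)


@dataclass(frozen=True)
class AncestrySpec:
    """One ancestry group: sample size, segregating sites, and AF law."""

    name: str
    n_individuals: int
    n_sites_present: int
    af_law: AFLaw = field(default_factory=AFLaw)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError(
                f"ancestry {self.name!r}: n_individuals must be >= 1, got {self.n_individuals}"
            )
        if self.n_sites_present < 1:
            raise ConfigurationError(
                f"ancestry {self.name!r}: n_sites_present must be >= 1, got {self.n_sites_present}"
            )


@dataclass(frozen=True)
class LabelModel:
    """P(pathogenic | AF) = logistic(intercept + slope * log10 AF).

    A negative slope makes rarer variants more likely pathogenic, the
    empirical pattern in curated clinical databases.  slope = 0 gives a flat
    model, useful for controlled null experiments.
    """

    intercept: float = 0.0
    slope: float = 0.0

    def prob_pathogenic(self, afs: np.ndarray) -> np.ndarray:
        afs = np.asarray(afs, dtype=float)
        if np.any(afs <= 0):
            raise DataError("assign_labels requires AF > 0 for every site")
        return expit(self.intercept + self.slope * np.log10(afs))


@dataclass(frozen=True)
class SeparationLaw:
    """Nonincreasing step function d(AF): the binormal class separation.

    ``breakpoints`` are interior AF edges; ``d_values`` has one entry per
    AF bin (``len(breakpoints) + 1``), nonincreasing so that discrimination
    declines as allele frequency rises.
    """

    breakpoints: tuple[float, ...]
    d_values: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        dv = np.asarray(self.d_values, dtype=float)
        if len(dv) != len(bp) + 1:
            raise ConfigurationError(
                "separation_law: need len(d_values) == len(breakpoints) + 1, "
                f"got {len(dv)} values for {len(bp)} breakpoints"
            )
        if len(bp) and np.any(np.diff(bp) <= 0):
            raise ConfigurationError("separation_law.breakpoints must be strictly increasing")
        if np.any(np.diff(dv) > 0):
            raise ConfigurationError("separation_law.d_values must be nonincreasing in AF")
        if np.any(dv < 0):
            raise ConfigurationError("separation_law.d_values must be >= 0")

    @classmethod
    def from_range(
        cls, d_max: float, d_min: float, breakpoints: Sequence[float]
    ) -> "SeparationLaw":
        """Linear ramp from d_max (rarest bin) down to d_min (commonest)."""
        n = len(breakpoints) + 1
        return cls(tuple(breakpoints), tuple(np.linspace(d_max, d_min, n)))

    def d(self, afs: np.ndarray) -> np.ndarray:
        afs = np.asarray(afs, dtype=float)
        idx = np.searchsorted(np.asarray(self.breakpoints), afs, side="right")
        return np.asarray(self.d_values, dtype=float)[idx]


@dataclass(frozen=True)
class ScoreModel:
    """Binormal predictor-score model.

    Latent score ~ Normal(mu_benign + d(AF) * 1[pathogenic], sigma^2), mapped
    to [0, 1] by a fixed logistic squashing.  The squashing is monotone, so
    every rank-based statistic (AUC, threshold-interval mapping after the
    same transform) is unchanged; the implied AUC within an AF bin is
    Phi(d / (sigma * sqrt(2))).
    """

    mu_benign: float = 0.0
    separation: SeparationLaw = field(
        default_factory=lambda: SeparationLaw((), (1.0,))
    )
    sigma: float = 1.0
    higher_is_pathogenic: bool = True

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigurationError(f"score model sigma must be > 0, got {self.sigma}")

    def theoretical_auc(self, afs: np.ndarray) -> np.ndarray:
        """Closed-form bin-wise AUC: Phi(d(AF) / (sigma * sqrt(2)))."""
        return ndtr(self.d(afs) / (self.sigma * _SQRT2))

    def d(self, afs: np.ndarray) -> np.ndarray:
        return self.separation.d(afs)

    def squash(self, latent: np.ndarray) -> np.ndarray:
        # fixed monotone map; center halfway up the largest separation so the
        # score range is used symmetrically
        center = self.mu_benign + 0.5 * max(self.separation.d_values)
        scaled = expit((latent - center) / self.sigma)
        return scaled if self.higher_is_pathogenic else 1.0 - scaled


@dataclass(frozen=True)
class ConservationModel:
    """Evolutionary-conservation score (GERP++-rank-like, descriptive only).

    Normal(mean_by_label + af_slope * log10 AF, sd^2); pathogenic sites are
    more conserved, and conservation drifts with AF at rate af_slope.
    """

    mean_pathogenic: float = 0.8
    mean_benign: float = 0.45
    sd: float = 0.15
    af_slope: float = 0.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ConfigurationError(f"conservation_model.sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort.

    Site accounting: the first ``round(shared_site_fraction * n_sites_total)``
    sites are present in every ancestry; the rest are private, partitioned so
    ancestry ``a`` holds ``a.n_sites_present - n_shared`` of them.  The counts
    must balance exactly; ``generate_cohort`` validates this.
    """

    ancestries: tuple[AncestrySpec, ...]
    n_sites_total: int
    shared_site_fraction: float = 0.0
    label_model: LabelModel = field(default_factory=LabelModel)
    score_models: Mapping[str, ScoreModel] = field(default_factory=dict)
    conservation_model: ConservationModel = field(default_factory=ConservationModel)
    missense_fraction: float = 0.7
    n_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        names = [a.name for a in self.ancestries]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"ancestry names must be unique, got {names}")
        if not self.ancestries:
            raise ConfigurationError("ancestries must be non-empty")
        if not 0 <= self.shared_site_fraction <= 1:
            raise ConfigurationError(
                f"shared_site_fraction must be in [0, 1], got {self.shared_site_fraction}"
            )
        if not 0 <= self.missense_fraction <= 1:
            raise ConfigurationError(
                f"missense_fraction must be in [0, 1], got {self.missense_fraction}"
            )
        if self.n_sites_total < 1:
            raise ConfigurationError("n_sites_total must be >= 1")

    @property
    def n_shared(self) -> int:
        return int(round(self.shared_site_fraction * self.n_sites_total))

    def validate_site_accounting(self) -> None:
        n_shared = self.n_shared
        private = []
        for a in self.ancestries:
            p = a.n_sites_present - n_shared
            if p < 0:
                raise ConfigurationError(
                    f"ancestry {a.name!r}: n_sites_present={a.n_sites_present} is smaller "
                    f"than the shared-site count {n_shared}"
                )
            private.append(p)
        total = n_shared + sum(private)
        if total != self.n_sites_total:
            raise ConfigurationError(
                f"site accounting does not balance: shared {n_shared} + private "
                f"{sum(private)} = {total} != n_sites_total {self.n_sites_total}"
            )


# ---------------------------------------------------------------------------
# Generation stages
# ---------------------------------------------------------------------------


def sample_site_frequencies(
    spec: CohortSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-ancestry AF vectors of length ``n_sites_total``.

    A site absent from an ancestry has AF exactly 0.  Presence is allocated
    deterministically (shared block first, then private blocks in ancestry
    order), so the shared-site fraction is matched exactly; the rng draws
    the frequencies only.
    """
    spec.validate_site_accounting()
    n_shared = spec.n_shared
    afs: dict[str, np.ndarray] = {}
    offset = n_shared
    for a in spec.ancestries:
        present = np.zeros(spec.n_sites_total, dtype=bool)
        present[:n_shared] = True
        n_private = a.n_sites_present - n_shared
        present[offset : offset + n_private] = True
        offset += n_private
        v = np.zeros(spec.n_sites_total)
        v[present] = a.af_law.sample(int(present.sum()), rng)
        afs[a.name] = v
    return afs


def assign_labels(
    afs: np.ndarray, model: LabelModel, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli pathogenic labels with P = logistic(a + b log10 AF)."""
    p = model.prob_pathogenic(afs)
    return rng.random(p.shape) < p


def simulate_scores(
    labels: np.ndarray,
    afs: np.ndarray,
    model: ScoreModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binormal latent scores squashed monotonically into [0, 1]."""
    labels = np.asarray(labels, dtype=bool)
    afs = np.asarray(afs, dtype=float)
    if labels.shape != afs.shape:
        raise DataError("labels and afs must be aligned")
    latent = model.mu_benign + model.d(afs) * labels + rng.normal(0.0, model.sigma, labels.shape)
    return model.squash(latent)


def sample_genotypes(
    afs: np.ndarray, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_individuals x n_sites) diploid dosages, each ~ Binomial(2, p)."""
    afs = np.asarray(afs, dtype=float)
    if np.any((afs < 0) | (afs > 1)):
        raise DataError("allele frequencies must lie in [0, 1]")
    return rng.binomial(2, afs, size=(n_individuals, afs.size)).astype(np.int8)


def theoretical_het_burden(afs: np.ndarray) -> float:
    """Expected heterozygous sites per individual: sum_v 2 p_v (1 - p_v)."""
    p = np.asarray(afs, dtype=float)
    return float(np.sum(2.0 * p * (1.0 - p)))


def het_burden_se_of_mean(afs: np.ndarray, n_individuals: int) -> float:
    """Analytic SE of the mean per-person het count over n individuals.

    Per-site het indicators are independent Bernoulli(2p(1-p)).
    """
    h = 2.0 * np.asarray(afs, dtype=float) * (1.0 - np.asarray(afs, dtype=float))
    return float(math.sqrt(np.sum(h * (1.0 - h)) / n_individuals))


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortTruth:
    """Generator ground truth for testing downstream stages."""

    labels: np.ndarray  # bool, per site: True = pathogenic
    basis_af: np.ndarray  # AF used for label/score/conservation models
    prob_pathogenic: np.ndarray
    theoretical_auc_by_bin: dict[str, list[dict]]  # predictor -> [{lo, hi, auc}]
    expected_het_burden: dict[str, float]  # ancestry -> sum 2p(1-p)

    def to_jsonable(self) -> dict:
        return {
            "n_pathogenic": int(self.labels.sum()),
            "n_sites": int(self.labels.size),
            "theoretical_auc_by_bin": self.theoretical_auc_by_bin,
            "expected_het_burden": self.expected_het_burden,
        }


@dataclass
class SyntheticCohort:
    """A generated cohort: variant table, genotypes, and ground truth."""

    spec: CohortSpec
    variants: pd.DataFrame  # one row per site; see column layout below
    genotypes: dict[str, np.ndarray]  # ancestry -> (n_individuals x n_sites)
    truth: CohortTruth

    @property
    def ancestry_names(self) -> list[str]:
        return [a.name for a in self.spec.ancestries]

    def af_vector(self, ancestry: str) -> np.ndarray:
        return self.variants[f"af_{ancestry}"].fillna(0.0).to_numpy()


def _stage_streams(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Independent substreams in fixed stage order; appending stages later
    never perturbs earlier draws."""
    return np.random.SeedSequence(seed).spawn(n)


def generate_cohort(spec: CohortSpec, genotypes: bool = True) -> SyntheticCohort:
    """Generate a full cohort; deterministic given ``spec.seed``.

    Stage order (each on its own seed substream): site frequencies,
    consequence mix, labels, per-predictor scores, conservation, genotypes.
    Set ``genotypes=False`` to skip the genotype matrices when only the
    variant-level table is needed (e.g. classifier-fairness experiments).
    """
    spec.validate_site_accounting()
    ss_af, ss_cons, ss_label, ss_score, ss_gerp, ss_geno = _stage_streams(spec.seed, 6)
    rng_af = np.random.default_rng(ss_af)
    rng_cons = np.random.default_rng(ss_cons)
    rng_label = np.random.default_rng(ss_label)
    rng_gerp = np.random.default_rng(ss_gerp)

    afs = sample_site_frequencies(spec, rng_af)
    af_matrix = np.column_stack([afs[a.name] for a in spec.ancestries])
    present = af_matrix > 0

    # basis AF: geometric mean over present ancestries (models are linear in
    # log10 AF, so the geometric mean is the natural cross-ancestry summary)
    with np.errstate(divide="ignore"):
        logs = np.where(present, np.log(np.where(present, af_matrix, 1.0)), 0.0)
    basis_af = np.exp(logs.sum(axis=1) / present.sum(axis=1))

    n = spec.n_sites_total
    is_missense = rng_cons.random(n) < spec.missense_fraction

    prob_path = spec.label_model.prob_pathogenic(basis_af)
    labels = rng_label.random(n) < prob_path
    labels &= is_missense  # synonymous sites are neutral controls

    predictors = sorted(spec.score_models)
    score_children = ss_score.spawn(len(predictors)) if predictors else []
    scores = {
        p: simulate_scores(labels, basis_af, spec.score_models[p], np.random.default_rng(c))
        for p, c in zip(predictors, score_children)
    }

    cm = spec.conservation_model
    cons_mean = np.where(labels, cm.mean_pathogenic, cm.mean_benign) + cm.af_slope * np.log10(basis_af)
    conservation = rng_gerp.normal(cons_mean, cm.sd)

    geno: dict[str, np.ndarray] = {}
    if genotypes:
        geno_children = ss_geno.spawn(len(spec.ancestries))
        for a, child in zip(spec.ancestries, geno_children):
            geno[a.name] = sample_genotypes(afs[a.name], a.n_individuals, np.random.default_rng(child))

    frame = pd.DataFrame(
        {
            "variant_id": [f"1-{i + 1}-A-G" for i in range(n)],
            "gene": [f"GENE{i % spec.n_genes}" for i in range(n)],
            "consequence": np.where(is_missense, "missense", "synonymous"),
            "label": np.where(labels, "pathogenic", "benign"),
            "label_source": "synthetic",
            "conservation": conservation,
        }
    )
    for a in spec.ancestries:
        frame[f"af_{a.name}"] = np.where(afs[a.name] > 0, afs[a.name], np.nan)
    for p in predictors:
        frame[f"score_{p}"] = scores[p]

    truth = CohortTruth(
        labels=labels,
        basis_af=basis_af,
        prob_pathogenic=prob_path,
        theoretical_auc_by_bin={p: _auc_table(spec, spec.score_models[p]) for p in predictors},
        expected_het_burden={a.name: theoretical_het_burden(afs[a.name]) for a in spec.ancestries},
    )
    return SyntheticCohort(spec=spec, variants=frame, genotypes=geno, truth=truth)


def _auc_table(spec: CohortSpec, model: ScoreModel) -> list[dict]:
    lo = min(a.af_law.af_min for a in spec.ancestries)
    hi = max(a.af_law.af_max for a in spec.ancestries)
    edges = [lo, *[b for b in model.separation.breakpoints if lo < b < hi], hi]
    out = []
    for b_lo, b_hi in zip(edges[:-1], edges[1:]):
        mid = math.sqrt(b_lo * b_hi)
        out.append(
            {"lo": b_lo, "hi": b_hi, "auc": float(model.theoretical_auc(np.array([mid]))[0])}
        )
    return out


# ---------------------------------------------------------------------------
# Serialization and demo configuration
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write variants TSV, per-ancestry genotype TSVs, and truth JSON."""
    from .variants import write_variant_frame  # local import to avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["variants"] = out / "variants.tsv"
    write_variant_frame(cohort.variants, paths["variants"])

    for name, g in cohort.genotypes.items():
        p = out / f"genotypes_{name}.tsv"
        gf = pd.DataFrame(
            g,
            index=[f"{name}_{i}" for i in range(g.shape[0])],
            columns=cohort.variants["variant_id"],
        )
        gf.index.name = "individual_id"
        gf.to_csv(p, sep="\t")
        paths[f"genotypes_{name}"] = p

    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(cohort.truth.to_jsonable(), indent=2))
    return paths


def demo_spec(seed: int = 0) -> CohortSpec:
    """A small three-ancestry demonstration cohort.

    EUR has the largest sample and the rarest-shifted AF law (emulating the
    much deeper European sampling of reference databases); AFR carries the
    most segregating sites per genome.  Three predictors with distinct,
    AF-declining separation laws emulate a REVEL/MutPred2/AlphaMissense-like
    panel.
    """
    laws = {
        "EUR": AFLaw(alpha=1.3, af_min=2e-5, af_max=0.01),
        "AFR": AFLaw(alpha=0.9, af_min=5e-5, af_max=0.01),
        "EAS": AFLaw(alpha=1.0, af_min=5e-5, af_max=0.01),
    }
    # shared 600 + private (300, 200, 100) = 1200 sites
    ancestries = (
        AncestrySpec("EUR", n_individuals=300, n_sites_present=900, af_law=laws["EUR"]),
        AncestrySpec("AFR", n_individuals=120, n_sites_present=800, af_law=laws["AFR"]),
        AncestrySpec("EAS", n_individuals=80, n_sites_present=700, af_law=laws["EAS"]),
    )
    bp = (1e-4, 1e-3)
    score_models = {
        "revel_like": ScoreModel(separation=SeparationLaw(bp, (2.3, 1.5, 0.9))),
        "mutpred_like": ScoreModel(separation=SeparationLaw(bp, (2.1, 1.4, 0.8))),
        "alphamissense_like": ScoreModel(separation=SeparationLaw(bp, (2.5, 1.6, 1.0))),
    }
    return CohortSpec(
        ancestries=ancestries,
        n_sites_total=1200,
        shared_site_fraction=0.5,
        label_model=LabelModel(intercept=-3.5, slope=-0.8),
        score_models=score_models,
        conservation_model=ConservationModel(af_slope=-0.02),
        missense_fraction=0.7,
        seed=seed,
    )
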