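"""Allele-frequency-binned, ancestry-stratified AUC comparison.

The question this module answers: do variant effect predictors discriminate
pathogenic from benign variants equally well across genetic ancestries?
Because rarer variants are both more likely pathogenic and more accurately
predicted, and ancestry groups differ sharply in their rare-variant AF
mixtures, the aggregate (all-variants) comparison is confounded by allele
frequency: an aggregate AUC gap can appear between ancestries whose
performance is identical within every AF bin (Simpson's reversal).

The evaluation therefore computes, per predictor, the Mann-Whitney AUC for
every ancestry in each AF bin and in the "all" aggregate, bootstraps the
variants with replacement independently within each (ancestry x AF bin)
stratum (the aggregate resample is the union of its bin-stratum resamples,
so stratum sizes are preserved), and reports the one-sided empirical
p-value: the fraction of paired iterations in which the comparison
ancestry's AUC exceeded the reference ancestry's.  Bonferroni-corrected
significance and a Simpson's-reversal flag (aggregate significant, no bin
significant, both post-correction) complete the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, DataError

__all__ = [
    "AFBinning",
    "EvalConfig",
    "FairnessCell",
    "FairnessResult",
    "compute_auc",
    "bootstrap_auc",
    "bin_variants",
    "stratified_bootstrap",
    "empirical_pvalue",
    "bonferroni_flags",
    "evaluate",
    "detect_simpson",
    "binormal_auc_ci",
]

ALL_BIN = "all"


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def compute_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties.

    (#{pairs pos > neg} + 0.5 * #{ties}) / (n_pos * n_neg); identical to the
    trapezoidal ROC area.  Returns NaN when either class is empty.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    n_pos, n_neg = pos.size, neg.size
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for a (B x n) score matrix with aligned
    boolean labels; NaN where a row lost a class."""
    r = rankdata(scores, axis=1)
    y = labels.astype(float)
    n = scores.shape[1]
    n_pos = y.sum(axis=1)
    n_neg = n - n_pos
    pos_rank_sum = (r * y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    auc[(n_pos == 0) | (n_neg == 0)] = np.nan
    return auc


def bootstrap_auc(
    scores: np.ndarray, labels: np.ndarray, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """B bootstrap AUCs for one stratum; also returns the (B x n) resample
    index matrix so aggregate cells can reuse the same stratified draws."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n = scores.size
    idx = rng.integers(0, n, size=(B, n))
    return _auc_rows(scores[idx], labels[idx]), idx


def binormal_auc_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.99
) -> tuple[float, float]:
    """Hanley-McNeil confidence interval for an empirical AUC."""
    from scipy.stats import norm

    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    z = norm.ppf(0.5 + level / 2)
    half = z * float(np.sqrt(max(var, 0.0)))
    return a - half, a + half


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AFBinning:
    """Half-open AF bins over (0, 0.01): (0, e1), [e1, e2), ..., [ek, 0.01).

    The bin boundaries behind published AF-stratified evaluations are rarely
    stated, so the edges are configuration, echoed into every output.
    """

    edges: tuple[float, ...] = (1e-5, 1e-4, 1e-3)
    upper: float = 0.01

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size == 0:
            raise ConfigurationError("AFBinning needs at least one interior edge")
        if np.any(np.diff(e) <= 0):
            raise ConfigurationError(f"bin edges must be strictly increasing, got {self.edges}")
        if e[0] <= 0 or e[-1] >= self.upper:
            raise ConfigurationError(
                f"bin edges must lie strictly inside (0, {self.upper}), got {self.edges}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    @property
    def bin_ids(self) -> list[str]:
        bounds = self.bounds()
        return [f"[{lo:g},{hi:g})" for lo, hi in bounds]

    def bounds(self) -> list[tuple[float, float]]:
        e = [0.0, *self.edges, self.upper]
        return list(zip(e[:-1], e[1:]))

    def assign(self, afs: np.ndarray) -> np.ndarray:
        """Bin index per AF; raises on AF outside (0, upper)."""
        afs = np.asarray(afs, dtype=float)
        if np.any(~(afs > 0) | (afs >= self.upper)):
            raise DataError(
                f"AF outside (0, {self.upper}); run the rarity filter before binning"
            )
        return np.searchsorted(np.asarray(self.edges), afs, side="right")


def bin_variants(
    frame: pd.DataFrame, binning: AFBinning, ancestry: str
) -> dict[str, np.ndarray]:
    """Positional indices of the ancestry's variants per bin (plus 'all').

    The frame rows are the ancestry's membership subset; binning uses that
    ancestry's own AF column.
    """
    af = frame[f"af_{ancestry}"].to_numpy(dtype=float)
    idx = binning.assign(af)
    out = {b: np.flatnonzero(idx == i) for i, b in enumerate(binning.bin_ids)}
    out[ALL_BIN] = np.arange(len(frame))
    return out


# ---------------------------------------------------------------------------
# Bootstrap machinery
# ---------------------------------------------------------------------------


def stratified_bootstrap(
    labeled_sets: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    B: int,
    rng: np.random.Generator,
) -> dict[tuple[str, str], np.ndarray]:
    """B resampled AUCs per (ancestry, bin) stratum.

    Each iteration resamples variants with replacement independently within
    each stratum, preserving the stratum size; iterations in which a stratum
    loses a class entirely yield NaN for that stratum-iteration.
    """
    if B < 1:
        raise ConfigurationError(f"bootstrap iterations B must be >= 1, got {B}")
    out = {}
    for key in sorted(labeled_sets):
        scores, labels = labeled_sets[key]
        out[key], _ = bootstrap_auc(scores, labels, B, rng)
    return out


def empirical_pvalue(
    ref_boot: np.ndarray, other_boot: np.ndarray, add_one: bool = False
) -> float:
    """One-sided empirical p: fraction of paired iterations in which the
    comparison group's AUC exceeded the reference's (strict inequality).

    Iterations with a missing AUC on either side are dropped from both the
    numerator and the denominator.  ``add_one`` switches to the
    (k+1)/(m+1) estimator (off by default).
    """
    ref = np.asarray(ref_boot, dtype=float)
    other = np.asarray(other_boot, dtype=float)
    usable = ~(np.isnan(ref) | np.isnan(other))
    m = int(usable.sum())
    if m == 0:
        return float("nan")
    k = int((other[usable] > ref[usable]).sum())
    return (k + 1) / (m + 1) if add_one else k / m


def bonferroni_flags(
    pval: float, family_size: int, alpha: float = 0.05
) -> tuple[bool, bool]:
    """(significant at alpha, significant at alpha / family_size)."""
    if family_size < 1:
        raise ConfigurationError(f"family_size must be >= 1, got {family_size}")
    if np.isnan(pval):
        return False, False
    return pval < alpha, pval < alpha / family_size


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------


@dataclass
class FairnessCell:
    predictor: str
    ancestry: str
    bin: str
    bin_lo: float
    bin_hi: float
    n_pos: int
    n_neg: int
    auc: float  # NaN when the minimum-count gate fails
    p_vs_reference: float = float("nan")
    significant_raw: bool = False
    significant_bonferroni: bool = False
    reason: str = ""
    boot_aucs: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class EvalConfig:
    predictors: tuple[str, ...]
    reference: str = "EUR"
    B: int = 1000
    alpha: float = 0.05
    family_size: int | None = None  # None: p-values computed per predictor grid
    min_pos: int = 10
    min_neg: int = 10
    add_one: bool = False
    missense_only: bool = True
    seed: int = 0
    exclusions: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ConfigurationError("EvalConfig.predictors must be non-empty")
        if self.B < 1:
            raise ConfigurationError(f"B must be >= 1, got {self.B}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class FairnessResult:
    cells: list[FairnessCell]
    reference: str
    binning: AFBinning
    B: int
    alpha: float
    family_sizes: dict[str, int]  # predictor -> divisor used
    simpson_flags: dict[tuple[str, str], bool] = field(default_factory=dict)
    config: EvalConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": c.predictor,
                "ancestry": c.ancestry,
                "bin": c.bin,
                "bin_lo": c.bin_lo,
                "bin_hi": c.bin_hi,
                "n_pos": c.n_pos,
                "n_neg": c.n_neg,
                "auc": c.auc,
                "p": c.p_vs_reference,
                "raw_sig": c.significant_raw,
                "bonf_sig": c.significant_bonferroni,
                "reason": c.reason,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)

    def summary_json(self) -> str:
        payload = {
            "reference": self.reference,
            "bin_edges": list(self.binning.edges),
            "bin_upper": self.binning.upper,
            "B": self.B,
            "alpha": self.alpha,
            "family_sizes": self.family_sizes,
            "seed": None if self.config is None else self.config.seed,
            "min_pos": None if self.config is None else self.config.min_pos,
            "min_neg": None if self.config is None else self.config.min_neg,
            "simpson_flags": {
                f"{p}|{a}": bool(v) for (p, a), v in self.simpson_flags.items()
            },
            "n_cells": len(self.cells),
        }
        return json.dumps(payload, indent=2)

    def cell(self, predictor: str, ancestry: str, bin_id: str) -> FairnessCell:
        for c in self.cells:
            if (c.predictor, c.ancestry, c.bin) == (predictor, ancestry, bin_id):
                return c
        raise KeyError((predictor, ancestry, bin_id))


def _labeled_subframe(frame: pd.DataFrame, predictor: str, cfg: EvalConfig) -> pd.DataFrame:
    mask = frame["label"].isin(["pathogenic", "benign"])
    if cfg.missense_only and "consequence" in frame.columns:
        mask &= frame["consequence"] == "missense"
    mask &= frame[f"score_{predictor}"].notna()
    excluded = cfg.exclusions.get(predictor)
    if excluded:
        mask &= ~frame["variant_id"].isin(excluded)
    return frame.loc[mask].reset_index(drop=True)


def evaluate(
    frame: pd.DataFrame,
    binning: AFBinning,
    config: EvalConfig,
) -> FairnessResult:
    """Full fairness grid over predictors x ancestries x (bins + 'all').

    ``frame`` is a wide variant table (labels harmonized, rarity filter and
    gene restriction already applied) with ``af_<ANCESTRY>`` and
    ``score_<PREDICTOR>`` columns.  Ancestry membership is AF > 0.  Cells
    below the minimum class-count gate carry a missing AUC and a reason;
    p-values compare each non-reference ancestry against the reference,
    paired by bootstrap iteration.
    """
    ancestries = sorted(c[3:] for c in frame.columns if c.startswith("af_"))
    if config.reference not in ancestries:
        raise ConfigurationError(
            f"reference ancestry {config.reference!r} not in table; options: {ancestries}"
        )

    bounds = dict(zip(binning.bin_ids, binning.bounds()))
    bounds[ALL_BIN] = (0.0, binning.upper)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    all_cells: list[FairnessCell] = []
    family_sizes: dict[str, int] = {}
    simpson_flags: dict[tuple[str, str], bool] = {}

    for predictor in config.predictors:
        if f"score_{predictor}" not in frame.columns:
            raise ConfigurationError(f"variant table has no score column for {predictor!r}")
        sub = _labeled_subframe(frame, predictor, config)
        labels_all = (sub["label"] == "pathogenic").to_numpy()
        scores_all = sub[f"score_{predictor}"].to_numpy(dtype=float)

        # per-ancestry bootstrap AUC matrices per bin; aggregate from the
        # union of the per-bin stratified resamples
        cells: dict[tuple[str, str], FairnessCell] = {}
        boots: dict[tuple[str, str], np.ndarray] = {}
        for anc in ancestries:
            member = sub[f"af_{anc}"].to_numpy(dtype=float) > 0
            midx = np.flatnonzero(member)
            mframe = sub.loc[member].reset_index(drop=True)
            bin_map = bin_variants(mframe, binning, anc) if len(mframe) else {
                b: np.array([], dtype=int) for b in [*binning.bin_ids, ALL_BIN]
            }
            agg_scores: list[np.ndarray] = []
            agg_labels: list[np.ndarray] = []
            for bin_id in binning.bin_ids:
                rows = midx[bin_map[bin_id]]
                s, y = scores_all[rows], labels_all[rows]
                n_pos, n_neg = int(y.sum()), int((~y).sum())
                cell = FairnessCell(
                    predictor, anc, bin_id, *bounds[bin_id], n_pos, n_neg, float("nan")
                )
                if n_pos >= config.min_pos and n_neg >= config.min_neg:
                    cell.auc = compute_auc(s[y], s[~y])
                else:
                    cell.reason = f"class counts below gate ({n_pos} pos, {n_neg} neg)"
                if s.size:
                    boot, idx = bootstrap_auc(s, y, config.B, rng)
                    boots[(anc, bin_id)] = boot
                    cell.boot_aucs = boot
                    agg_scores.append(s[idx])
                    agg_labels.append(y[idx])
                cells[(anc, bin_id)] = cell

            # aggregate cell
            rows = midx
            s, y = scores_all[rows], labels_all[rows]
            n_pos, n_neg = int(y.sum()), int((~y).sum())
            cell = FairnessCell(
                predictor, anc, ALL_BIN, *bounds[ALL_BIN], n_pos, n_neg, float("nan")
            )
            if n_pos >= config.min_pos and n_neg >= config.min_neg:
                cell.auc = compute_auc(s[y], s[~y])
            else:
                cell.reason = f"class counts below gate ({n_pos} pos, {n_neg} neg)"
            if agg_scores:
                boot = _auc_rows(
                    np.concatenate(agg_scores, axis=1), np.concatenate(agg_labels, axis=1)
                )
                boots[(anc, ALL_BIN)] = boot
                cell.boot_aucs = boot
            cells[(anc, ALL_BIN)] = cell

        # p-values vs reference, paired by iteration
        p_cells: list[FairnessCell] = []
        for anc in ancestries:
            if anc == config.reference:
                continue
            for bin_id in [*binning.bin_ids, ALL_BIN]:
                cell = cells[(anc, bin_id)]
                ref_cell = cells[(config.reference, bin_id)]
                gate_ok = not np.isnan(cell.auc) and not np.isnan(ref_cell.auc)
                if gate_ok and (anc, bin_id) in boots and (config.reference, bin_id) in boots:
                    cell.p_vs_reference = empirical_pvalue(
                        boots[(config.reference, bin_id)],
                        boots[(anc, bin_id)],
                        add_one=config.add_one,
                    )
                    p_cells.append(cell)

        family = config.family_size if config.family_size is not None else max(len(p_cells), 1)
        family_sizes[predictor] = family
        for cell in p_cells:
            cell.significant_raw, cell.significant_bonferroni = bonferroni_flags(
                cell.p_vs_reference, family, config.alpha
            )

        all_cells.extend(cells[k] for k in sorted(cells))

    result = FairnessResult(
        cells=all_cells,
        reference=config.reference,
        binning=binning,
        B=config.B,
        alpha=config.alpha,
        family_sizes=family_sizes,
        config=config,
    )
    result.simpson_flags = detect_simpson(result)
    return result


def detect_simpson(result: FairnessResult, alpha: float | None = None) -> dict[tuple[str, str], bool]:
    """Flag (predictor, ancestry) pairs showing Simpson's reversal.

    Flagged iff the aggregate ('all') comparison against the reference is
    significant after Bonferroni correction while no per-bin comparison is
    (same corrected criterion for both levels).
    """
    del alpha  # corrected flags are precomputed on the cells
    flags: dict[tuple[str, str], bool] = {}
    by_pa: dict[tuple[str, str], list[FairnessCell]] = {}
    for c in result.cells:
        if c.ancestry == result.reference:
            continue
        by_pa.setdefault((c.predictor, c.ancestry), []).append(c)
    for key, cells in by_pa.items():
        agg = [c for c in cells if c.bin == ALL_BIN]
        bins = [c for c in cells if c.bin != ALL_BIN]
        agg_sig = any(c.significant_bonferroni for c in agg)
        bin_sig = any(c.significant_bonferroni for c in bins)
        flags[key] = bool(agg_sig and not bin_sig)
    return flags
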