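"""Per-individual rare-variant burden and evidence-yield summaries.

For each genome: the count of heterozygous rare missense and synonymous
sites (genotype exactly 1; homozygous-alternate sites are not counted), the
mean allele frequency and mean conservation over those het sites, and the
per-predictor yield of PP3/BP4 evidence categories over het missense sites.
Summaries per ancestry report mean, SD (n-1 denominator), median, and
quartiles (linear interpolation between order statistics — the boxplot
convention used throughout the outputs).

mean_af uses the individual's own ancestry's allele frequency for each
site; sites with missing conservation are excluded from mean_conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DimensionError
from .evidence import CATEGORIES

__all__ = [
    "IndividualBurden",
    "per_individual_burden",
    "evidence_yield_per_individual",
    "average_over_predictors",
    "summarize",
    "burdens_to_frame",
]


@dataclass
class IndividualBurden:
    individual_id: str
    ancestry: str
    het_count_missense: int
    het_count_synonymous: int
    mean_af: float | None
    mean_conservation: float | None
    het_missense_sites: np.ndarray = field(repr=False, default_factory=lambda: np.array([], dtype=int))
    evidence_yield: dict[str, dict[str, float]] = field(default_factory=dict)


def per_individual_burden(
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    ancestry: str,
    individual_ids: Sequence[str] | None = None,
) -> list[IndividualBurden]:
    """Burden rows for every individual in one ancestry's genotype matrix.

    ``genotypes`` is individuals x sites and must align column-for-column
    with ``variants``; the ancestry's AF column ``af_<ancestry>`` supplies
    the frequencies for mean_af.  Counts cover heterozygous sites only.
    """
    G = np.asarray(genotypes)
    if G.ndim != 2 or G.shape[1] != len(variants):
        raise DimensionError(
            f"genotype matrix has {G.shape} but the variant table has {len(variants)} sites"
        )
    af_col = f"af_{ancestry}"
    if af_col not in variants.columns:
        raise ConfigurationError(f"variant table has no AF column for ancestry {ancestry!r}")

    af = variants[af_col].to_numpy(dtype=float)
    cons = (
        variants["conservation"].to_numpy(dtype=float)
        if "conservation" in variants.columns
        else np.full(len(variants), np.nan)
    )
    consequence = variants["consequence"].to_numpy()
    is_mis = consequence == "missense"
    is_syn = consequence == "synonymous"

    het = G == 1
    ids = (
        list(individual_ids)
        if individual_ids is not None
        else [f"{ancestry}_{i}" for i in range(G.shape[0])]
    )
    if len(ids) != G.shape[0]:
        raise DimensionError("individual_ids length does not match the genotype matrix")

    out: list[IndividualBurden] = []
    for i, ind in enumerate(ids):
        h = het[i]
        h_any = h & (is_mis | is_syn)
        n_mis = int((h & is_mis).sum())
        n_syn = int((h & is_syn).sum())
        af_vals = af[h_any]
        af_vals = af_vals[~np.isnan(af_vals)]
        mean_af = float(af_vals.mean()) if af_vals.size else None
        hm = h & is_mis
        cons_vals = cons[hm]
        cons_vals = cons_vals[~np.isnan(cons_vals)]
        mean_cons = float(cons_vals.mean()) if cons_vals.size else None
        out.append(
            IndividualBurden(
                individual_id=ind,
                ancestry=ancestry,
                het_count_missense=n_mis,
                het_count_synonymous=n_syn,
                mean_af=mean_af,
                mean_conservation=mean_cons,
                het_missense_sites=np.flatnonzero(hm),
            )
        )
    return out


def evidence_yield_per_individual(
    burdens: Sequence[IndividualBurden],
    site_points: Mapping[str, np.ndarray],
) -> list[IndividualBurden]:
    """Fill per-predictor evidence-category counts over het missense sites.

    ``site_points`` maps predictor -> per-site evidence points aligned with
    the variant table used to build the burdens (NaN = missing score).
    Sites with a missing score are excluded from that predictor's yield, so
    the category counts sum to the individual's het missense sites that
    carry a score for the predictor.
    """
    point_cat = {4: "PP3-strong", 3: "PP3-moderate", 2: "PP3-moderate", 1: "PP3-supporting",
                 0: "indeterminate", -1: "BP4-supporting", -2: "BP4-moderate",
                 -3: "BP4-moderate", -4: "BP4-strong"}
    for b in burdens:
        b.evidence_yield = {}
        for pred, pts in site_points.items():
            pts = np.asarray(pts, dtype=float)
            mine = pts[b.het_missense_sites]
            mine = mine[~np.isnan(mine)]
            counts = {c: 0.0 for c in CATEGORIES}
            for p in mine:
                counts[point_cat[int(p)]] += 1
            b.evidence_yield[pred] = counts
    return list(burdens)


def average_over_predictors(
    yields: Mapping[str, Mapping[str, float]], predictors: Sequence[str]
) -> dict[str, float]:
    """Per-category arithmetic mean of one individual's counts across
    predictors (may be fractional)."""
    if not predictors:
        raise ConfigurationError("average_over_predictors requires at least one predictor")
    for p in predictors:
        if p not in yields:
            raise ConfigurationError(f"no evidence yield for predictor {p!r}")
    return {
        c: float(np.mean([yields[p].get(c, 0.0) for p in predictors])) for c in CATEGORIES
    }


def burdens_to_frame(burdens: Sequence[IndividualBurden]) -> pd.DataFrame:
    """Long per-individual table (evidence yield flattened per predictor)."""
    rows = []
    for b in burdens:
        row = {
            "individual_id": b.individual_id,
            "ancestry": b.ancestry,
            "het_count_missense": b.het_count_missense,
            "het_count_synonymous": b.het_count_synonymous,
            "mean_af": np.nan if b.mean_af is None else b.mean_af,
            "mean_conservation": np.nan if b.mean_conservation is None else b.mean_conservation,
        }
        for pred, counts in b.evidence_yield.items():
            for c, v in counts.items():
                row[f"yield_{pred}_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(values: pd.DataFrame, statistic: str) -> pd.DataFrame:
    """Per-ancestry summary of one statistic over individuals.

    ``values`` needs columns ``ancestry`` and ``statistic``; returns one row
    per ancestry with n, mean, sd, median, q1, q3.  SD is missing for a
    single individual.
    """
    if statistic not in values.columns:
        raise ConfigurationError(f"no column {statistic!r} to summarize")
    rows = []
    for anc, grp in values.groupby("ancestry", sort=True):
        x = grp[statistic].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0:
            rows.append({"ancestry": anc, "statistic": statistic, "n": 0,
                         "mean": np.nan, "sd": np.nan, "median": np.nan,
                         "q1": np.nan, "q3": np.nan})
            continue
        rows.append(
            {
                "ancestry": anc,
                "statistic": statistic,
                "n": int(x.size),
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if x.size > 1 else np.nan,
                "median": float(np.median(x)),
                "q1": float(np.percentile(x, 25)),  # linear interpolation
                "q3": float(np.percentile(x, 75)),
            }
        )
    return pd.DataFrame(rows)
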