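"""Variant table IO and dataset-construction filters.

Reads and writes the pipeline's variant tables (TSV and VCF), and applies
the filters used to build the evaluation datasets: the rarity filter
(alternate allele frequency below 1% in every ancestry where the variant is
observed), ancestry membership by presence in the frequency reference,
ClinVar/HGMD label harmonization, per-predictor training-set exclusion, and
disease-gene restriction.

Missing AF is distinct from AF 0: a missing value means the variant was not
observed in that ancestry's reference sample, and observation (AF > 0)
defines ancestry membership.  Coordinates are 1-based VCF convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "VariantRecord",
    "GNOMAD_DIALECT",
    "RARITY_CUTOFF",
    "read_variant_table",
    "write_variant_table",
    "write_variant_frame",
    "records_to_frame",
    "frame_to_records",
    "apply_rarity_filter",
    "assign_ancestry_membership",
    "harmonize_labels",
    "apply_labels",
    "apply_exclusions",
    "restrict_to_gene_set",
    "read_id_list",
]

#: gnomAD population codes -> the ancestry labels used throughout the pipeline
GNOMAD_DIALECT: dict[str, str] = {
    "nfe": "EUR",
    "afr": "AFR",
    "amr": "AMR",
    "eas": "EAS",
    "sas": "SAS",
    "mid": "MID",
}

#: strict rarity cutoff: retain only variants with max AF < 1% across ancestries
RARITY_CUTOFF = 0.01

CONSEQUENCES = ("missense", "synonymous", "other")
LABELS = ("pathogenic", "benign", "unlabeled")

# raw clinical-significance vocabularies for label harmonization
_POSITIVE = {
    "pathogenic",
    "pathogenic/likely pathogenic",
    "likely pathogenic",
    "dm",
}
_NEGATIVE = {"benign", "benign/likely benign", "likely benign"}
_KNOWN_NEUTRAL = {"uncertain significance", "vus", "conflicting"}


@dataclass
class VariantRecord:
    """One alternate allele with its annotations.

    ``variant_id`` is chrom-pos-ref-alt (1-based).  ``af_by_ancestry`` maps
    ancestry label to frequency; an absent key means "not observed in that
    ancestry", which is semantically different from frequency 0.
    """

    variant_id: str
    gene: str
    consequence: str = "other"
    label: str = "unlabeled"
    label_source: str = "none"
    af_by_ancestry: dict[str, float] = field(default_factory=dict)
    conservation: float | None = None
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for anc, af in self.af_by_ancestry.items():
            if not 0 <= af <= 1:
                raise DataError(
                    f"variant {self.variant_id}: AF for {anc} out of [0, 1]: {af}"
                )

    def max_af(self) -> float | None:
        """Maximum AF over ancestries where the variant was observed."""
        observed = [v for v in self.af_by_ancestry.values() if v > 0]
        return max(observed) if observed else None


# ---------------------------------------------------------------------------
# Frame <-> records
# ---------------------------------------------------------------------------

_CORE_COLUMNS = ["variant_id", "gene", "consequence", "label", "label_source", "conservation"]


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Wide table: core columns plus af_<ANCESTRY> and score_<PREDICTOR>."""
    ancestries = sorted({a for r in records for a in r.af_by_ancestry})
    predictors = sorted({p for r in records for p in r.scores})
    rows = []
    for r in records:
        row: dict = {
            "variant_id": r.variant_id,
            "gene": r.gene,
            "consequence": r.consequence,
            "label": r.label,
            "label_source": r.label_source,
            "conservation": np.nan if r.conservation is None else r.conservation,
        }
        for a in ancestries:
            row[f"af_{a}"] = r.af_by_ancestry.get(a, np.nan)
        for p in predictors:
            row[f"score_{p}"] = r.scores.get(p, np.nan)
        rows.append(row)
    cols = _CORE_COLUMNS + [f"af_{a}" for a in ancestries] + [f"score_{p}" for p in predictors]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(frame: pd.DataFrame) -> list[VariantRecord]:
    af_cols = [c for c in frame.columns if c.startswith("af_")]
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    records = []
    for _, row in frame.iterrows():
        afs = {c[3:]: float(row[c]) for c in af_cols if pd.notna(row[c])}
        scores = {c[6:]: float(row[c]) for c in score_cols if pd.notna(row[c])}
        cons = row.get("conservation", np.nan)
        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                gene=str(row["gene"]),
                consequence=str(row.get("consequence", "other")),
                label=str(row.get("label", "unlabeled")),
                label_source=str(row.get("label_source", "none")),
                af_by_ancestry=afs,
                conservation=None if pd.isna(cons) else float(cons),
                scores=scores,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_variant_table(
    path: str | Path,
    format: str = "tsv",
    dialect: Mapping[str, str] = GNOMAD_DIALECT,
    genotypes: bool = False,
):
    """Read a variant table from TSV or VCF.

    TSV: header row, tab-separated, '.' for missing, columns as written by
    :func:`write_variant_table`.  VCF: one record per alternate allele
    (multi-allelic sites decomposed); per-ancestry AFs read from INFO keys
    ``AF_<code>`` with gnomAD population codes mapped through ``dialect``,
    predictor scores from ``score_<predictor>``, gene / consequence /
    conservation from ``GENE`` / ``CONSEQUENCE`` / ``CONS``.  Missing INFO
    fields become missing values, never zeros.

    Returns a list of :class:`VariantRecord`; with ``genotypes=True`` on a
    VCF, returns ``(records, dosage_matrix)`` where the matrix is
    individuals x records with values 0/1/2 parsed from GT.
    """
    if format == "tsv":
        if genotypes:
            raise ConfigurationError("genotypes=True is only supported for VCF input")
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path, dialect, genotypes)
    raise ConfigurationError(f"unknown variant table format {format!r} (expected tsv or vcf)")


def _read_tsv(path: str | Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", na_values=["."], dtype={"variant_id": str})
    if "variant_id" not in frame.columns or "gene" not in frame.columns:
        raise DataError(f"{path}: missing required columns variant_id/gene")
    af_cols = [c for c in frame.columns if c.startswith("af_")]
    for c in af_cols:
        bad = frame.index[(frame[c] < 0) | (frame[c] > 1)]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            raise DataError(f"{path}: AF out of [0, 1] in column {c} at line {bad[0] + 2}")
    return frame_to_records(frame)


def _read_vcf(path: str | Path, dialect: Mapping[str, str], genotypes: bool):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    records: list[VariantRecord] = []
    dosages: list[np.ndarray] = []
    info_keys = [h["ID"] for h in vcf.header_iter() if h["HeaderType"] == "INFO"]
    af_keys = [k for k in info_keys if k.startswith("AF_")]
    score_keys = [k for k in info_keys if k.startswith("score_")]
    unknown = [k for k in af_keys if k[3:] not in dialect]
    for k in unknown:
        warnings.warn(f"unknown ancestry code {k[3:]!r} in INFO field {k}; field skipped")
    af_keys = [k for k in af_keys if k[3:] in dialect]

    for v in vcf:
        alts = v.ALT or []
        gts = np.asarray(v.genotype.array())[:, :2] if (genotypes and len(vcf.samples)) else None
        for ai, alt in enumerate(alts):
            afs: dict[str, float] = {}
            for k in af_keys:
                val = _info_per_alt(v.INFO.get(k), ai, len(alts))
                if val is not None:
                    afs[dialect[k[3:]]] = float(val)
            scores: dict[str, float] = {}
            for k in score_keys:
                val = _info_per_alt(v.INFO.get(k), ai, len(alts))
                if val is not None:
                    scores[k[6:]] = float(val)
            cons = v.INFO.get("CONS")
            records.append(
                VariantRecord(
                    variant_id=f"{v.CHROM}-{v.POS}-{v.REF}-{alt}",
                    gene=str(v.INFO.get("GENE") or "."),
                    consequence=str(v.INFO.get("CONSEQUENCE") or "other"),
                    label=str(v.INFO.get("LABEL") or "unlabeled"),
                    label_source=str(v.INFO.get("LABEL_SOURCE") or "none"),
                    af_by_ancestry=afs,
                    conservation=None if cons is None else float(cons),
                    scores=scores,
                )
            )
            if gts is not None:
                dosages.append((gts == ai + 1).sum(axis=1))
    if genotypes:
        mat = np.column_stack(dosages) if dosages else np.zeros((0, 0), dtype=int)
        return records, mat
    return records


def _info_per_alt(value, alt_index: int, n_alts: int):
    """INFO values with Number=A come back as tuples; scalars apply to all alts."""
    if value is None:
        return None
    if isinstance(value, (tuple, list, np.ndarray)):
        if alt_index >= len(value):
            return None
        v = value[alt_index]
        return None if v is None else v
    return value


def write_variant_frame(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=".")


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as TSV ('.' for missing)."""
    write_variant_frame(records_to_frame(records), path)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def apply_rarity_filter(
    records: Iterable[VariantRecord], cutoff: float = RARITY_CUTOFF
) -> list[VariantRecord]:
    """Retain variants observed somewhere with max AF strictly below cutoff.

    Variants not observed in any ancestry (no AF key, or all AFs zero) are
    dropped.  The cutoff is strict: AF exactly at the cutoff is excluded.
    Idempotent.
    """
    out = []
    for r in records:
        m = r.max_af()
        if m is not None and m < cutoff:
            out.append(r)
    return out


def assign_ancestry_membership(
    records: Sequence[VariantRecord],
) -> dict[str, list[VariantRecord]]:
    """A variant belongs to every ancestry in which it was observed (AF > 0).

    Subsets may overlap; their union is the input set whenever the rarity
    filter has already dropped never-observed variants.
    """
    out: dict[str, list[VariantRecord]] = {}
    for r in records:
        for anc, af in r.af_by_ancestry.items():
            if af > 0:
                out.setdefault(anc, []).append(r)
    return out


def harmonize_labels(
    clinvar_labels: Mapping[str, str], hgmd_labels: Mapping[str, str]
) -> dict[str, tuple[str, str]]:
    """Unified labels from ClinVar and HGMD raw designations.

    Positives: pathogenic, pathogenic/likely pathogenic, likely pathogenic
    (ClinVar) and DM (HGMD).  Negatives: benign, benign/likely benign,
    likely benign.  On conflict the ClinVar designation is retained.
    Variants in neither class vocabulary are unlabeled; unknown strings
    trigger a warning and are treated as unlabeled.

    Returns variant_id -> (label, source).
    """

    def classify(raw: str) -> str:
        key = raw.strip().lower()
        if key in _POSITIVE:
            return "pathogenic"
        if key in _NEGATIVE:
            return "benign"
        if key not in _KNOWN_NEUTRAL:
            warnings.warn(f"unknown clinical-significance label {raw!r}; treated as unlabeled")
        return "unlabeled"

    out: dict[str, tuple[str, str]] = {}
    for vid, raw in hgmd_labels.items():
        lab = classify(raw)
        if lab != "unlabeled":
            out[vid] = (lab, "hgmd")
    for vid, raw in clinvar_labels.items():
        lab = classify(raw)
        if lab != "unlabeled":
            out[vid] = (lab, "clinvar")  # ClinVar wins on conflict
        elif vid not in out:
            out[vid] = ("unlabeled", "none")
    return out


def apply_labels(
    records: Sequence[VariantRecord], harmonized: Mapping[str, tuple[str, str]]
) -> list[VariantRecord]:
    """Attach harmonized labels to records (records absent from the map are
    left unlabeled)."""
    out = []
    for r in records:
        lab, src = harmonized.get(r.variant_id, ("unlabeled", "none"))
        out.append(
            VariantRecord(
                variant_id=r.variant_id,
                gene=r.gene,
                consequence=r.consequence,
                label=lab,
                label_source=src,
                af_by_ancestry=dict(r.af_by_ancestry),
                conservation=r.conservation,
                scores=dict(r.scores),
            )
        )
    return out


def apply_exclusions(
    records: Iterable[VariantRecord],
    predictor: str,
    exclusion_lists: Mapping[str, set[str]],
) -> list[VariantRecord]:
    """Drop variants listed in the predictor's training-set exclusion list.

    The exclusion applies to that predictor's evaluation only; a predictor
    with no list entry keeps every record.
    """
    excluded = exclusion_lists.get(predictor, set())
    return [r for r in records if r.variant_id not in excluded]


def restrict_to_gene_set(
    records: Iterable[VariantRecord], gene_set: set[str]
) -> list[VariantRecord]:
    """Keep only variants in the given genes (e.g. a disease-gene panel)."""
    return [r for r in records if r.gene in gene_set]


def read_id_list(path: str | Path) -> set[str]:
    """One identifier per line; '#' starts a comment."""
    out = set()
    for line in Path(path).read_text().splitlines():
        item = line.split("#", 1)[0].strip()
        if item:
            out.add(item)
    return out
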