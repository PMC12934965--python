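"""Mapping predictor scores to ACMG/AMP PP3/BP4 evidence points.

Under the point-based sequence-variant classification scheme, computational
evidence toward pathogenicity (PP3) or benignity (BP4) is graded
supporting (+/-1 point), moderate (+/-2 or +/-3), and strong (+/-4); the
sign encodes direction.  Each predictor ships a calibration table of score
intervals per point tier.  Scores falling between the calibrated benign and
pathogenic regions are indeterminate (0 points).

Tie convention: pathogenic tiers are closed at their minimum score (score
>= threshold qualifies) and benign tiers are closed at their maximum.
Calibration tables are configuration, so either open/closed reading of a
published threshold can be encoded by nudging the value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .variants import VariantRecord

__all__ = [
    "CalibrationTable",
    "EvidenceAssignment",
    "CATEGORIES",
    "points_to_category",
    "map_score_to_points",
    "score_array_to_points",
    "annotate_points",
    "annotate_frame",
    "category_counts",
    "load_calibration_tables",
]

#: the seven evidence categories, strongest-pathogenic first
CATEGORIES = (
    "PP3-strong",
    "PP3-moderate",
    "PP3-supporting",
    "indeterminate",
    "BP4-supporting",
    "BP4-moderate",
    "BP4-strong",
)

_POINT_CATEGORY = {
    4: "PP3-strong",
    3: "PP3-moderate",
    2: "PP3-moderate",
    1: "PP3-supporting",
    0: "indeterminate",
    -1: "BP4-supporting",
    -2: "BP4-moderate",
    -3: "BP4-moderate",
    -4: "BP4-strong",
}


def points_to_category(points: int) -> str:
    return _POINT_CATEGORY[int(points)]


@dataclass(frozen=True)
class EvidenceAssignment:
    points: int
    category: str


@dataclass(frozen=True)
class CalibrationTable:
    """Per-predictor score intervals for each evidence-point tier.

    ``pathogenic_thresholds``: ordered (min_score, points) pairs with points
    in {1, 2, 3, 4}; a score at or above min_score earns at least that tier.
    ``benign_thresholds``: (max_score, points) pairs with points in
    {-1, ..., -4}; a score at or below max_score earns at least that tier.
    Thresholds are expressed in the predictor's own score space; with
    ``higher_is_pathogenic=False`` the comparisons run in the reflected
    space (score and thresholds negated), so pathogenic min_scores are then
    *decreasing* in the raw space.
    """

    predictor: str
    pathogenic_thresholds: tuple[tuple[float, int], ...]
    benign_thresholds: tuple[tuple[float, int], ...] = ()
    higher_is_pathogenic: bool = True

    def __post_init__(self) -> None:
        sign = 1.0 if self.higher_is_pathogenic else -1.0
        name = self.predictor

        path = sorted(self.pathogenic_thresholds, key=lambda t: t[1])
        if any(p not in (1, 2, 3, 4) for _, p in path):
            raise ConfigurationError(f"{name}: pathogenic points must be in 1..4")
        if len({p for _, p in path}) != len(path):
            raise ConfigurationError(f"{name}: duplicate pathogenic point tiers")
        canon_path = [sign * s for s, _ in path]
        if any(b <= a for a, b in zip(canon_path, canon_path[1:])):
            raise ConfigurationError(
                f"{name}: pathogenic thresholds must be strictly increasing with points"
            )

        ben = sorted(self.benign_thresholds, key=lambda t: -t[1])  # -1, -2, ...
        if any(p not in (-1, -2, -3, -4) for _, p in ben):
            raise ConfigurationError(f"{name}: benign points must be in -4..-1")
        if len({p for _, p in ben}) != len(ben):
            raise ConfigurationError(f"{name}: duplicate benign point tiers")
        canon_ben = [sign * s for s, _ in ben]
        if any(b >= a for a, b in zip(canon_ben, canon_ben[1:])):
            raise ConfigurationError(
                f"{name}: benign thresholds must be strictly decreasing with |points|"
            )

        if canon_path and canon_ben and canon_path[0] <= canon_ben[0]:
            raise ConfigurationError(
                f"{name}: pathogenic and benign score regions overlap "
                f"(lowest pathogenic threshold {canon_path[0]} <= "
                f"highest benign threshold {canon_ben[0]} in canonical space)"
            )

        # canonical arrays for vectorized lookup (higher-is-pathogenic space)
        object.__setattr__(self, "_path_mins", np.array(canon_path))
        object.__setattr__(self, "_path_points", np.array([p for _, p in path]))
        # benign sorted ascending by canonical max: -4 tier first
        ben_asc = sorted(zip(canon_ben, (p for _, p in ben)))
        object.__setattr__(self, "_ben_maxs", np.array([s for s, _ in ben_asc]))
        object.__setattr__(self, "_ben_points", np.array([p for _, p in ben_asc]))


def score_array_to_points(scores: np.ndarray, table: CalibrationTable) -> np.ndarray:
    """Vectorized evidence points; NaN scores map to NaN (missing, not 0)."""
    s = np.asarray(scores, dtype=float)
    if not table.higher_is_pathogenic:
        s = -s
    points = np.zeros(s.shape)

    if len(table._path_mins):
        idx = np.searchsorted(table._path_mins, s, side="right")
        hit = idx > 0
        points[hit] = table._path_points[idx[hit] - 1]
    if len(table._ben_maxs):
        idx = np.searchsorted(table._ben_maxs, s, side="left")
        hit = (idx < len(table._ben_maxs)) & (points == 0)
        points[hit] = table._ben_points[idx[hit]]
    points[np.isnan(s)] = np.nan
    return points


def map_score_to_points(score: float, table: CalibrationTable) -> EvidenceAssignment:
    """Assign the highest-|points| tier whose interval contains the score.

    Returns the indeterminate assignment (0 points) when the score falls in
    the gap between the calibrated benign and pathogenic regions.
    """
    if np.isnan(score):
        raise ConfigurationError(
            f"{table.predictor}: cannot map a missing score; filter missing scores upstream"
        )
    p = score_array_to_points(np.array([score]), table)[0]
    p = int(p)
    return EvidenceAssignment(points=p, category=points_to_category(p))


def annotate_points(
    records: Sequence[VariantRecord],
    tables: Mapping[str, CalibrationTable],
    predictors: Sequence[str] | None = None,
) -> list[dict[str, EvidenceAssignment | None]]:
    """Per-record, per-predictor evidence assignments, order preserved.

    A missing score yields a missing assignment (None), never indeterminate.
    Every requested predictor must have a calibration table.
    """
    preds = list(predictors) if predictors is not None else sorted(tables)
    for p in preds:
        if p not in tables:
            raise ConfigurationError(f"no calibration table for predictor {p!r}")
    out: list[dict[str, EvidenceAssignment | None]] = []
    for r in records:
        row: dict[str, EvidenceAssignment | None] = {}
        for p in preds:
            s = r.scores.get(p)
            row[p] = None if s is None or np.isnan(s) else map_score_to_points(s, tables[p])
        out.append(row)
    return out


def annotate_frame(
    frame, tables: Mapping[str, CalibrationTable], predictors: Sequence[str] | None = None
):
    """Add ``points_<predictor>`` columns to a variant frame (NaN = missing)."""
    preds = list(predictors) if predictors is not None else sorted(tables)
    out = frame.copy()
    for p in preds:
        if p not in tables:
            raise ConfigurationError(f"no calibration table for predictor {p!r}")
        col = f"score_{p}"
        if col not in frame.columns:
            raise ConfigurationError(f"variant table has no score column for predictor {p!r}")
        out[f"points_{p}"] = score_array_to_points(frame[col].to_numpy(dtype=float), tables[p])
    return out


def category_counts(
    assignments: Sequence[EvidenceAssignment | None],
) -> dict[str, int]:
    """Counts over the seven categories; missing assignments are excluded,
    so the counts sum to the number of non-missing assignments."""
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        if a is not None:
            counts[a.category] += 1
    return counts


def load_calibration_tables(path: str | Path) -> dict[str, CalibrationTable]:
    """Load calibration tables from a YAML config.

    Layout::

        revel_like:
          higher_is_pathogenic: true
          pathogenic:        # points -> min score (score >= qualifies)
            1: 0.644
            2: 0.773
            4: 0.932
          benign:            # points -> max score (score <= qualifies)
            -1: 0.290
            -2: 0.183
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: calibration config must be a mapping of predictors")
    tables: dict[str, CalibrationTable] = {}
    for name, block in raw.items():
        if not isinstance(block, dict):
            raise ConfigurationError(f"{path}: predictor {name!r} block must be a mapping")
        try:
            path_th = tuple(
                (float(v), int(k)) for k, v in (block.get("pathogenic") or {}).items()
            )
            ben_th = tuple((float(v), int(k)) for k, v in (block.get("benign") or {}).items())
        except (TypeError, ValueError) as e:
            raise ConfigurationError(f"{path}: predictor {name!r}: bad threshold entry: {e}")
        tables[name] = CalibrationTable(
            predictor=str(name),
            pathogenic_thresholds=path_th,
            benign_thresholds=ben_th,
            higher_is_pathogenic=bool(block.get("higher_is_pathogenic", True)),
        )
    return tables
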