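"""Cognitive-flexibility scoring and ranking-based grouping.

Subjects fill three questionnaires yielding five scores:

* CFI Alternatives (mean of 12 items, 1-7) and CFI Control (mean of 7 items,
  1-7) -- generating alternatives vs. perceived controllability;
* CFS (mean of 12 items, 1-6) -- communication-flexibility scale;
* CCFQ Cognitive Control over Emotion and CCFQ Appraisal & Coping
  Flexibility (each the sum of 9 items, 1-7, hence 9-63).

Grouping works on within-cohort ranks: for each score in a four-score set,
percentiles are rank/(n+1)*100 with average ranks for ties; a subject is
High above the 75th percentile, Low below the 25th, Average in between, and
gets a final label only when at least 3 of the 4 scores agree (otherwise
Unclassified). High and Low are then merged into a single "Extreme" group
for the physiological contrast against Average.

The module is fully deterministic, and because it is rank-based the
classification is invariant under any strictly monotone transform applied
to a score across the whole cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DesignError, InvalidParameterError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaleDef:
    """Definition of one questionnaire scale."""

    name: str
    n_items: int
    item_min: float
    item_max: float
    aggregation: str  # "mean" or "sum"
    reverse_items: frozenset = frozenset()

    @property
    def score_min(self) -> float:
        return self.item_min if self.aggregation == "mean" else self.n_items * self.item_min

    @property
    def score_max(self) -> float:
        return self.item_max if self.aggregation == "mean" else self.n_items * self.item_max


SCALES: dict[str, ScaleDef] = {
    "cfi_alt": ScaleDef("cfi_alt", 12, 1, 7, "mean"),
    "cfi_ctrl": ScaleDef("cfi_ctrl", 7, 1, 7, "mean"),
    "cfs": ScaleDef("cfs", 12, 1, 6, "mean"),
    "ccfq_cce": ScaleDef("ccfq_cce", 9, 1, 7, "sum"),
    "ccfq_acf": ScaleDef("ccfq_acf", 9, 1, 7, "sum"),
}

#: the four scores entering the ranking (CFS can be swapped in via config)
DEFAULT_SCORE_SET = ("cfi_alt", "cfi_ctrl", "ccfq_cce", "ccfq_acf")


@dataclass
class QuestionnaireScores:
    """Scale-level scores for one subject."""

    cfi_alt: float
    cfi_ctrl: float
    cfs: float
    ccfq_cce: float
    ccfq_acf: float

    def __post_init__(self) -> None:
        for name, sd in SCALES.items():
            v = getattr(self, name)
            if not (sd.score_min <= v <= sd.score_max):
                raise InvalidParameterError(
                    f"{name}={v} outside [{sd.score_min}, {sd.score_max}]"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SCALES}


@dataclass
class FlexLabel:
    """Per-subject classification with audit trail of per-score categories."""

    label: str  # High | Average | Low | Unclassified
    merged: str | None = None  # Extreme | Average | Unclassified
    per_score: dict = field(default_factory=dict)
    percentiles: dict = field(default_factory=dict)


def score_questionnaire(items, scale_def: ScaleDef) -> float:
    """Aggregate raw item responses into a scale score.

    Reverse-keyed items (0-based indices in ``scale_def.reverse_items``) are
    flipped as ``min + max - item`` before aggregation.
    """
    items = np.asarray(items, dtype=float)
    if items.size != scale_def.n_items:
        raise InvalidParameterError(
            f"{scale_def.name} expects {scale_def.n_items} items, got {items.size}"
        )
    if np.any(items < scale_def.item_min) or np.any(items > scale_def.item_max):
        raise InvalidParameterError(
            f"{scale_def.name} items must lie in "
            f"[{scale_def.item_min}, {scale_def.item_max}]"
        )
    vals = items.copy()
    for i in scale_def.reverse_items:
        vals[i] = scale_def.item_min + scale_def.item_max - vals[i]
    return float(vals.mean() if scale_def.aggregation == "mean" else vals.sum())


@dataclass
class RankConfig:
    low_pct: float = 25.0
    high_pct: float = 75.0
    min_consistent: int = 3
    score_set: tuple = DEFAULT_SCORE_SET

    def __post_init__(self) -> None:
        if not (0 < self.low_pct < self.high_pct < 100):
            raise InvalidParameterError("need 0 < low_pct < high_pct < 100")
        if len(self.score_set) != 4:
            raise InvalidParameterError("score_set must contain exactly 4 scores")
        unknown = set(self.score_set) - set(SCALES)
        if unknown:
            raise InvalidParameterError(f"unknown scores: {sorted(unknown)}")


def rank_classify(
    scores: list[QuestionnaireScores], config: RankConfig | None = None
) -> list[FlexLabel]:
    """Classify each subject High/Average/Low by cross-scale rank consistency."""
    config = config or RankConfig()
    n = len(scores)
    if n < 4:
        raise DesignError(f"need at least 4 subjects to rank, got {n}")
    per_score_cat: dict[str, list[str]] = {}
    per_score_pct: dict[str, np.ndarray] = {}
    for name in config.score_set:
        vals = np.array([getattr(s, name) for s in scores], dtype=float)
        pct = rankdata(vals, method="average") / (n + 1) * 100.0
        cats = np.where(
            pct > config.high_pct, "High",
            np.where(pct < config.low_pct, "Low", "Average"),
        )
        per_score_cat[name] = list(cats)
        per_score_pct[name] = pct
    labels = []
    for i in range(n):
        cats = {name: per_score_cat[name][i] for name in config.score_set}
        counts = pd.Series(list(cats.values())).value_counts()
        top = counts.index[0]
        label = top if counts.iloc[0] >= config.min_consistent else "Unclassified"
        labels.append(
            FlexLabel(
                label=label,
                per_score=cats,
                percentiles={
                    name: float(per_score_pct[name][i]) for name in config.score_set
                },
            )
        )
    return labels


def merge_extremes(labels: list[FlexLabel]) -> list[FlexLabel]:
    """Set the merged group: High and Low become Extreme; others pass through."""
    n_unclassified = 0
    for lab in labels:
        if lab.label in ("High", "Low"):
            lab.merged = "Extreme"
        elif lab.label == "Average":
            lab.merged = "Average"
        else:
            lab.merged = "Unclassified"
            n_unclassified += 1
    if n_unclassified:
        log.warning(
            "%d subject(s) unclassified; excluded from group analysis",
            n_unclassified,
        )
    if not any(lab.merged == "Extreme" for lab in labels):
        warnings.warn("no Extreme subjects in cohort", RuntimeWarning, stacklevel=2)
    return labels


def labels_to_frame(
    subject_ids: list[str], labels: list[FlexLabel]
) -> pd.DataFrame:
    rows = []
    for sid, lab in zip(subject_ids, labels):
        row = {"subject_id": sid}
        row.update({f"{k}_pct": v for k, v in lab.percentiles.items()})
        row["label"] = lab.label
        row["merged"] = lab.merged
        rows.append(row)
    return pd.DataFrame(rows)
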