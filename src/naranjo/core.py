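"""Naranjo Algorithm scoring, diagnostic accuracy, and cohort simulation.

The Naranjo Algorithm (NA) is a ten-question instrument for judging whether
a suspected adverse drug reaction (ADR) was actually caused by the drug.
Each question is answered yes / no / do-not-know and contributes an integer
score between -1 and +2; the total score summarises the weight of causal
evidence, and a suspected ADR is called an ADR when the total reaches a
cut-off.

This module implements, in pipeline order:

1.  the data model — answers, assessment records, and four scoring schemes
    (the original ten-component instrument plus three reduced/binarized
    variants designed for quick bedside use);
2.  scoring of records under a scheme and classification at a cut-off;
3.  diagnostic accuracy against a gold-standard ADR adjudication —
    confusion matrices, sensitivity/specificity, ROC curves, trapezoidal
    AUC, and DeLong confidence intervals;
4.  a latent-class synthetic-cohort generator calibrated to the published
    summary statistics of the JADE inpatient pharmacovigilance cohort
    (1579 suspected ADRs, 997 physician-confirmed), so the instrument's
    evaluation can be reproduced and extended without patient-level data;
5.  CSV/JSON readers and writers and a JSON report format.

Answers map to scores via the scheme's score table; do-not-know always
falls in a zero-scoring branch of the original instrument.  Classification
is inclusive: a record is predicted to be an ADR when ``total >= cutoff``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("naranjo")

__all__ = [
    "Answer",
    "AssessmentRecord",
    "ScoringScheme",
    "SchemeError",
    "MissingAnswerError",
    "RecordFormatError",
    "CalibrationError",
    "SCHEME_NAMES",
    "ORIGINAL_COMPONENT_SCORES",
    "COMPONENT_QUESTIONS",
    "build_scheme",
    "binarize_score",
    "scheme_from_dict",
    "ScoredRecord",
    "score_record",
    "score_records",
    "classify",
    "apply_cutoff",
    "with_gold_labels",
    "ConfusionMatrix",
    "confusion",
    "sensitivity",
    "specificity",
    "ROCCurve",
    "roc",
    "auc_ci",
    "accuracy_table",
    "adr_rate_by_total",
    "round_half_up",
    "CohortParameters",
    "calibrate",
    "simulate",
    "reconstruction_fixture_component1",
    "component_confusion",
    "model_score_distribution",
    "model_auc",
    "JADE_N_TOTAL",
    "JADE_N_ADR",
    "JADE_N_NOT_ADR",
    "PRINTED_COMPONENT_ACCURACY",
    "read_records",
    "write_records",
    "write_report",
]


# ---------------------------------------------------------------------------
# Data model: answers, records, scoring schemes
# ---------------------------------------------------------------------------


class Answer(enum.Enum):
    """One answer to a Naranjo question: yes, no, or do-not-know."""

    YES = "yes"
    NO = "no"
    DO_NOT_KNOW = "dk"

    @classmethod
    def from_token(cls, token: str) -> "Answer":
        """Parse a case-insensitive text token (``yes`` / ``no`` / ``dk``)."""
        try:
            return _ANSWER_TOKENS[token.strip().lower()]
        except (KeyError, AttributeError):
            raise ValueError(
                f"unknown answer token {token!r}; expected one of yes, no, dk"
            ) from None


_ANSWER_TOKENS = {a.value: a for a in Answer}
_Y, _N, _D = Answer.YES, Answer.NO, Answer.DO_NOT_KNOW


class SchemeError(ValueError):
    """Unknown or invalid scoring scheme."""


class MissingAnswerError(ValueError):
    """A record lacks answers required by the active scheme."""


class RecordFormatError(ValueError):
    """Malformed record table (bad header, token, or duplicate id)."""


class CalibrationError(ValueError):
    """The cohort calibration is internally inconsistent."""


COMPONENT_QUESTIONS: Mapping[int, str] = {
    1: "previous conclusive reports on this reaction",
    2: "event appeared after the suspected drug was administered",
    3: "reaction improved on discontinuation or specific antagonist",
    4: "reaction reappeared on rechallenge",
    5: "alternative causes that could alone have caused the reaction",
    6: "reaction reappeared when a placebo was given",
    7: "drug detected in blood at toxic concentration",
    8: "reaction worse at higher dose or milder at lower dose",
    9: "similar reaction to the same or similar drug previously",
    10: "event confirmed by objective evidence",
}

# 1981 instrument score table: component -> answer -> points.  For the four
# evidence-against questions (2, 4, 5, 6) a "wrong-direction" answer scores
# -1 while do-not-know stays at 0; question 5 is phrased so that NO (no
# alternative cause) is the evidence FOR causality (+2).
ORIGINAL_COMPONENT_SCORES: Mapping[int, Mapping[Answer, int]] = {
    1: {_Y: +1, _N: 0, _D: 0},
    2: {_Y: +2, _N: -1, _D: 0},
    3: {_Y: +1, _N: 0, _D: 0},
    4: {_Y: +2, _N: -1, _D: 0},
    5: {_Y: -1, _N: +2, _D: 0},
    6: {_Y: -1, _N: +1, _D: 0},
    7: {_Y: +1, _N: 0, _D: 0},
    8: {_Y: +1, _N: 0, _D: 0},
    9: {_Y: +1, _N: 0, _D: 0},
    10: {_Y: +1, _N: 0, _D: 0},
}

_NARANJO_SCORE_VALUES = (-1, 0, 1, 2)


def binarize_score(original_score: int) -> int:
    """Collapse a Naranjo component score to 0/1.

    Positive scores become +1; zero and negative scores become 0.  Raises
    ``ValueError`` outside the instrument's score range {-1, 0, +1, +2}.
    """
    if original_score not in _NARANJO_SCORE_VALUES:
        raise ValueError(
            f"score {original_score} outside the Naranjo range {-1}..{+2}"
        )
    return 1 if original_score > 0 else 0


def _binary_component_scores(component_id: int) -> Mapping[Answer, int]:
    # Binarized questionnaire semantics: do-not-know is grouped with "no"
    # (the instruments print a single "No/Do not know" column), then the
    # positive-score rule applies.  This differs from binarizing the raw
    # score only for question 5, where NO is the positive branch and
    # do-not-know therefore also scores +1.
    original = ORIGINAL_COMPONENT_SCORES[component_id]
    return {
        _Y: binarize_score(original[_Y]),
        _N: binarize_score(original[_N]),
        _D: binarize_score(original[_N]),
    }


@dataclasses.dataclass(frozen=True)
class ScoringScheme:
    """A Naranjo-style questionnaire: components, score table, cut-off.

    Attributes
    ----------
    name:
        Scheme identifier.
    components:
        Ordered component ids (subset of 1..10) the scheme uses.
    score_map:
        ``component -> answer -> points``; total over the three answers.
    default_cutoff:
        Total score at or above which a record is predicted to be an ADR.
    binarized:
        True when every component contributes 0 or 1.
    """

    name: str
    components: tuple[int, ...]
    score_map: Mapping[int, Mapping[Answer, int]]
    default_cutoff: int
    binarized: bool = False

    def __post_init__(self) -> None:
        if not self.components:
            raise SchemeError("scheme has no components")
        for cid in self.components:
            if cid not in range(1, 11):
                raise SchemeError(f"component id {cid} outside 1..10")
            table = self.score_map.get(cid)
            if table is None or set(table) != {_Y, _N, _D}:
                raise SchemeError(
                    f"score map for component {cid} must cover yes/no/do-not-know"
                )

    def score(self, component_id: int, answer: Answer) -> int:
        """Points contributed by one answer to one component."""
        return self.score_map[component_id][answer]

    def total_range(self) -> tuple[int, int]:
        """Theoretical (min, max) total over all answer combinations."""
        lo = sum(min(self.score_map[c].values()) for c in self.components)
        hi = sum(max(self.score_map[c].values()) for c in self.components)
        return lo, hi

    def to_dict(self) -> dict:
        """JSON-serialisable description (answers keyed by token)."""
        return {
            "name": self.name,
            "components": list(self.components),
            "score_map": {
                str(c): {a.value: s for a, s in self.score_map[c].items()}
                for c in self.components
            },
            "default_cutoff": self.default_cutoff,
            "binarized": self.binarized,
        }


def scheme_from_dict(payload: Mapping) -> ScoringScheme:
    """Rebuild a (possibly custom) scheme from its JSON description."""
    score_map = {
        int(c): {Answer.from_token(tok): int(s) for tok, s in table.items()}
        for c, table in payload["score_map"].items()
    }
    return ScoringScheme(
        name=str(payload["name"]),
        components=tuple(int(c) for c in payload["components"]),
        score_map=score_map,
        default_cutoff=int(payload["default_cutoff"]),
        binarized=bool(payload.get("binarized", False)),
    )


def _build_builtin(name: str) -> ScoringScheme:
    if name == "original10":
        comps = tuple(range(1, 11))
        return ScoringScheme(name, comps, ORIGINAL_COMPONENT_SCORES, 5, False)
    if name == "modified5":
        comps = tuple(range(1, 6))
        smap = {c: ORIGINAL_COMPONENT_SCORES[c] for c in comps}
        return ScoringScheme(name, comps, smap, 5, False)
    if name == "binary5":
        comps = tuple(range(1, 6))
        smap = {c: _binary_component_scores(c) for c in comps}
        return ScoringScheme(name, comps, smap, 4, True)
    if name == "binary4":
        comps = tuple(range(2, 6))
        smap = {c: _binary_component_scores(c) for c in comps}
        return ScoringScheme(name, comps, smap, 3, True)
    raise AssertionError(name)


SCHEME_NAMES: tuple[str, ...] = ("original10", "modified5", "binary5", "binary4")
_BUILTIN_SCHEMES = {name: _build_builtin(name) for name in SCHEME_NAMES}


def build_scheme(name: str) -> ScoringScheme:
    """Return one of the built-in schemes.

    ``original10``
        The full 1981 ten-question instrument, cut-off 5.
    ``modified5``
        Questions 1-5 with the original weights, cut-off 5.
    ``binary5``
        Questions 1-5, each collapsed to 0/1, cut-off 4.
    ``binary4``
        Questions 2-5 collapsed to 0/1 (the simplest bedside variant,
        dropping the literature-knowledge question), cut-off 3.
    """
    try:
        return _BUILTIN_SCHEMES[name]
    except KeyError:
        raise SchemeError(
            f"unknown scheme {name!r}; valid schemes: {', '.join(SCHEME_NAMES)}"
        ) from None


@dataclasses.dataclass
class AssessmentRecord:
    """One suspected ADR: answers to the questionnaire plus optional truth.

    ``gold_label`` is the adjudicated outcome (True = confirmed ADR) when
    available; ``metadata`` carries free-form strings (ward, drug class)
    that the package passes through untouched.
    """

    record_id: str
    answers: dict[int, Answer]
    gold_label: Optional[bool] = None
    metadata: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        for cid, ans in self.answers.items():
            if cid not in range(1, 11):
                raise ValueError(f"component id {cid} outside 1..10")
            if not isinstance(ans, Answer):
                raise TypeError(f"answer for component {cid} is not an Answer")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ScoredRecord:
    """A record's per-component and total score under one scheme."""

    record_id: str
    scheme_name: str
    component_scores: dict[int, int]
    total: int
    gold_label: Optional[bool] = None
    predicted: Optional[bool] = None


def score_record(record: AssessmentRecord, scheme: ScoringScheme) -> ScoredRecord:
    """Score one record under a scheme.

    Raises ``MissingAnswerError`` (listing the offending components) when
    the record lacks an answer required by the scheme.
    """
    missing = [c for c in scheme.components if c not in record.answers]
    if missing:
        raise MissingAnswerError(
            f"record {record.record_id!r} missing answers for components {missing}"
        )
    component_scores = {
        c: scheme.score(c, record.answers[c]) for c in scheme.components
    }
    return ScoredRecord(
        record_id=record.record_id,
        scheme_name=scheme.name,
        component_scores=component_scores,
        total=sum(component_scores.values()),
        gold_label=record.gold_label,
    )


def score_records(
    records: Iterable[AssessmentRecord], scheme: ScoringScheme
) -> list[ScoredRecord]:
    """Score a collection of records under one scheme."""
    return [score_record(r, scheme) for r in records]


def classify(scored: ScoredRecord, cutoff: int) -> bool:
    """Predict ADR when the total score reaches the cut-off (inclusive)."""
    return scored.total >= cutoff


def apply_cutoff(scored: Sequence[ScoredRecord], cutoff: int) -> list[ScoredRecord]:
    """Set ``predicted`` on every record at the given cut-off (in place)."""
    for s in scored:
        s.predicted = classify(s, cutoff)
    return list(scored)


def with_gold_labels(scored: Sequence[ScoredRecord]) -> list[ScoredRecord]:
    """Drop records without a gold label, logging how many were dropped."""
    kept = [s for s in scored if s.gold_label is not None]
    dropped = len(scored) - len(kept)
    if dropped:
        logger.info("dropped %d record(s) without a gold label", dropped)
    return kept


# ---------------------------------------------------------------------------
# Diagnostics: confusion, sensitivity/specificity, ROC, AUC, DeLong CI
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts for one scheme at one cut-off."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _split_by_label(
    scored: Sequence[ScoredRecord],
) -> tuple[np.ndarray, np.ndarray]:
    if not scored:
        raise ValueError("no scored records")
    if any(s.gold_label is None for s in scored):
        raise ValueError(
            "records without gold labels present; filter with with_gold_labels()"
        )
    totals = np.array([s.total for s in scored], dtype=float)
    labels = np.array([s.gold_label for s in scored], dtype=bool)
    pos, neg = totals[labels], totals[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one gold-positive and one gold-negative record")
    return pos, neg


def confusion(scored: Sequence[ScoredRecord], cutoff: int) -> ConfusionMatrix:
    """Cross-classify predicted (total >= cutoff) against the gold label."""
    pos, neg = _split_by_label(scored)
    tp = int(np.sum(pos >= cutoff))
    fp = int(np.sum(neg >= cutoff))
    return ConfusionMatrix(tp=tp, fp=fp, tn=len(neg) - fp, fn=len(pos) - tp)


def sensitivity(cm: ConfusionMatrix) -> float:
    """True-positive rate tp / (tp + fn) among confirmed ADRs."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no gold-positive records: sensitivity undefined")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """True-negative rate tn / (tn + fp) among non-ADRs."""
    if cm.tn + cm.fp == 0:
        raise ValueError("no gold-negative records: specificity undefined")
    return cm.tn / (cm.tn + cm.fp)


@dataclasses.dataclass
class ROCCurve:
    """ROC staircase over score thresholds.

    ``points`` is ordered by decreasing threshold, starting at
    (+inf, 0, 0) and ending at (min score, 1, 1); ``auc`` is the
    trapezoidal area, identical to the tie-corrected Mann-Whitney
    statistic P(S+ > S-) + 0.5 P(S+ = S-).
    """

    points: list[tuple[float, float, float]]  # (threshold, FPR, TPR)
    auc: float
    ci: Optional[tuple[float, float, float]] = None  # (lower, upper, level)


def roc(scored: Sequence[ScoredRecord]) -> ROCCurve:
    """Build the ROC staircase with one threshold per distinct total."""
    pos, neg = _split_by_label(scored)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(math.inf, 0.0, 0.0)]
    for t in thresholds:
        tpr = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        points.append((float(t), fpr, tpr))
    fprs = np.array([p[1] for p in points])
    tprs = np.array([p[2] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return ROCCurve(points=points, auc=auc)


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong (placement-value) variance.

    Placements are computed from midranks, handling ties the same way the
    Mann-Whitney statistic does (ties count one half).
    """
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n  # P(score beats a random negative), per positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    if m > 1 and n > 1:
        var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    else:
        var = float("nan")
    return auc, var


def auc_ci(
    scored: Sequence[ScoredRecord], level: float = 0.95
) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, clipped to [0, 1].

    Degenerate inputs (perfect or null separation) yield a zero-width
    variance estimate; the interval is still returned, clipped, with a
    logged warning.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    pos, neg = _split_by_label(scored)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least two records per class for a CI")
    auc, var = _delong_auc_variance(pos, neg)
    if auc in (0.0, 1.0) or var == 0.0:
        logger.warning("degenerate AUC %.3f: confidence interval is boundary-clipped", auc)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def accuracy_table(scored: Sequence[ScoredRecord]) -> pd.DataFrame:
    """Sensitivity and specificity at every observed total used as cut-off.

    Returns a frame with columns ``cutoff``, ``sensitivity``,
    ``specificity``; sensitivity is non-increasing and specificity
    non-decreasing as the cut-off rises.
    """
    pos, neg = _split_by_label(scored)
    cutoffs = np.unique(np.concatenate([pos, neg]))
    rows = [
        {
            "cutoff": float(c),
            "sensitivity": float(np.mean(pos >= c)),
            "specificity": float(np.mean(neg < c)),
        }
        for c in cutoffs
    ]
    return pd.DataFrame(rows, columns=["cutoff", "sensitivity", "specificity"])


def adr_rate_by_total(scored: Sequence[ScoredRecord]) -> pd.DataFrame:
    """Fraction of confirmed ADRs at each total score.

    Columns: ``total``, ``n``, ``adr_fraction``.  Rows partition the
    labelled records, so ``n`` sums to the cohort size.
    """
    labelled = [s for s in scored if s.gold_label is not None]
    if any(s.gold_label is None for s in scored):
        raise ValueError("gold labels required for ADR rate by total")
    frame = pd.DataFrame(
        {"total": [s.total for s in labelled], "adr": [s.gold_label for s in labelled]}
    )
    grouped = (
        frame.groupby("total")["adr"].agg(n="size", adr_fraction="mean").reset_index()
    )
    return grouped[["total", "n", "adr_fraction"]]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (presentation rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Synthetic cohort: calibration to the JADE summaries and simulation
# ---------------------------------------------------------------------------

JADE_N_TOTAL = 1579
JADE_N_ADR = 997
JADE_N_NOT_ADR = JADE_N_TOTAL - JADE_N_ADR  # 582

# Published marginal counts of each component score (n records per score).
_TABLE_SCORE_COUNTS: Mapping[int, Mapping[int, int]] = {
    1: {+1: 1002, 0: 577},
    2: {+2: 1172, 0: 400, -1: 7},
    3: {+1: 322, 0: 1257},
    4: {+2: 309, 0: 1040, -1: 230},
    5: {+2: 761, 0: 422, -1: 396},
    6: {+1: 3, 0: 1576, -1: 0},
    7: {+1: 2, 0: 1577},
    8: {+1: 24, 0: 1555},
    9: {+1: 35, 0: 1544},
    10: {+1: 53, 0: 1526},
}

# Published single-component accuracy (sensitivity, specificity), where a
# positive component score predicts ADR and do-not-know counts as negative.
PRINTED_COMPONENT_ACCURACY: Mapping[int, tuple[float, float]] = {
    1: (0.87, 0.77),
    2: (0.99, 0.68),
    3: (0.31, 0.97),
    4: (0.27, 0.93),
    5: (0.71, 0.91),
}

# Component 1 is the only component whose class-conditional counts are
# printed directly: 866 of the 1002 yes-answers and 131 of the 577
# no/do-not-know answers were confirmed ADRs.
_C1_TP, _C1_FP = 866, 136

_CLASS_ADR, _CLASS_NOT = "ADR", "NOT_ADR"


def _answer_for_score(component_id: int, score: int) -> Answer:
    """The answer mapped to a given score column, resolving 0-column ties.

    Where both NO and DO_NOT_KNOW score 0 the published tables pool them in
    one column; the split is score-invariant under every scheme, so a single
    representative answer is used (NO for components 1-5, DO_NOT_KNOW for
    the rarely-informative components 6-10, matching the tables' labels).
    """
    table = ORIGINAL_COMPONENT_SCORES[component_id]
    matches = [a for a in (_Y, _N, _D) if table[a] == score]
    if len(matches) == 1:
        return matches[0]
    return _N if component_id <= 5 else _D


@dataclasses.dataclass
class CohortParameters:
    """Latent-class generative model for a suspected-ADR cohort.

    A hidden label (ADR / not-ADR) is drawn with prevalence
    ``n_adr / n_total``; the ten answers are then drawn independently from
    class-conditional categorical distributions.  ``class_counts`` holds the
    integer reconstruction behind the probabilities, for audit.
    """

    n_total: int = JADE_N_TOTAL
    n_adr: int = JADE_N_ADR
    class_counts: dict[int, dict[str, dict[Answer, float]]] = dataclasses.field(
        default_factory=dict
    )
    seed: int = 0

    @property
    def n_not_adr(self) -> int:
        return self.n_total - self.n_adr

    @property
    def prevalence(self) -> float:
        return self.n_adr / self.n_total

    def probabilities(self, component_id: int, adr: bool) -> dict[Answer, float]:
        """Class-conditional answer distribution for one component."""
        counts = self.class_counts[component_id][_CLASS_ADR if adr else _CLASS_NOT]
        total = sum(counts.values())
        return {a: counts.get(a, 0.0) / total for a in (_Y, _N, _D)}

    def validate(self) -> None:
        if self.n_adr <= 0 or self.n_adr >= self.n_total:
            raise CalibrationError("prevalence must be strictly between 0 and 1")
        for cid, per_class in self.class_counts.items():
            for cls, counts in per_class.items():
                if any(v < 0 for v in counts.values()):
                    raise CalibrationError(
                        f"negative count for component {cid}, class {cls}: {counts}"
                    )
                p = self.probabilities(cid, cls == _CLASS_ADR)
                if abs(sum(p.values()) - 1.0) > 1e-9:
                    raise CalibrationError(
                        f"probabilities for component {cid}/{cls} do not sum to 1"
                    )


def calibrate() -> CohortParameters:
    """Reconstruct class-conditional answer distributions from the
    published cohort summaries.

    Component 1 uses the directly printed confirmed/unconfirmed counts.
    For components 2-5 the true-positive count is recovered from the
    printed sensitivity (TP = round(sens x 997)); the remainder of the
    positive-score column is false positives, negative-score answers are
    assigned to the non-ADR class (they are evidence against causality),
    and the zero-score column takes what is left of each class.  The
    reconstruction is rejected unless the implied specificity matches the
    printed value within 0.01.  Components 6-10 assign the handful of
    positive-score answers to the ADR class and everything else to the
    zero-score column.
    """
    counts: dict[int, dict[str, dict[Answer, float]]] = {}

    def empty() -> dict[str, dict[Answer, float]]:
        return {
            _CLASS_ADR: {a: 0.0 for a in (_Y, _N, _D)},
            _CLASS_NOT: {a: 0.0 for a in (_Y, _N, _D)},
        }

    # component 1: counts printed directly
    c1 = empty()
    zero_answer = _answer_for_score(1, 0)
    c1[_CLASS_ADR][_Y] = _C1_TP
    c1[_CLASS_NOT][_Y] = _C1_FP
    c1[_CLASS_ADR][zero_answer] = JADE_N_ADR - _C1_TP
    c1[_CLASS_NOT][zero_answer] = JADE_N_NOT_ADR - _C1_FP
    counts[1] = c1

    # components 2-5: reconstruct from printed sensitivity + marginals
    for cid in (2, 3, 4, 5):
        sens_printed, spec_printed = PRINTED_COMPONENT_ACCURACY[cid]
        marginals = _TABLE_SCORE_COUNTS[cid]
        pos_score = max(marginals)
        pos_answer = _answer_for_score(cid, pos_score)
        tp = round(sens_printed * JADE_N_ADR)
        fp = marginals[pos_score] - tp
        if fp < 0:
            raise CalibrationError(
                f"component {cid}: reconstructed FP negative (TP={tp} exceeds column)"
            )
        implied_spec = (JADE_N_NOT_ADR - fp) / JADE_N_NOT_ADR
        if abs(implied_spec - spec_printed) > 0.01:
            raise CalibrationError(
                f"component {cid}: implied specificity {implied_spec:.3f} "
                f"deviates from printed {spec_printed:.2f} by more than 0.01"
            )
        table = empty()
        table[_CLASS_ADR][pos_answer] = tp
        table[_CLASS_NOT][pos_answer] = fp
        adr_rest = JADE_N_ADR - tp
        not_rest = JADE_N_NOT_ADR - fp
        if -1 in marginals:  # evidence-against answers go to the non-ADR class
            neg_answer = _answer_for_score(cid, -1)
            neg_count = marginals[-1]
            if neg_count > not_rest:
                raise CalibrationError(
                    f"component {cid}: negative-score column exceeds non-ADR mass"
                )
            table[_CLASS_NOT][neg_answer] += neg_count
            not_rest -= neg_count
        zero_answer = _answer_for_score(cid, 0)
        table[_CLASS_ADR][zero_answer] += adr_rest
        table[_CLASS_NOT][zero_answer] += not_rest
        counts[cid] = table

    # components 6-10: positive-score answers are confirmed ADRs
    for cid in (6, 7, 8, 9, 10):
        marginals = _TABLE_SCORE_COUNTS[cid]
        pos_score = max(marginals)
        pos_answer = _answer_for_score(cid, pos_score)
        pos_count = marginals[pos_score]
        table = empty()
        zero_answer = _answer_for_score(cid, 0)
        table[_CLASS_ADR][pos_answer] = pos_count
        table[_CLASS_ADR][zero_answer] = JADE_N_ADR - pos_count
        table[_CLASS_NOT][zero_answer] = JADE_N_NOT_ADR
        counts[cid] = table

    params = CohortParameters(class_counts=counts)
    params.validate()
    _check_marginals(params)
    return params


def _check_marginals(params: CohortParameters) -> None:
    """Implied score-column counts must match the published table within 1."""
    for cid, marginals in _TABLE_SCORE_COUNTS.items():
        table = ORIGINAL_COMPONENT_SCORES[cid]
        for score, expected in marginals.items():
            implied = sum(
                params.class_counts[cid][cls].get(a, 0.0)
                for cls in (_CLASS_ADR, _CLASS_NOT)
                for a in (_Y, _N, _D)
                if table[a] == score
            )
            if abs(implied - expected) > 1:
                raise CalibrationError(
                    f"component {cid}, score {score:+d}: implied marginal "
                    f"{implied:.0f} differs from published {expected} by more than 1"
                )


def simulate(
    params: CohortParameters, n: int, seed: Optional[int] = None
) -> list[AssessmentRecord]:
    """Draw a labelled synthetic cohort of ``n`` suspected ADRs.

    Labels are Bernoulli(prevalence); answers are drawn independently per
    component conditional on the label.  The same seed yields the same
    cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    labels = rng.random(n) < params.prevalence
    answers_by_component: dict[int, np.ndarray] = {}
    answer_order = (_Y, _N, _D)
    for cid in range(1, 11):
        idx = np.empty(n, dtype=np.int64)
        for adr in (True, False):
            mask = labels == adr
            p = params.probabilities(cid, adr)
            pvec = np.array([p[a] for a in answer_order])
            idx[mask] = rng.choice(3, size=int(mask.sum()), p=pvec)
        answers_by_component[cid] = idx
    digits = len(str(n))
    return [
        AssessmentRecord(
            record_id=f"sim{i:0{digits}d}",
            answers={
                cid: answer_order[answers_by_component[cid][i]] for cid in range(1, 11)
            },
            gold_label=bool(labels[i]),
        )
        for i in range(n)
    ]


def reconstruction_fixture_component1() -> list[AssessmentRecord]:
    """The exact published cross-tabulation of question 1 against the
    adjudicated outcome, expanded to 1579 single-question records:
    866 (yes, ADR), 136 (yes, not ADR), 131 (no, ADR), 446 (no, not ADR).
    """
    blocks = [
        (_Y, True, _C1_TP),
        (_Y, False, _C1_FP),
        (_N, True, JADE_N_ADR - _C1_TP),
        (_N, False, JADE_N_NOT_ADR - _C1_FP),
    ]
    records = []
    i = 0
    for answer, label, count in blocks:
        for _ in range(count):
            records.append(
                AssessmentRecord(
                    record_id=f"jade{i:04d}", answers={1: answer}, gold_label=label
                )
            )
            i += 1
    return records


def component_confusion(
    records: Sequence[AssessmentRecord], component_id: int
) -> ConfusionMatrix:
    """Single-component accuracy: a positive component score predicts ADR.

    Do-not-know scores 0 and therefore counts as a negative prediction
    (it is pooled with "no" in the published per-component analysis).
    """
    table = ORIGINAL_COMPONENT_SCORES[component_id]
    tp = fp = tn = fn = 0
    for r in records:
        if r.gold_label is None:
            raise ValueError("gold labels required for component accuracy")
        if component_id not in r.answers:
            raise MissingAnswerError(
                f"record {r.record_id!r} missing answer for component {component_id}"
            )
        predicted = table[r.answers[component_id]] > 0
        if predicted and r.gold_label:
            tp += 1
        elif predicted:
            fp += 1
        elif r.gold_label:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def model_score_distribution(
    params: CohortParameters, scheme: ScoringScheme
) -> tuple[dict[int, float], dict[int, float]]:
    """Exact class-conditional total-score distributions under the model.

    Convolves the per-component score distributions (components are
    independent given the class), returning (ADR pmf, non-ADR pmf) keyed
    by total score.  Useful as an analytic reference for simulated
    cohorts.
    """
    out = []
    for adr in (True, False):
        pmf: dict[int, float] = {0: 1.0}
        for cid in scheme.components:
            p = params.probabilities(cid, adr)
            new: dict[int, float] = {}
            for total, mass in pmf.items():
                for a in (_Y, _N, _D):
                    if p[a] == 0.0:
                        continue
                    t = total + scheme.score(cid, a)
                    new[t] = new.get(t, 0.0) + mass * p[a]
            pmf = new
        out.append(pmf)
    return out[0], out[1]


def model_auc(params: CohortParameters, scheme: ScoringScheme) -> float:
    """Exact model AUC: P(S+ > S-) + 0.5 P(S+ = S-) under the model."""
    pos, neg = model_score_distribution(params, scheme)
    auc = 0.0
    for sp, pp in pos.items():
        for sn, pn in neg.items():
            if sp > sn:
                auc += pp * pn
            elif sp == sn:
                auc += 0.5 * pp * pn
    return auc


# ---------------------------------------------------------------------------
# Input / output
# ---------------------------------------------------------------------------

_LABEL_TOKENS = {"adr": True, "no_adr": False}
_REQUIRED_COLUMNS = ["record_id"] + [f"q{i}" for i in range(1, 11)]


def _parse_answer_cell(
    raw, row_label: str, column: str, coerce_missing_to_dk: bool
) -> Answer:
    missing = raw is None or (isinstance(raw, float) and math.isnan(raw)) or (
        isinstance(raw, str) and raw.strip() == ""
    )
    if missing:
        if coerce_missing_to_dk:
            return _D
        raise RecordFormatError(
            f"missing answer at row {row_label}, column {column} "
            "(pass coerce_missing_to_dk=True to read it as do-not-know)"
        )
    try:
        return Answer.from_token(str(raw))
    except ValueError:
        raise RecordFormatError(
            f"unknown answer token {raw!r} at row {row_label}, column {column}"
        ) from None


def _parse_label_cell(raw, row_label: str) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    token = str(raw).strip().lower()
    if token == "":
        return None
    if token not in _LABEL_TOKENS:
        raise RecordFormatError(
            f"unknown label token {raw!r} at row {row_label} (expected adr/no_adr)"
        )
    return _LABEL_TOKENS[token]


def read_records(
    path, dialect: Optional[str] = None, coerce_missing_to_dk: bool = False
) -> list[AssessmentRecord]:
    """Read assessment records from CSV or JSON.

    CSV requires a header with ``record_id`` and ``q1``..``q10`` (answers
    ``yes``/``no``/``dk``, case-insensitive) plus an optional ``label``
    column (``adr``/``no_adr``); any further columns become metadata.
    JSON holds a list of record objects as produced by
    :func:`write_records`.  Unknown answer tokens are rejected with their
    row and column; empty cells are rejected unless
    ``coerce_missing_to_dk`` is set, in which case they read as
    do-not-know (logged).
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect not in ("csv", "json"):
        raise ValueError(f"unknown dialect {dialect!r}; expected csv or json")
    if dialect == "json":
        records = _read_records_json(path, coerce_missing_to_dk)
    else:
        records = _read_records_csv(path, coerce_missing_to_dk)
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise RecordFormatError(f"duplicate record_id {r.record_id!r}")
        seen.add(r.record_id)
    n_labelled = sum(r.gold_label is not None for r in records)
    logger.info(
        "read %d record(s) from %s (%d labelled)", len(records), path, n_labelled
    )
    return records


def _read_records_csv(path: Path, coerce: bool) -> list[AssessmentRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise RecordFormatError(f"missing required column(s): {missing_cols}")
    extra_cols = [
        c for c in frame.columns if c not in _REQUIRED_COLUMNS and c != "label"
    ]
    records = []
    n_coerced = 0
    for i, row in frame.iterrows():
        row_label = str(i + 2)  # 1-based file line, after the header
        answers = {}
        for cid in range(1, 11):
            raw = row[f"q{cid}"]
            ans = _parse_answer_cell(raw, row_label, f"q{cid}", coerce)
            if ans is _D and str(raw).strip() == "":
                n_coerced += 1
            answers[cid] = ans
        label = _parse_label_cell(row.get("label"), row_label) if "label" in frame.columns else None
        metadata = {c: row[c] for c in extra_cols if str(row[c]).strip() != ""} or None
        records.append(
            AssessmentRecord(
                record_id=str(row["record_id"]),
                answers=answers,
                gold_label=label,
                metadata=metadata,
            )
        )
    if n_coerced:
        logger.info("coerced %d empty answer cell(s) to do-not-know", n_coerced)
    return records


def _read_records_json(path: Path, coerce: bool) -> list[AssessmentRecord]:
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, list):
        raise RecordFormatError("JSON records file must contain a list of objects")
    records = []
    for i, obj in enumerate(payload):
        row_label = str(i)
        answers = {
            int(cid): _parse_answer_cell(tok, row_label, f"q{cid}", coerce)
            for cid, tok in obj.get("answers", {}).items()
        }
        label = _parse_label_cell(obj.get("label"), row_label)
        records.append(
            AssessmentRecord(
                record_id=str(obj["record_id"]),
                answers=answers,
                gold_label=label,
                metadata=obj.get("metadata"),
            )
        )
    return records


def write_records(
    records: Sequence[AssessmentRecord], path, dialect: Optional[str] = None
) -> None:
    """Write records to CSV or JSON (inverse of :func:`read_records`)."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        payload = [
            {
                "record_id": r.record_id,
                "answers": {str(c): a.value for c, a in sorted(r.answers.items())},
                "label": None
                if r.gold_label is None
                else ("adr" if r.gold_label else "no_adr"),
                "metadata": r.metadata,
            }
            for r in records
        ]
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}; expected csv or json")
    meta_cols: list[str] = []
    for r in records:
        for k in r.metadata or {}:
            if k not in meta_cols:
                meta_cols.append(k)
    rows = []
    for r in records:
        row = {"record_id": r.record_id}
        for cid in range(1, 11):
            row[f"q{cid}"] = r.answers[cid].value if cid in r.answers else ""
        row["label"] = (
            "" if r.gold_label is None else ("adr" if r.gold_label else "no_adr")
        )
        for k in meta_cols:
            row[k] = (r.metadata or {}).get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


REPORT_SCHEMA_VERSION = "1"


def write_report(report: Mapping, path) -> None:
    """Write an evaluation report as JSON with deterministic key order."""
    if not report:
        raise ValueError("refusing to write an empty report")
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def evaluation_report(
    records: Sequence[AssessmentRecord],
    scheme: ScoringScheme,
    cutoff: Optional[int] = None,
    ci_level: float = 0.95,
) -> dict:
    """Score, classify and evaluate a labelled cohort in one pass.

    Returns a JSON-ready dict with the confusion counts, sensitivity and
    specificity (raw and rounded to 2 decimals), trapezoidal AUC with its
    DeLong interval, and the full cut-off accuracy table.
    """
    if cutoff is None:
        cutoff = scheme.default_cutoff
    scored = with_gold_labels(score_records(records, scheme))
    cm = confusion(scored, cutoff)
    curve = roc(scored)
    lower, upper = auc_ci(scored, level=ci_level)
    table = accuracy_table(scored)
    return {
        "scheme": scheme.name,
        "cutoff": cutoff,
        "n": cm.n,
        "n_unlabelled_dropped": len(records) - cm.n,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "sensitivity": round_half_up(sensitivity(cm)),
        "specificity": round_half_up(specificity(cm)),
        "sensitivity_raw": sensitivity(cm),
        "specificity_raw": specificity(cm),
        "auc": curve.auc,
        "auc_ci": {"lower": lower, "upper": upper, "level": ci_level},
        "accuracy_table": table.to_dict(orient="records"),
    }
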