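"""Sequential-precedence assignment of records and patients to treatment groups.

The published search strategy scans a corpus one treatment group at a time —
TKIs first, then pemetrexed+bevacizumab combinations, pemetrexed-based,
bevacizumab-based, platinum doublets, single agents — removing matched
records before the next pass, then flags explicit no-treatment statements,
and calls everything left unknown.  Because each record is claimed by the
first group whose drugs it mentions, that elimination order is equivalent to
a fixed precedence over the non-negated drug classes present in a single
record, which is how :func:`assign_group` implements it (better audit trail,
identical record-level labels).

Patient-level first-line assignment picks the earliest-dated record among
those classified into one of the six treatment groups; explicit no-treatment
evidence beats absence of information.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .lexicon import CompiledMatcher, Lexicon, compile_lexicon, default_lexicon
from .matcher import (
    DEFAULT_NEGATION_WINDOW,
    DrugMention,
    TextRecord,
    detect_no_treatment,
    find_mentions,
)

__all__ = [
    "TreatmentGroup",
    "RecordClassification",
    "PatientClassification",
    "FirstLineClassifier",
    "assign_group",
    "classify_record",
    "classify_patient",
    "classify_cohort",
]


class TreatmentGroup(str, Enum):
    """The eight first-line systemic treatment categories."""

    TKI = "tki"
    PEM_BEV = "pem_bev"
    PEMETREXED_BASED = "pemetrexed_based"
    BEVACIZUMAB_BASED = "bevacizumab_based"
    PLATINUM_DOUBLET = "platinum_doublet"
    SINGLE_AGENT = "single_agent"
    NO_TREATMENT = "no_treatment"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_treatment(self) -> bool:
        """True for the six drug-defined groups."""
        return self not in (TreatmentGroup.NO_TREATMENT, TreatmentGroup.UNKNOWN)


#: Precedence order of the six drug-defined groups (searched first to last).
TREATMENT_GROUPS: tuple[TreatmentGroup, ...] = (
    TreatmentGroup.TKI,
    TreatmentGroup.PEM_BEV,
    TreatmentGroup.PEMETREXED_BASED,
    TreatmentGroup.BEVACIZUMAB_BASED,
    TreatmentGroup.PLATINUM_DOUBLET,
    TreatmentGroup.SINGLE_AGENT,
)


@dataclass(frozen=True)
class RecordClassification:
    record_id: str
    group: TreatmentGroup
    mentions: tuple[DrugMention, ...] = ()
    rule_fired: str = "unknown"


@dataclass(frozen=True)
class PatientClassification:
    patient_id: str
    group: TreatmentGroup
    source_record_id: str | None = None
    n_records: int = 0


def assign_group(
    mentions: Sequence[DrugMention],
    no_treatment_flag: bool,
    mode: str = "faithful",
) -> tuple[TreatmentGroup, str]:
    """First matching label, in strict precedence order, for one record.

    ``mentions`` must already exclude negated mentions.  Distinctness is by
    canonical drug name.  ``mode='faithful'`` mirrors the published
    behaviour where any leftover drug evidence falls into the single-agent
    catch-all; ``mode='strict'`` sends multi-drug non-platinum leftovers to
    unknown instead.

    Returns ``(group, rule_fired)`` where ``rule_fired`` names the matched
    stage for auditing.
    """
    if mode not in ("faithful", "strict"):
        raise ValueError(f"mode must be 'faithful' or 'strict', got {mode!r}")
    classes = {m.drug_class for m in mentions}
    canonicals = {m.canonical for m in mentions}
    if "tki" in classes:
        return TreatmentGroup.TKI, "stage1_tki"
    if "pemetrexed" in classes and "bevacizumab" in classes:
        return TreatmentGroup.PEM_BEV, "stage2_pem_bev"
    if "pemetrexed" in classes:
        return TreatmentGroup.PEMETREXED_BASED, "stage3_pemetrexed"
    if "bevacizumab" in classes:
        return TreatmentGroup.BEVACIZUMAB_BASED, "stage4_bevacizumab"
    if "platinum" in classes and "other_chemo" in classes:
        return TreatmentGroup.PLATINUM_DOUBLET, "stage5_platinum_doublet"
    if canonicals:
        if mode == "strict" and len(canonicals) > 1:
            return TreatmentGroup.UNKNOWN, "stage8_unknown_multi_agent"
        return TreatmentGroup.SINGLE_AGENT, "stage6_single_agent"
    if no_treatment_flag:
        return TreatmentGroup.NO_TREATMENT, "stage7_no_treatment"
    return TreatmentGroup.UNKNOWN, "stage8_unknown"


def classify_record(
    record: TextRecord,
    matcher: CompiledMatcher,
    mode: str = "faithful",
    negation_window: int = DEFAULT_NEGATION_WINDOW,
    count_uncertain: bool = True,
) -> RecordClassification:
    """Classify one record: normalize, find mentions, drop negated mentions,
    detect no-treatment statements, assign the precedence group.

    Uncertain mentions count as treatment evidence by default (matching the
    published algorithm's observed false-positive behaviour); pass
    ``count_uncertain=False`` to exclude them.
    """
    mentions = find_mentions(record, matcher, negation_window=negation_window)
    qualifying = [
        m
        for m in mentions
        if not m.negated and (count_uncertain or not m.uncertain)
    ]
    flag = detect_no_treatment(record.text, matcher.lexicon.phrases)
    group, rule = assign_group(qualifying, flag, mode=mode)
    return RecordClassification(
        record_id=record.record_id,
        group=group,
        mentions=tuple(mentions),
        rule_fired=rule,
    )


def _record_sort_key(record: TextRecord, date_policy: str):
    # Undated records sort first ("date unknown, possibly earliest") under
    # the default policy; record_id breaks ties deterministically.
    undated = record.record_date is None
    rank = (0 if undated else 1) if date_policy == "undated-first" else (1 if undated else 0)
    return (rank, record.record_date or date.min, record.record_id)


def classify_patient(
    record_classifications: Sequence[RecordClassification],
    records: Sequence[TextRecord],
    date_policy: str = "undated-first",
) -> PatientClassification:
    """Aggregate one patient's record labels into a first-line label.

    Among records classified into the six treatment groups, the earliest by
    ``record_date`` determines the patient group.  If there is none, any
    no-treatment record yields no_treatment (explicit negative evidence
    outweighs absence of information); otherwise unknown.
    """
    if date_policy not in ("undated-first", "undated-last"):
        raise ValueError(f"unknown date_policy {date_policy!r}")
    if not records or not record_classifications:
        raise ValueError("classify_patient requires non-empty inputs")
    patient_ids = {r.patient_id for r in records}
    if len(patient_ids) != 1:
        raise ValueError(f"records span multiple patients: {sorted(patient_ids)}")
    patient_id = patient_ids.pop()
    by_id = {r.record_id: r for r in records}
    missing = [c.record_id for c in record_classifications if c.record_id not in by_id]
    if missing:
        raise ValueError(f"classifications reference unknown records: {missing}")

    def sort_key(c: RecordClassification):
        return _record_sort_key(by_id[c.record_id], date_policy)

    treated = sorted(
        (c for c in record_classifications if c.group.is_treatment), key=sort_key
    )
    if treated:
        first = treated[0]
        return PatientClassification(
            patient_id, first.group, first.record_id, len(records)
        )
    untreated = sorted(
        (c for c in record_classifications if c.group is TreatmentGroup.NO_TREATMENT),
        key=sort_key,
    )
    if untreated:
        return PatientClassification(
            patient_id, TreatmentGroup.NO_TREATMENT, untreated[0].record_id, len(records)
        )
    return PatientClassification(patient_id, TreatmentGroup.UNKNOWN, None, len(records))


def classify_cohort(
    records: Sequence[TextRecord],
    matcher: CompiledMatcher,
    mode: str = "faithful",
    negation_window: int = DEFAULT_NEGATION_WINDOW,
    date_policy: str = "undated-first",
    count_uncertain: bool = True,
) -> list[PatientClassification]:
    """Classify a whole corpus: one :class:`PatientClassification` per
    distinct patient_id, sorted by patient_id.  Deterministic and invariant
    to input record ordering."""
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise ValueError(f"duplicate record_id {r.record_id!r}")
        seen.add(r.record_id)
    by_patient: dict[str, list[TextRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    out: list[PatientClassification] = []
    for patient_id in sorted(by_patient):
        recs = sorted(by_patient[patient_id], key=lambda r: r.record_id)
        classifications = [
            classify_record(
                r,
                matcher,
                mode=mode,
                negation_window=negation_window,
                count_uncertain=count_uncertain,
            )
            for r in recs
        ]
        out.append(classify_patient(classifications, recs, date_policy=date_policy))
    return out


class FirstLineClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based classifier of registry free text into the eight first-line
    systemic treatment groups.

    A scikit-learn compatible estimator: ``fit`` compiles the lexicon (no
    parameters are learned — the rules are the model), ``predict`` labels an
    array of free-text strings record by record.  Patient-level aggregation
    over a records table is exposed via :meth:`predict_patients`.

    Parameters
    ----------
    lexicon :
        A :class:`~firstline.lexicon.Lexicon`, or None for the packaged
        default.
    mode :
        'faithful' (published catch-all behaviour for leftover drug
        evidence) or 'strict' (multi-drug non-platinum leftovers -> unknown).
    negation_window :
        Characters between a negation/uncertainty phrase and a mention
        within which the phrase applies.
    date_policy :
        'undated-first' or 'undated-last' — where records without a date
        sort when choosing the earliest treatment record.
    count_uncertain :
        Whether uncertain mentions ("unknown if given") count as treatment
        evidence.
    """

    def __init__(
        self,
        lexicon: Lexicon | None = None,
        mode: str = "faithful",
        negation_window: int = DEFAULT_NEGATION_WINDOW,
        date_policy: str = "undated-first",
        count_uncertain: bool = True,
    ):
        self.lexicon = lexicon
        self.mode = mode
        self.negation_window = negation_window
        self.date_policy = date_policy
        self.count_uncertain = count_uncertain

    def fit(self, X=None, y=None) -> "FirstLineClassifier":
        """Validate parameters and compile the lexicon.  ``X`` and ``y`` are
        accepted for pipeline compatibility and ignored."""
        if self.mode not in ("faithful", "strict"):
            raise ValueError(f"mode must be 'faithful' or 'strict', got {self.mode!r}")
        if self.date_policy not in ("undated-first", "undated-last"):
            raise ValueError(f"unknown date_policy {self.date_policy!r}")
        if not (isinstance(self.negation_window, (int, np.integer)) and self.negation_window >= 0):
            raise ValueError("negation_window must be a non-negative integer")
        self.lexicon_ = self.lexicon if self.lexicon is not None else default_lexicon()
        self.matcher_ = compile_lexicon(self.lexicon_)
        self.classes_ = np.array([g.value for g in TreatmentGroup], dtype=object)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "matcher_"):
            raise AttributeError(
                "This FirstLineClassifier instance is not fitted yet; call fit() first."
            )

    def classify_record(self, record: TextRecord) -> RecordClassification:
        self._check_fitted()
        return classify_record(
            record,
            self.matcher_,
            mode=self.mode,
            negation_window=self.negation_window,
            count_uncertain=self.count_uncertain,
        )

    def predict(self, X: Iterable[str]) -> np.ndarray:
        """Record-level group labels for an iterable of free-text strings."""
        self._check_fitted()
        labels = []
        for i, text in enumerate(X):
            rec = TextRecord(patient_id=f"x{i}", record_id=f"x{i}", text=str(text))
            labels.append(self.classify_record(rec).group.value)
        return np.asarray(labels, dtype=object)

    def predict_records(self, records: Sequence[TextRecord]) -> list[RecordClassification]:
        self._check_fitted()
        return [self.classify_record(r) for r in records]

    def predict_patients(self, records: Sequence[TextRecord]) -> list[PatientClassification]:
        """Patient-level first-line labels for a corpus of records."""
        self._check_fitted()
        return classify_cohort(
            records,
            self.matcher_,
            mode=self.mode,
            negation_window=self.negation_window,
            date_policy=self.date_policy,
            count_uncertain=self.count_uncertain,
        )
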