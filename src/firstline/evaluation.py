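"""Agreement and diagnostic-accuracy statistics against a gold standard.

Each of the eight treatment groups is evaluated one-vs-rest: both labelings
are dichotomized at the group, giving a 2x2 contingency table from which
percent agreement, Cohen's kappa, sensitivity, specificity, PPV, NPV and
false-positive / false-negative / total-error counts are derived — the full
set of statistics a registry validation study reports.

Confidence intervals: Wilson score by default for proportions (Wald and
Clopper-Pearson available), and the asymptotic large-sample standard error
of kappa (Fleiss, Cohen & Everitt) for the kappa interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .classify import TreatmentGroup

__all__ = [
    "ContingencyTable2x2",
    "Metric",
    "GroupEvaluation",
    "EvaluationReport",
    "UndefinedMetricError",
    "build_contingency",
    "percent_agreement",
    "cohen_kappa",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "error_counts",
    "evaluate",
    "evaluate_tables",
]

_CI_METHODS = {"wilson": "wilson", "wald": "normal", "exact": "beta"}


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero or its table is degenerate."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """One-vs-rest counts: tp = algorithm yes & gold yes, fp = algorithm yes
    & gold no, fn = algorithm no & gold yes, tn = algorithm no & gold no."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metric:
    """A point estimate with its 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate + 1e-12 and self.estimate <= self.ci_high + 1e-12):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket {self.estimate}"
            )


def _require_n(t: ContingencyTable2x2) -> None:
    if t.n == 0:
        raise UndefinedMetricError("contingency table is empty (n=0)")


def _proportion(num: int, den: int, n: int, ci_method: str, what: str) -> Metric:
    if den == 0:
        raise UndefinedMetricError(f"{what} undefined: denominator is zero")
    if ci_method not in _CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    low, high = proportion_confint(num, den, alpha=0.05, method=_CI_METHODS[ci_method])
    est = num / den
    # Wald intervals can escape [0,1] and need not bracket at the boundary.
    low = min(max(float(low), 0.0), est)
    high = max(min(float(high), 1.0), est)
    return Metric(estimate=est, ci_low=low, ci_high=high, n=den)


def percent_agreement(t: ContingencyTable2x2, ci_method: str = "wilson") -> Metric:
    """Observed agreement (tp+tn)/n for the one-vs-rest dichotomization."""
    _require_n(t)
    return _proportion(t.tp + t.tn, t.n, t.n, ci_method, "percent agreement")


def _kappa_se(t: ContingencyTable2x2, po: float, pe: float) -> float:
    """Asymptotic large-sample SE of kappa for a 2x2 table
    (Fleiss, Cohen & Everitt 1969)."""
    n = t.n
    # cell proportions: rows = algorithm, columns = gold
    p = [[t.tp / n, t.fp / n], [t.fn / n, t.tn / n]]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
    term1 = sum(
        p[i][i] * ((1 - pe) - (col[i] + row[i]) * (1 - po)) ** 2 for i in range(2)
    )
    term2 = (1 - po) ** 2 * sum(
        p[i][j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    return math.sqrt(max(var, 0.0))


def cohen_kappa(t: ContingencyTable2x2, ci_method: str = "wilson") -> Metric:
    """Chance-corrected agreement (po - pe) / (1 - pe).

    pe comes from the table's marginals.  The CI uses the asymptotic
    standard error regardless of ``ci_method`` (accepted for interface
    symmetry with the proportion metrics).
    """
    _require_n(t)
    n = t.n
    po = (t.tp + t.tn) / n
    pe = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / n**2
    if pe >= 1.0:
        raise UndefinedMetricError("kappa undefined: expected agreement is 1 (degenerate marginals)")
    k = (po - pe) / (1 - pe)
    se = _kappa_se(t, po, pe)
    z = norm.ppf(0.975)
    low = max(k - z * se, -1.0)
    high = min(k + z * se, 1.0)
    return Metric(estimate=k, ci_low=min(low, k), ci_high=max(high, k), n=n)


def sensitivity(t: ContingencyTable2x2, ci_method: str = "wilson") -> Metric:
    """tp / (tp + fn): proportion of gold-positive patients the algorithm finds."""
    _require_n(t)
    return _proportion(t.tp, t.tp + t.fn, t.n, ci_method, "sensitivity")


def specificity(t: ContingencyTable2x2, ci_method: str = "wilson") -> Metric:
    """tn / (tn + fp): proportion of gold-negative patients correctly excluded."""
    _require_n(t)
    return _proportion(t.tn, t.tn + t.fp, t.n, ci_method, "specificity")


def ppv(t: ContingencyTable2x2, ci_method: str = "wilson") -> Metric:
    """tp / (tp + fp): precision of positive algorithm calls."""
    _require_n(t)
    return _proportion(t.tp, t.tp + t.fp, t.n, ci_method, "PPV")


def npv(t: ContingencyTable2x2, ci_method: str = "wilson") -> Metric:
    """tn / (tn + fn): precision of negative algorithm calls."""
    _require_n(t)
    return _proportion(t.tn, t.tn + t.fn, t.n, ci_method, "NPV")


def error_counts(t: ContingencyTable2x2) -> tuple[int, int, int]:
    """(false positives, false negatives, total errors) for one group."""
    return (t.fp, t.fn, t.fp + t.fn)


def _as_label_map(
    labels: Iterable[tuple[str, TreatmentGroup | str]], name: str
) -> dict[str, TreatmentGroup]:
    out: dict[str, TreatmentGroup] = {}
    for patient_id, group in labels:
        if patient_id in out:
            raise ValueError(f"{name} labels contain duplicate patient_id {patient_id!r}")
        out[patient_id] = TreatmentGroup(group)
    return out


def build_contingency(
    pred: Iterable[tuple[str, TreatmentGroup | str]],
    gold: Iterable[tuple[str, TreatmentGroup | str]],
    group: TreatmentGroup | str,
) -> ContingencyTable2x2:
    """Dichotomize both labelings at ``group`` over a matched patient set."""
    group = TreatmentGroup(group)
    p = _as_label_map(pred, "pred")
    g = _as_label_map(gold, "gold")
    if p.keys() != g.keys():
        missing_in_pred = sorted(g.keys() - p.keys())
        missing_in_gold = sorted(p.keys() - g.keys())
        raise ValueError(
            "patient sets differ: "
            f"missing in pred {missing_in_pred[:10]}, missing in gold {missing_in_gold[:10]}"
        )
    tp = fp = fn = tn = 0
    for pid, pg in p.items():
        algo_yes = pg is group
        gold_yes = g[pid] is group
        if algo_yes and gold_yes:
            tp += 1
        elif algo_yes:
            fp += 1
        elif gold_yes:
            fn += 1
        else:
            tn += 1
    return ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class GroupEvaluation:
    """All statistics for one treatment group's one-vs-rest table."""

    group: TreatmentGroup
    table: ContingencyTable2x2
    agreement: Metric
    kappa: Metric
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    fp: int
    fn: int
    total_errors: int


@dataclass(frozen=True)
class EvaluationReport:
    """Per-group statistics for all eight groups plus the overall n."""

    groups: Mapping[TreatmentGroup, GroupEvaluation]
    n: int

    def __post_init__(self) -> None:
        missing = [g for g in TreatmentGroup if g not in self.groups]
        if missing:
            raise ValueError(f"report missing groups: {[g.value for g in missing]}")
        for ge in self.groups.values():
            if ge.table.n != self.n:
                raise ValueError(
                    f"group {ge.group.value} table n={ge.table.n} != overall n={self.n}"
                )

    def to_frame(self):
        """The report as a pandas DataFrame, one row per group, percentages
        and kappa at the conventional display precision."""
        import pandas as pd

        rows = []
        for g in TreatmentGroup:
            ge = self.groups[g]
            rows.append(
                {
                    "group": g.value,
                    "tp": ge.table.tp,
                    "fp": ge.table.fp,
                    "fn": ge.table.fn,
                    "tn": ge.table.tn,
                    "agreement_pct": round_half_up(100 * ge.agreement.estimate, 1),
                    "kappa": round_half_up(ge.kappa.estimate, 2),
                    "sensitivity_pct": round_half_up(100 * ge.sensitivity.estimate, 1),
                    "specificity_pct": round_half_up(100 * ge.specificity.estimate, 1),
                    "ppv_pct": round_half_up(100 * ge.ppv.estimate, 1),
                    "npv_pct": round_half_up(100 * ge.npv.estimate, 1),
                    "false_positives": ge.fp,
                    "false_negatives": ge.fn,
                    "total_errors": ge.total_errors,
                }
            )
        return pd.DataFrame(rows)


def round_half_up(x: float, digits: int) -> float:
    """Decimal half-up rounding, the convention used for display tables."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _evaluate_table(
    group: TreatmentGroup, t: ContingencyTable2x2, ci_method: str
) -> GroupEvaluation:
    fp_, fn_, tot = error_counts(t)
    return GroupEvaluation(
        group=group,
        table=t,
        agreement=percent_agreement(t, ci_method),
        kappa=cohen_kappa(t, ci_method),
        sensitivity=sensitivity(t, ci_method),
        specificity=specificity(t, ci_method),
        ppv=ppv(t, ci_method),
        npv=npv(t, ci_method),
        fp=fp_,
        fn=fn_,
        total_errors=tot,
    )


def evaluate_tables(
    tables: Mapping[TreatmentGroup | str, ContingencyTable2x2],
    ci_method: str = "wilson",
) -> EvaluationReport:
    """Build a report directly from eight one-vs-rest contingency tables
    (the counts-only entry point for published tables)."""
    normalized = {TreatmentGroup(g): t for g, t in tables.items()}
    ns = {t.n for t in normalized.values()}
    if len(ns) != 1:
        raise ValueError(f"tables disagree on n: {sorted(ns)}")
    groups = {g: _evaluate_table(g, t, ci_method) for g, t in normalized.items()}
    return EvaluationReport(groups=groups, n=ns.pop())


def evaluate(
    pred: Iterable[tuple[str, TreatmentGroup | str]],
    gold: Iterable[tuple[str, TreatmentGroup | str]],
    ci_method: str = "wilson",
) -> EvaluationReport:
    """Full one-vs-rest evaluation of predicted vs gold patient labels."""
    pred = list(pred)
    gold = list(gold)
    tables = {g: build_contingency(pred, gold, g) for g in TreatmentGroup}
    return evaluate_tables(tables, ci_method=ci_method)
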