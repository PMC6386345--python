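"""Synthetic registry-style free-text corpora with known gold labels.

The generator emulates the structure of a cancer-registry treatment-text
corpus: one gold first-line group per patient, one informative record plus a
variable number of follow-up records (some blank), telegraphic phrasing,
brand names / abbreviations / curated misspellings, negated distractor
drugs ("not a candidate for X"), uncertainty phrasing, and explicit
refusal / hospice statements for untreated patients.

Default prevalences echo a realistic stage IV NSCLC registry cohort of the
2012-2014 era: roughly a third of patients untreated and a fifth with
unknown treatment, the remainder split across the six drug-defined groups
with platinum doublets and pemetrexed-based regimens most common.

Every noise channel is label-preserving by construction except uncertainty
phrasing on untreated patients, whose effect on the patient-level confusion
matrix is available in closed form from :func:`expected_confusion`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .classify import TreatmentGroup
from .matcher import TextRecord

__all__ = [
    "SimulationConfig",
    "GoldLabeledCorpus",
    "UnsupportedConfigError",
    "generate_corpus",
    "expected_confusion",
    "DEFAULT_PREVALENCE",
]

#: Cohort composition the generator emulates by default: ~32% untreated,
#: ~22% unknown, the remaining 46% split across the six treatment groups
#: in realistic proportions (platinum doublets and pemetrexed-based most
#: common, single agents rarest).
DEFAULT_PREVALENCE: dict[TreatmentGroup, float] = {
    TreatmentGroup.PLATINUM_DOUBLET: 0.155,
    TreatmentGroup.PEMETREXED_BASED: 0.120,
    TreatmentGroup.BEVACIZUMAB_BASED: 0.030,
    TreatmentGroup.PEM_BEV: 0.035,
    TreatmentGroup.SINGLE_AGENT: 0.020,
    TreatmentGroup.TKI: 0.100,
    TreatmentGroup.NO_TREATMENT: 0.320,
    TreatmentGroup.UNKNOWN: 0.220,
}

_PLATINUM = ("cisplatin", "carboplatin")
_OTHER = ("paclitaxel", "docetaxel", "gemcitabine", "vinorelbine", "etoposide",
          "nab-paclitaxel", "irinotecan")
_TKI = ("erlotinib", "gefitinib", "afatinib", "crizotinib")

# Surface-variant tables mirroring the packaged default lexicon; swapping a
# canonical for any of these never changes the classification because the
# lexicon resolves them back to the canonical.
_BRANDS = {
    "cisplatin": "platinol", "carboplatin": "paraplatin", "pemetrexed": "alimta",
    "bevacizumab": "avastin", "erlotinib": "tarceva", "gefitinib": "iressa",
    "afatinib": "gilotrif", "crizotinib": "xalkori", "paclitaxel": "taxol",
    "nab-paclitaxel": "abraxane", "docetaxel": "taxotere", "gemcitabine": "gemzar",
    "vinorelbine": "navelbine", "etoposide": "vepesid", "irinotecan": "camptosar",
}
_ABBREVS = {
    "cisplatin": "cddp", "carboplatin": "carbo", "bevacizumab": "bev",
    "gemcitabine": "gem", "etoposide": "vp-16", "irinotecan": "cpt-11",
}
_MISSPELLINGS = {
    "cisplatin": "cisplantin", "carboplatin": "carboplaten",
    "pemetrexed": "premetrexed", "bevacizumab": "bevacuzimab",
    "erlotinib": "erlotnib", "gefitinib": "gefitnib", "paclitaxel": "paclitaxol",
    "docetaxel": "docetaxol", "gemcitabine": "gemcitabene",
    "vinorelbine": "vinorelbin", "etoposide": "etopocide",
}

#: Drug offered in the "recommended, unknown if given" template, with the
#: group an uncertain (but counted) mention of it maps to.  Fixed so the
#: induced confusion is enumerable.
UNCERTAINTY_DRUGS: tuple[tuple[str, TreatmentGroup], ...] = (
    ("carboplatin", TreatmentGroup.SINGLE_AGENT),
    ("pemetrexed", TreatmentGroup.PEMETREXED_BASED),
    ("bevacizumab", TreatmentGroup.BEVACIZUMAB_BASED),
    ("erlotinib", TreatmentGroup.TKI),
    ("docetaxel", TreatmentGroup.SINGLE_AGENT),
)

_DEFAULT_TEMPLATES: dict[str, tuple[str, ...]] = {
    "platinum_doublet": (
        "{plat} and {other} started {month}/{year}",
        "plan: {plat}/{other} x4 cycles",
        "received {plat} with {other}",
        "{plat} + {other} initiated",
    ),
    "pemetrexed_based": (
        "started {pem} {month}/{year}",
        "{pem} and {plat} q3w",
        "{pem} maintenance ongoing",
    ),
    "bevacizumab_based": (
        "{bev} added to {other}",
        "{bev} + {plat} begun",
        "{bev} monotherapy",
    ),
    "pem_bev": (
        "{pem} + {bev} started",
        "started {pem}, {bev} and {plat}",
        "{pem}/{bev} combination {month}/{year}",
    ),
    "single_agent": (
        "single agent {drug}",
        "{drug} monotherapy",
        "{drug} weekly",
    ),
    "tki": (
        "started {tki} daily",
        "{tki} po daily",
        "on {tki} since {month}/{year}",
    ),
    "no_treatment": (
        "patient refused treatment",
        "patient opted for hospice instead of treatment",
        "no treatment given. family informed.",
        "patient died before any treatment given",
        "comfort care only",
    ),
    "unknown": (
        "",
        "",
        "see chart",
        "follow-up scheduled",
        "records requested from facility",
    ),
    "uncertainty": (
        "{drug} recommended, unknown if given",
    ),
    "distractor": (
        "not a candidate for {drug}",
    ),
}


class UnsupportedConfigError(ValueError):
    """The configuration falls outside the analytically tractable subset."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    ``records_per_patient_mean`` is the mean of 1 + Poisson; probabilities
    are per-drug-rendering (surface swaps), per-record (distractors, blank
    extras) or per-untreated-patient (uncertainty phrasing).
    """

    n_patients: int = 17310
    group_prevalence: Mapping[TreatmentGroup, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    records_per_patient_mean: float = 1.435
    p_misspell: float = 0.03
    p_abbrev: float = 0.10
    p_brand: float = 0.20
    p_negation_distractor: float = 0.05
    p_uncertainty: float = 0.05
    p_blank_extra_record: float = 0.50
    p_undated: float = 0.05
    seed: int = 0
    templates: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.records_per_patient_mean < 1:
            raise ValueError("records_per_patient_mean must be >= 1")
        prev = {TreatmentGroup(g): p for g, p in self.group_prevalence.items()}
        object.__setattr__(self, "group_prevalence", prev)
        if abs(sum(prev.values()) - 1.0) > 1e-9:
            raise ValueError(f"group prevalences sum to {sum(prev.values())}, not 1")
        for name in ("p_misspell", "p_abbrev", "p_brand", "p_negation_distractor",
                     "p_uncertainty", "p_blank_extra_record", "p_undated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_misspell + self.p_abbrev + self.p_brand > 1.0:
            raise ValueError("surface-variant probabilities sum to more than 1")

    def template_pool(self, key: str) -> tuple[str, ...]:
        if self.templates is not None and key in self.templates:
            pool = tuple(self.templates[key])
            if not pool:
                raise ValueError(f"empty template pool for {key!r}")
            return pool
        return _DEFAULT_TEMPLATES[key]


@dataclass(frozen=True)
class GoldLabeledCorpus:
    records: tuple[TextRecord, ...]
    gold: tuple[tuple[str, TreatmentGroup], ...]
    config_used: SimulationConfig

    def __post_init__(self) -> None:
        patients_with_records = {r.patient_id for r in self.records}
        gold_ids = [pid for pid, _ in self.gold]
        if len(gold_ids) != len(set(gold_ids)):
            raise ValueError("gold contains duplicate patient ids")
        missing = set(gold_ids) - patients_with_records
        if missing:
            raise ValueError(f"gold patients without records: {sorted(missing)[:10]}")


def _render_drug(canonical: str, rng: np.random.Generator, cfg: SimulationConfig) -> str:
    r = rng.random()
    if r < cfg.p_brand:
        return _BRANDS.get(canonical, canonical)
    if r < cfg.p_brand + cfg.p_abbrev:
        return _ABBREVS.get(canonical, canonical)
    if r < cfg.p_brand + cfg.p_abbrev + cfg.p_misspell:
        return _MISSPELLINGS.get(canonical, canonical)
    return canonical


def _pick(rng: np.random.Generator, pool: Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _regimen_text(
    group: TreatmentGroup, rng: np.random.Generator, cfg: SimulationConfig
) -> str:
    """One informative record's text for a gold group (before distractors)."""
    month = int(rng.integers(1, 13))
    year = int(rng.integers(2012, 2015))
    fields = {"month": month, "year": year}
    key = group.value
    template = _pick(rng, cfg.template_pool(key))
    if group is TreatmentGroup.PLATINUM_DOUBLET:
        fields["plat"] = _render_drug(_pick(rng, _PLATINUM), rng, cfg)
        fields["other"] = _render_drug(_pick(rng, _OTHER), rng, cfg)
    elif group is TreatmentGroup.PEMETREXED_BASED:
        fields["pem"] = _render_drug("pemetrexed", rng, cfg)
        fields["plat"] = _render_drug(_pick(rng, _PLATINUM), rng, cfg)
    elif group is TreatmentGroup.BEVACIZUMAB_BASED:
        fields["bev"] = _render_drug("bevacizumab", rng, cfg)
        fields["plat"] = _render_drug(_pick(rng, _PLATINUM), rng, cfg)
        fields["other"] = _render_drug(_pick(rng, _OTHER), rng, cfg)
    elif group is TreatmentGroup.PEM_BEV:
        fields["pem"] = _render_drug("pemetrexed", rng, cfg)
        fields["bev"] = _render_drug("bevacizumab", rng, cfg)
        fields["plat"] = _render_drug(_pick(rng, _PLATINUM), rng, cfg)
    elif group is TreatmentGroup.SINGLE_AGENT:
        fields["drug"] = _render_drug(_pick(rng, _PLATINUM + _OTHER), rng, cfg)
    elif group is TreatmentGroup.TKI:
        fields["tki"] = _render_drug(_pick(rng, _TKI), rng, cfg)
    return template.format(**fields)


_DISTRACTOR_POOL: dict[TreatmentGroup, tuple[str, ...]] = {
    # Distractor drugs come from a class absent from the gold regimen so a
    # failed negation is detectable as a label flip in property tests.
    TreatmentGroup.PLATINUM_DOUBLET: _TKI,
    TreatmentGroup.PEMETREXED_BASED: _TKI,
    TreatmentGroup.BEVACIZUMAB_BASED: _TKI,
    TreatmentGroup.PEM_BEV: _TKI,
    TreatmentGroup.SINGLE_AGENT: _TKI,
    TreatmentGroup.TKI: ("pemetrexed", "bevacizumab"),
    TreatmentGroup.NO_TREATMENT: _TKI + ("pemetrexed", "carboplatin"),
    TreatmentGroup.UNKNOWN: _TKI + ("pemetrexed", "carboplatin"),
}


def generate_corpus(config: SimulationConfig) -> GoldLabeledCorpus:
    """Generate a gold-labeled corpus; byte-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_prevalence)
    probs = np.array([config.group_prevalence[g] for g in groups], dtype=float)
    probs = probs / probs.sum()
    base = date(2012, 1, 1)

    records: list[TextRecord] = []
    gold: list[tuple[str, TreatmentGroup]] = []
    width = max(4, len(str(config.n_patients)))
    for i in range(config.n_patients):
        pid = f"p{i + 1:0{width}d}"
        g = groups[int(rng.choice(len(groups), p=probs))]
        gold.append((pid, g))

        texts: list[str] = [_regimen_text(g, rng, config)]
        n_extra = int(rng.poisson(config.records_per_patient_mean - 1.0))
        for _ in range(n_extra):
            if rng.random() < config.p_blank_extra_record or g is TreatmentGroup.UNKNOWN:
                texts.append(_pick(rng, config.template_pool("unknown")))
            else:
                texts.append(_regimen_text(g, rng, config))
        # Negated distractor drugs, appended per record.
        for j, text in enumerate(texts):
            if rng.random() < config.p_negation_distractor:
                drug = _render_drug(_pick(rng, _DISTRACTOR_POOL[g]), rng, config)
                phrase = _pick(rng, config.template_pool("distractor")).format(drug=drug)
                texts[j] = f"{text}; {phrase}" if text else phrase
        # Uncertainty phrasing: an extra record saying a drug was recommended
        # but possibly never given; applied to untreated patients, where it
        # is the one channel that can flip the patient label.
        if g is TreatmentGroup.NO_TREATMENT and rng.random() < config.p_uncertainty:
            k = int(rng.integers(len(UNCERTAINTY_DRUGS)))
            drug, _ = UNCERTAINTY_DRUGS[k]
            texts.append(
                _pick(rng, config.template_pool("uncertainty")).format(drug=drug)
            )

        for j, text in enumerate(texts, start=1):
            undated = rng.random() < config.p_undated
            record_date = None if undated else base + timedelta(days=int(rng.integers(0, 1096)))
            records.append(
                TextRecord(
                    patient_id=pid,
                    record_id=f"{pid}-r{j}",
                    text=text,
                    record_date=record_date,
                )
            )
    return GoldLabeledCorpus(tuple(records), tuple(gold), config)


def expected_confusion(
    config: SimulationConfig,
    mode: str = "faithful",
    count_uncertain: bool = True,
) -> dict[tuple[TreatmentGroup, TreatmentGroup], float]:
    """Closed-form per-patient confusion probabilities P(predicted | gold).

    Surface-variant swaps resolve through the lexicon, distractor drugs are
    always negated, and blank extra records never change a patient label, so
    each of those channels is identity at patient level.  The only
    off-diagonal channel is uncertainty phrasing on untreated patients: with
    probability ``p_uncertainty`` an extra "recommended, unknown if given"
    record appears whose drug (uniform over :data:`UNCERTAINTY_DRUGS`)
    outranks the no-treatment statement when uncertain mentions count as
    evidence.

    Raises :class:`UnsupportedConfigError` for custom template pools, whose
    effect on the classifier is not enumerable here.
    """
    if config.templates is not None:
        raise UnsupportedConfigError(
            "expected_confusion supports only the built-in template pools"
        )
    if mode not in ("faithful", "strict"):
        raise ValueError(f"mode must be 'faithful' or 'strict', got {mode!r}")
    conf: dict[tuple[TreatmentGroup, TreatmentGroup], float] = {
        (g, h): 0.0 for g in TreatmentGroup for h in TreatmentGroup
    }
    for g in TreatmentGroup:
        conf[(g, g)] = 1.0
    if count_uncertain and config.p_uncertainty > 0:
        nt = TreatmentGroup.NO_TREATMENT
        conf[(nt, nt)] = 1.0 - config.p_uncertainty
        share = config.p_uncertainty / len(UNCERTAINTY_DRUGS)
        for _, target in UNCERTAINTY_DRUGS:
            conf[(nt, target)] += share
    return conf
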