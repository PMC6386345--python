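"""Precedence rules, record classification, patient aggregation, cohort runs."""

from datetime import date
from itertools import product

import pytest
from sklearn.base import clone

from firstline.classify import (
    FirstLineClassifier,
    TreatmentGroup,
    assign_group,
    classify_cohort,
    classify_patient,
    classify_record,
)
from firstline.matcher import DrugMention, TextRecord

# One representative drug per class, for synthesizing mention sets.
REPRESENTATIVE = {
    "platinum": "carboplatin",
    "pemetrexed": "pemetrexed",
    "bevacizumab": "bevacizumab",
    "tki": "erlotinib",
    "other_chemo": "gemcitabine",
}


def mentions_for(*canonicals):
    out = []
    pos = 0
    class_of = {v: k for k, v in REPRESENTATIVE.items()}
    for c in canonicals:
        out.append(DrugMention(c, class_of.get(c, "platinum"), pos, pos + len(c), c))
        pos += len(c) + 1
    return out


def oracle_elimination(classes: frozenset, flag: bool) -> TreatmentGroup:
    """Independent brute-force reference: the search stages as a data table
    of set predicates, evaluated in the published elimination order."""
    stages = [
        (TreatmentGroup.TKI, lambda s: "tki" in s),
        (TreatmentGroup.PEM_BEV, lambda s: {"pemetrexed", "bevacizumab"} <= s),
        (TreatmentGroup.PEMETREXED_BASED, lambda s: "pemetrexed" in s),
        (TreatmentGroup.BEVACIZUMAB_BASED, lambda s: "bevacizumab" in s),
        (TreatmentGroup.PLATINUM_DOUBLET, lambda s: {"platinum", "other_chemo"} <= s),
        (TreatmentGroup.SINGLE_AGENT, lambda s: bool(s)),
        (TreatmentGroup.NO_TREATMENT, lambda s: flag),
    ]
    for group, hit in stages:
        if hit(classes):
            return group
    return TreatmentGroup.UNKNOWN


class TestAssignGroup:
    @pytest.mark.parametrize(
        "canonicals, flag, expected",
        [
            (("pemetrexed", "bevacizumab", "carboplatin"), False, TreatmentGroup.PEM_BEV),
            ((), False, TreatmentGroup.UNKNOWN),
            ((), True, TreatmentGroup.NO_TREATMENT),
            (("carboplatin", "gemcitabine"), False, TreatmentGroup.PLATINUM_DOUBLET),
            (("erlotinib", "carboplatin"), False, TreatmentGroup.TKI),
            (("carboplatin", "carboplatin"), False, TreatmentGroup.SINGLE_AGENT),
            (("pemetrexed", "carboplatin"), False, TreatmentGroup.PEMETREXED_BASED),
            (("bevacizumab", "gemcitabine"), False, TreatmentGroup.BEVACIZUMAB_BASED),
        ],
    )
    def test_examples(self, canonicals, flag, expected):
        group, _ = assign_group(mentions_for(*canonicals), flag)
        assert group is expected

    @pytest.mark.parametrize(
        "present, flag",
        list(product(product([False, True], repeat=5), [False, True])),
    )
    def test_matches_elimination_oracle_over_all_class_combinations(self, present, flag):
        """All 2^5 class-presence combinations x no-treatment flag agree with
        an independent transcription of the ordered search stages."""
        classes = [c for c, p in zip(REPRESENTATIVE, present) if p]
        mentions = mentions_for(*(REPRESENTATIVE[c] for c in classes))
        group, _ = assign_group(mentions, flag)
        assert group is oracle_elimination(frozenset(classes), flag)

    def test_strict_mode_multi_drug_non_platinum(self):
        mentions = mentions_for("gemcitabine") + [
            DrugMention("docetaxel", "other_chemo", 50, 59, "docetaxel")
        ]
        assert assign_group(mentions, False, mode="faithful")[0] is TreatmentGroup.SINGLE_AGENT
        assert assign_group(mentions, False, mode="strict")[0] is TreatmentGroup.UNKNOWN

    def test_precedence_soundness_pem_bev(self):
        """pemetrexed + bevacizumab evidence never lands in a lower group."""
        for extra in product([False, True], repeat=2):  # platinum, other_chemo
            canonicals = ["pemetrexed", "bevacizumab"]
            if extra[0]:
                canonicals.append("carboplatin")
            if extra[1]:
                canonicals.append("gemcitabine")
            group, _ = assign_group(mentions_for(*canonicals), False)
            assert group is TreatmentGroup.PEM_BEV

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            assign_group([], False, mode="lenient")


class TestClassifyRecord:
    def test_negated_drug_plus_hospice_is_no_treatment(self, matcher):
        rec = TextRecord("p1", "r1", "not a candidate for erlotinib; patient opted for hospice instead of treatment")
        c = classify_record(rec, matcher)
        assert c.group is TreatmentGroup.NO_TREATMENT
        assert c.rule_fired == "stage7_no_treatment"
        assert all(m.negated for m in c.mentions)

    def test_blank_is_unknown(self, matcher):
        c = classify_record(TextRecord("p1", "r1", ""), matcher)
        assert c.group is TreatmentGroup.UNKNOWN and c.mentions == ()

    def test_brand_abbreviation_combination(self, matcher):
        c = classify_record(TextRecord("p1", "r1", "alimta + avastin + carbo started"), matcher)
        assert c.group is TreatmentGroup.PEM_BEV
        assert c.rule_fired == "stage2_pem_bev"

    def test_uncertain_mention_counts_by_default_but_not_when_excluded(self, matcher):
        rec = TextRecord("p1", "r1", "carboplatin recommended, unknown if given")
        assert classify_record(rec, matcher).group is TreatmentGroup.SINGLE_AGENT
        assert (
            classify_record(rec, matcher, count_uncertain=False).group
            is TreatmentGroup.UNKNOWN
        )

    def test_negating_all_drugs_only_moves_label_down(self, matcher):
        """Negation monotonicity: wrapping every drug in a negation phrase
        can only move a record to no_treatment/unknown."""
        drug_texts = [
            "carboplatin and gemcitabine",
            "alimta + avastin",
            "erlotinib daily",
            "single agent docetaxel",
        ]
        for text in drug_texts:
            base = classify_record(TextRecord("p", "r", text), matcher)
            assert base.group.is_treatment
            drugs = [m.canonical for m in base.mentions]
            negated_text = "; ".join(f"not a candidate for {d}" for d in drugs)
            negated = classify_record(TextRecord("p", "r", negated_text), matcher)
            assert negated.group in (TreatmentGroup.NO_TREATMENT, TreatmentGroup.UNKNOWN)


def rc(record_id, group):
    from firstline.classify import RecordClassification

    return RecordClassification(record_id, group)


class TestClassifyPatient:
    def test_earliest_dated_treatment_wins(self):
        records = [
            TextRecord("p1", "r1", "x", date(2013, 1, 5)),
            TextRecord("p1", "r2", "x", date(2013, 3, 1)),
        ]
        cls = [rc("r1", TreatmentGroup.PLATINUM_DOUBLET), rc("r2", TreatmentGroup.TKI)]
        out = classify_patient(cls, records)
        assert out.group is TreatmentGroup.PLATINUM_DOUBLET
        assert out.source_record_id == "r1"
        assert out.n_records == 2

    def test_no_treatment_beats_unknown(self):
        records = [TextRecord("p1", "r1", ""), TextRecord("p1", "r2", "refused treatment")]
        cls = [rc("r1", TreatmentGroup.UNKNOWN), rc("r2", TreatmentGroup.NO_TREATMENT)]
        out = classify_patient(cls, records)
        assert out.group is TreatmentGroup.NO_TREATMENT
        assert out.source_record_id == "r2"

    def test_treatment_beats_no_treatment_regardless_of_dates(self):
        records = [
            TextRecord("p1", "r1", "x", date(2012, 1, 1)),
            TextRecord("p1", "r2", "x", date(2013, 1, 1)),
        ]
        cls = [rc("r1", TreatmentGroup.NO_TREATMENT), rc("r2", TreatmentGroup.TKI)]
        assert classify_patient(cls, records).group is TreatmentGroup.TKI

    @pytest.mark.parametrize(
        "policy, expected_group, expected_source",
        [
            ("undated-first", TreatmentGroup.TKI, "r1"),
            ("undated-last", TreatmentGroup.PLATINUM_DOUBLET, "r2"),
        ],
    )
    def test_undated_policy_table(self, policy, expected_group, expected_source):
        records = [
            TextRecord("p1", "r1", "x", None),
            TextRecord("p1", "r2", "x", date(2013, 2, 1)),
        ]
        cls = [rc("r1", TreatmentGroup.TKI), rc("r2", TreatmentGroup.PLATINUM_DOUBLET)]
        out = classify_patient(cls, records, date_policy=policy)
        assert out.group is expected_group and out.source_record_id == expected_source

    def test_date_tie_breaks_by_record_id(self):
        d = date(2013, 5, 5)
        records = [TextRecord("p1", "rB", "x", d), TextRecord("p1", "rA", "x", d)]
        cls = [rc("rB", TreatmentGroup.TKI), rc("rA", TreatmentGroup.SINGLE_AGENT)]
        assert classify_patient(cls, records).source_record_id == "rA"

    def test_mixed_patients_rejected(self):
        records = [TextRecord("p1", "r1", "x"), TextRecord("p2", "r2", "x")]
        cls = [rc("r1", TreatmentGroup.TKI), rc("r2", TreatmentGroup.TKI)]
        with pytest.raises(ValueError, match="multiple patients"):
            classify_patient(cls, records)


class TestClassifyCohort:
    def test_one_row_per_patient(self, matcher):
        records = [
            TextRecord("p1", "r1", "carboplatin and taxol"),
            TextRecord("p1", "r2", ""),
            TextRecord("p2", "r3", "tarceva daily"),
        ]
        out = classify_cohort(records, matcher)
        assert [(c.patient_id, c.group) for c in out] == [
            ("p1", TreatmentGroup.PLATINUM_DOUBLET),
            ("p2", TreatmentGroup.TKI),
        ]

    def test_all_blank_cohort_is_unknown(self, matcher):
        records = [TextRecord(f"p{i}", f"r{i}", "") for i in range(5)]
        out = classify_cohort(records, matcher)
        assert all(c.group is TreatmentGroup.UNKNOWN for c in out)

    def test_duplicate_record_id_rejected(self, matcher):
        records = [TextRecord("p1", "r1", ""), TextRecord("p2", "r1", "")]
        with pytest.raises(ValueError, match="duplicate record_id"):
            classify_cohort(records, matcher)

    def test_order_invariance(self, matcher):
        records = [
            TextRecord("p1", "r1", "alimta", date(2013, 1, 1)),
            TextRecord("p1", "r2", "tarceva", date(2012, 6, 1)),
            TextRecord("p2", "r3", "refused treatment"),
            TextRecord("p3", "r4", ""),
        ]
        forward = classify_cohort(records, matcher)
        backward = classify_cohort(list(reversed(records)), matcher)
        assert forward == backward

    def test_partition_counts_sum_to_patients(self, clf):
        from firstline.simulate import SimulationConfig, generate_corpus

        corpus = generate_corpus(SimulationConfig(n_patients=120, seed=11))
        out = clf.predict_patients(list(corpus.records))
        assert len(out) == 120
        assert len({c.patient_id for c in out}) == 120
        from collections import Counter

        counts = Counter(c.group for c in out)
        assert sum(counts.values()) == 120


class TestEstimatorApi:
    def test_predict_requires_fit(self):
        with pytest.raises(AttributeError, match="not fitted"):
            FirstLineClassifier().predict(["carboplatin"])

    def test_get_set_params_and_clone(self):
        clf = FirstLineClassifier(mode="strict", negation_window=25)
        params = clf.get_params()
        assert params["mode"] == "strict" and params["negation_window"] == 25
        cloned = clone(clf)
        assert cloned.get_params() == params
        cloned.set_params(mode="faithful").fit()
        assert cloned.mode == "faithful"

    def test_invalid_params_rejected_at_fit(self):
        with pytest.raises(ValueError):
            FirstLineClassifier(mode="bogus").fit()
        with pytest.raises(ValueError):
            FirstLineClassifier(negation_window=-1).fit()

    def test_predict_labels_are_class_values(self, clf):
        labels = clf.predict(["cisplatin + etoposide", "", "no treatment given"])
        assert list(labels) == ["platinum_doublet", "unknown", "no_treatment"]
        assert set(clf.classes_) >= set(labels)
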