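"""Confusion counts, precision/recall/F1, kappa, consensus adjudication."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from fracsurv.corpus import Label, LabelRecord, LabelSource
from fracsurv.evaluation import (
    ConfusionCounts,
    cohens_kappa,
    confusion_counts,
    consensus_labels,
    display_round,
    labels_to_dict,
    metrics,
    overall_f1,
)

A, N = Label.affirmed, Label.not_affirmed


def lab(d: dict[str, Label], source=LabelSource.gold):
    return [LabelRecord(k, source, v) for k, v in d.items()]


class TestConfusionCounts:
    def test_identity_prediction(self):
        gold = {f"r{i}": (A if i < 4 else N) for i in range(10)}
        cc = confusion_counts(gold, gold)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (4, 6, 0, 0)

    def test_degenerate_all_negative_predictor(self):
        gold = {f"r{i}": (A if i < 3 else N) for i in range(8)}
        pred = {k: N for k in gold}
        cc = confusion_counts(pred, gold)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (0, 5, 0, 3)

    def test_hand_enumerated_fixture(self):
        pred = {f"r{i}": v for i, v in enumerate([A, A, N, N, A, N, A, N, A, N, N, A])}
        gold = {f"r{i}": v for i, v in enumerate([A, N, N, A, A, N, N, N, A, A, N, A])}
        # brute-force enumeration over the 12 pairs
        tp = sum(pred[k] is A and gold[k] is A for k in pred)
        tn = sum(pred[k] is N and gold[k] is N for k in pred)
        fp = sum(pred[k] is A and gold[k] is N for k in pred)
        fn = sum(pred[k] is N and gold[k] is A for k in pred)
        cc = confusion_counts(pred, gold)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (tp, tn, fp, fn) == (4, 4, 2, 2)

    def test_mismatched_id_sets_rejected_with_difference(self):
        with pytest.raises(ValueError, match="only in"):
            confusion_counts({"a": A}, {"b": A})

    def test_swap_exchanges_fp_fn_and_precision_recall(self):
        pred = {f"r{i}": v for i, v in enumerate([A, A, N, A, N, N])}
        gold = {f"r{i}": v for i, v in enumerate([A, N, N, N, A, A])}
        cc, cs = confusion_counts(pred, gold), confusion_counts(gold, pred)
        assert (cc.fp, cc.fn) == (cs.fn, cs.fp)
        m, ms = metrics(cc), metrics(cs)
        assert m.precision == ms.recall and m.recall == ms.precision
        assert m.f1 == pytest.approx(ms.f1)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            # printed performance-table rows (2 d.p. display)
            ((263, 606, 54, 60), (0.83, 0.81, 0.82)),
            ((177, 364, 55, 55), (0.76, 0.76, 0.76)),
        ],
    )
    def test_reference_rows_two_decimals(self, counts, expected):
        m = metrics(ConfusionCounts(*counts))
        assert (
            display_round(m.precision),
            display_round(m.recall),
            display_round(m.f1),
        ) == expected

    def test_perfect_prediction(self):
        m = metrics(ConfusionCounts(7, 13, 0, 0))
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_undefined_is_explicit_not_zero(self):
        m = metrics(ConfusionCounts(0, 5, 0, 3))  # no predicted positives
        assert m.precision is None and not m.defined

    def test_f1_between_min_and_arithmetic_mean(self):
        m = metrics(ConfusionCounts(50, 100, 30, 10))
        assert min(m.precision, m.recall) <= m.f1 <= (m.precision + m.recall) / 2


class TestKappa:
    def test_identical_vectors(self):
        labels = {f"r{i}": (A if i % 3 else N) for i in range(9)}
        assert cohens_kappa(labels, labels).kappa == 1.0

    def test_perfect_disagreement_balanced(self):
        a = {f"r{i}": (A if i < 5 else N) for i in range(10)}
        b = {k: (N if v is A else A) for k, v in a.items()}
        assert cohens_kappa(a, b).kappa == pytest.approx(-1.0)

    def test_hand_computed_2x2_table(self):
        # table (both affirmed, a-only, b-only, both not) = (40, 5, 10, 45):
        # p_o = 0.85, p_e = 0.45*0.5 + 0.55*0.5 = 0.5, kappa = 0.35/0.5 = 0.7
        a, b = {}, {}
        i = 0
        for n, (la, lb) in [(40, (A, A)), (5, (A, N)), (10, (N, A)), (45, (N, N))]:
            for _ in range(n):
                a[f"r{i}"], b[f"r{i}"] = la, lb
                i += 1
        res = cohens_kappa(a, b)
        assert res.observed_agreement == pytest.approx(0.85)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.7)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(5)
        a = {f"r{i}": (A if x < 0.4 else N) for i, x in enumerate(rng.random(200))}
        b = {
            f"r{i}": (a[f"r{i}"] if x < 0.8 else (N if a[f"r{i}"] is A else A))
            for i, x in enumerate(rng.random(200))
        }
        ours = cohens_kappa(a, b).kappa
        ids = sorted(a)
        ref = cohen_kappa_score(
            [a[i].value for i in ids], [b[i].value for i in ids]
        )
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_symmetry(self):
        a = {f"r{i}": (A if i % 2 else N) for i in range(20)}
        b = {f"r{i}": (A if i % 3 else N) for i in range(20)}
        assert cohens_kappa(a, b).kappa == pytest.approx(cohens_kappa(b, a).kappa)

    def test_independent_raters_have_near_zero_mean_kappa(self):
        rng = np.random.default_rng(42)
        kappas = []
        for _ in range(300):
            a = {f"r{i}": (A if x < 0.35 else N) for i, x in enumerate(rng.random(60))}
            b = {f"r{i}": (A if x < 0.35 else N) for i, x in enumerate(rng.random(60))}
            kappas.append(cohens_kappa(a, b).kappa)
        # mean over replicates ~ Normal(0, sd/sqrt(300))
        assert abs(np.mean(kappas)) < 4 * np.std(kappas) / np.sqrt(len(kappas))


class TestConsensus:
    def test_full_agreement_passes_through(self):
        a = {f"r{i}": (A if i % 2 else N) for i in range(6)}
        out = consensus_labels(a, dict(a), {})
        assert {o.report_id: o.label for o in out} == a
        assert all(o.source is LabelSource.consensus for o in out)

    def test_adjudicator_decides_disagreements(self):
        a = {"r0": A, "r1": N, "r2": A}
        b = {"r0": A, "r1": A, "r2": A}
        out = consensus_labels(a, b, {"r1": A})
        assert {o.report_id: o.label for o in out} == {"r0": A, "r1": A, "r2": A}

    def test_hand_merged_20_report_fixture(self):
        rng = np.random.default_rng(9)
        a = {f"r{i:02d}": (A if x < 0.5 else N) for i, x in enumerate(rng.random(20))}
        b = dict(a)
        flipped = ["r03", "r07", "r11", "r15"]
        for rid in flipped:
            b[rid] = N if a[rid] is A else A
        adjudicator = {rid: A for rid in flipped}
        out = {o.report_id: o.label for o in consensus_labels(a, b, adjudicator)}
        expected = {rid: (adjudicator[rid] if rid in adjudicator else a[rid]) for rid in a}
        assert out == expected

    def test_adjudicator_set_must_match_exactly(self):
        a, b = {"r0": A, "r1": N}, {"r0": A, "r1": A}
        with pytest.raises(ValueError):
            consensus_labels(a, b, {})  # missing the disagreement
        with pytest.raises(ValueError):
            consensus_labels(a, b, {"r0": A, "r1": A})  # labels an agreement


class TestOverallF1:
    def test_mean_of_reference_years_displays_081(self):
        assert overall_f1([0.82, 0.79]) == pytest.approx(0.805)
        assert display_round(overall_f1([0.82, 0.79])) == 0.81

    @pytest.mark.parametrize("values,expected", [([0.5], 0.5), ([1.0, 1.0, 1.0], 1.0)])
    def test_trivial_means(self, values, expected):
        assert overall_f1(values) == expected

    def test_labels_to_dict_rejects_duplicates(self):
        recs = lab({"a": A}) + lab({"a": N})
        with pytest.raises(ValueError):
            labels_to_dict(recs)
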