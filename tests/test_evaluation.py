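"""PPV/recall/specificity, two-point AUROC, implied-AUROC reconstruction, FP breakdown."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from fallsift.annotation import BinaryLabel, Category, GoldAnnotation
from fallsift.evaluation import (
    EvaluationError,
    evaluate,
    fp_breakdown,
    implied_auroc,
    reconstruct_reported_auroc,
    round_half_away,
)
from fallsift.records import Label


def labels(bits, prefix="n"):
    return [
        BinaryLabel(f"{prefix}{i}", Label.POSITIVE if b else Label.NEGATIVE)
        for i, b in enumerate(bits)
    ]


class TestEvaluate:
    def test_perfect_predictions(self):
        gold = labels([1, 1, 0, 0])
        report = evaluate(gold, gold)
        assert report.precision == report.recall == report.auroc == 1.0

    def test_all_positive_predictions_auroc_half(self):
        gold = labels([1, 1, 0, 0])
        preds = labels([1, 1, 1, 1])
        assert evaluate(preds, gold).auroc == 0.5

    def test_auroc_is_balanced_accuracy_identity(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(4, 40))
            g = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if g.sum() in (0, n):
                continue
            report = evaluate(labels(p), labels(g))
            assert report.auroc == (report.recall + report.specificity) / 2

    def test_auroc_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            n = int(rng.integers(4, 30))
            g = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if g.sum() in (0, n):
                continue
            report = evaluate(labels(p), labels(g))
            # brute force over all (positive, negative) gold pairs: score 1
            # for a concordant pair, 0.5 for a tie
            pos_scores = p[g == 1]
            neg_scores = p[g == 0]
            conc = sum(
                1.0 if ps > ns else 0.5 if ps == ns else 0.0
                for ps in pos_scores
                for ns in neg_scores
            ) / (len(pos_scores) * len(neg_scores))
            assert report.auroc == pytest.approx(conc)
            assert report.auroc == pytest.approx(roc_auc_score(g, p))

    def test_order_invariance(self):
        gold = labels([1, 0, 1, 0, 0])
        preds = labels([1, 1, 0, 0, 0])
        shuffled = list(reversed(preds))
        assert evaluate(preds, gold) == evaluate(shuffled, gold)

    def test_no_gold_positives_signalled(self):
        with pytest.raises(EvaluationError, match="recall undefined"):
            evaluate(labels([0, 0]), labels([0, 0]))

    def test_mismatched_note_sets_rejected(self):
        with pytest.raises(EvaluationError):
            evaluate(labels([1], prefix="a"), labels([1], prefix="b"))


class TestImpliedAuroc:
    def test_internal_table_row(self):
        assert round_half_away(implied_auroc(0.72, 0.90, 260, 340)) == 0.82

    def test_external_table_row(self):
        assert round_half_away(implied_auroc(0.93, 0.94, 120, 80)) == 0.92

    def test_perfect_classifier(self):
        assert implied_auroc(1.0, 1.0, 50, 50) == 1.0

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(EvaluationError, match="infeasible"):
            implied_auroc(0.10, 1.0, 500, 10)

    def test_round_trip_with_evaluate(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            n = int(rng.integers(6, 50))
            g = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            report_ok = g.sum() not in (0, n) and (p & g).sum() > 0
            if not report_ok:
                continue
            report = evaluate(labels(p), labels(g))
            implied = implied_auroc(
                report.precision, report.recall, int(g.sum()), int(n - g.sum())
            )
            assert implied == pytest.approx(report.auroc)

    def test_eight_of_twelve_published_rows_reconstruct(self):
        rows = reconstruct_reported_auroc()
        assert sum(r["matches_printed"] for r in rows) == 8


class TestFpBreakdown:
    def test_error_analysis_proportions(self):
        # 20 false positives: 17 historical, 2 miscellaneous, 1 fall risk
        cats = (
            [Category.HISTORY_OF_FALLS] * 17
            + [Category.OTHER_MENTION] * 2
            + [Category.FALL_RISK]
        )
        anns = [GoldAnnotation(f"n{i}", c, "gold") for i, c in enumerate(cats)]
        preds = labels([1] * 20)
        out = fp_breakdown(preds, anns)
        assert out["history_of_falls"] == (17, pytest.approx(0.85))
        assert out["other_mention"] == (2, pytest.approx(0.10))
        assert out["fall_risk"] == (1, pytest.approx(0.05))

    def test_no_false_positives_empty(self):
        anns = [GoldAnnotation("n0", Category.FALL_EVENT, "gold")]
        assert fp_breakdown(labels([1]), anns) == {}

    def test_counts_equal_groupby_oracle(self):
        rng = np.random.default_rng(15)
        cats = list(Category)
        anns = [
            GoldAnnotation(f"n{i}", cats[int(rng.integers(5))], "gold") for i in range(80)
        ]
        preds = labels(rng.integers(0, 2, 80))
        out = fp_breakdown(preds, anns)
        by_note = {a.note_id: a.category for a in anns}
        expected: dict[str, int] = {}
        for p in preds:
            cat = by_note[p.note_id]
            if p.label is Label.POSITIVE and cat is not Category.FALL_EVENT:
                expected[cat.value] = expected.get(cat.value, 0) + 1
        assert {k: v[0] for k, v in out.items()} == expected

    def test_missing_annotation_for_fp_is_error(self):
        anns = [GoldAnnotation("n0", Category.NO_FALL, "gold")]
        with pytest.raises(EvaluationError, match="n1"):
            fp_breakdown(labels([1, 1]), anns)
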