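import math

import numpy as np
import pandas as pd
import pytest

from sonohcc.diagstats import (
    ContingencyTable2x2,
    build_contingency,
    chi_square_test,
    cohen_kappa,
    diagnostic_performance,
    feature_frequency_table,
    fisher_exact_test,
    round_half_up,
)
from sonohcc.modality import ModalityCall


class TestBuildContingency:
    def test_all_correct(self):
        calls = ["malignant"] * 3 + ["benign"] * 2
        t = build_contingency(calls, calls)
        assert (t.fp, t.fn) == (0, 0)
        assert (t.tp, t.tn) == (3, 2)

    def test_accepts_modality_calls(self):
        calls = [ModalityCall("multimodal", "malignant"), ModalityCall("multimodal", "benign")]
        t = build_contingency(calls, ["benign", "benign"])
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 1, 0, 1)

    def test_random_labels_match_bruteforce_tally(self, rng):
        calls = list(rng.choice(["benign", "malignant"], size=200))
        truth = list(rng.choice(["benign", "malignant"], size=200))
        t = build_contingency(calls, truth)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for c, g in zip(calls, truth):
            key = ("t" if c == g else "f") + ("p" if c == "malignant" else "n")
            tally[key] += 1
        assert (t.tp, t.fp, t.fn, t.tn) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"],
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(["benign"], ["benign", "malignant"])


class TestDiagnosticPerformance:
    def test_multimodal_cells(self):
        s = diagnostic_performance(ContingencyTable2x2(24, 1, 3, 10))
        assert s.specificity == 90.91
        assert s.accuracy == 89.47
        assert s.sensitivity == 88.89

    def test_elastography_cells(self):
        s = diagnostic_performance(ContingencyTable2x2(16, 3, 10, 7))
        assert (s.sensitivity, s.specificity, s.accuracy) == (61.54, 70.00, 63.89)

    def test_perfect_table(self):
        s = diagnostic_performance(ContingencyTable2x2(7, 0, 0, 7))
        assert (s.sensitivity, s.specificity, s.accuracy) == (100.0, 100.0, 100.0)

    def test_accuracy_times_total_equals_tp_plus_tn(self, rng):
        for _ in range(30):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + fp + fn + tn == 0:
                continue
            t = ContingencyTable2x2(tp, fp, fn, tn)
            s = diagnostic_performance(t)
            assert s.raw_accuracy * t.total == pytest.approx(tp + tn)

    def test_undefined_statistics_flagged(self):
        s = diagnostic_performance(ContingencyTable2x2(0, 3, 0, 5))
        assert s.sensitivity is None
        assert s.specificity is not None


class TestCohenKappa:
    def test_perfect_agreement(self):
        kappa, band = cohen_kappa(ContingencyTable2x2(5, 0, 0, 5))
        assert kappa == pytest.approx(1.0)
        assert band == "satisfactory"

    def test_chance_level_agreement(self):
        kappa, band = cohen_kappa(ContingencyTable2x2(25, 25, 25, 25))
        assert kappa == pytest.approx(0.0)
        assert band == "poor"

    def test_multimodal_cells_hand_computation(self):
        # p_o = 34/38, p_e = (25*27 + 13*11)/38^2 = 818/1444, kappa = 474/626
        kappa, band = cohen_kappa(ContingencyTable2x2(24, 1, 3, 10))
        assert kappa == pytest.approx(474 / 626)
        assert band == "satisfactory"

    def test_matches_sklearn_on_random_tables(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 30, size=4))
            t = ContingencyTable2x2(tp, fp, fn, tn)
            rater_a = [1] * (tp + fp) + [0] * (fn + tn)
            rater_b = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            kappa, _ = cohen_kappa(t)
            assert kappa == pytest.approx(cohen_kappa_score(rater_a, rater_b))

    def test_degenerate_margins_undefined(self):
        kappa, band = cohen_kappa(ContingencyTable2x2(10, 0, 0, 0))
        assert kappa is None and band is None

    def test_transposition_invariance(self, rng):
        for _ in range(10):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 30, size=4))
            k1, _ = cohen_kappa(ContingencyTable2x2(tp, fp, fn, tn))
            k2, _ = cohen_kappa(ContingencyTable2x2(tp, fn, fp, tn))
            assert k1 == pytest.approx(k2)


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        stat, p, _ = chi_square_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_observed_expected_oracle(self, rng):
        for _ in range(20):
            grid = rng.integers(1, 40, size=(2, 3)).astype(float)
            stat, _, expected = chi_square_test(grid)
            oracle = 0.0
            row, col, total = grid.sum(1), grid.sum(0), grid.sum()
            for i in range(2):
                for j in range(3):
                    e = row[i] * col[j] / total
                    oracle += (grid[i, j] - e) ** 2 / e
            assert stat == pytest.approx(oracle, abs=1e-10)
            assert expected == pytest.approx(np.outer(row, col) / total)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 3]])


class TestFisherExact:
    def test_degenerate_table(self):
        assert fisher_exact_test(ContingencyTable2x2(0, 0, 0, 9)) == pytest.approx(1.0)

    def test_five_zero_zero_five_full_enumeration(self):
        # margins (5,5)x(5,5): P(a) = C(5,a) C(5,5-a) / C(10,5); two-sided p
        # sums tables with probability <= P(a=5) = 1/252, i.e. a in {0, 5}.
        p = fisher_exact_test(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252)

    def test_row_swap_symmetry(self, rng):
        for _ in range(10):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 15, size=4))
            p1 = fisher_exact_test(ContingencyTable2x2(tp, fp, fn, tn))
            p2 = fisher_exact_test(ContingencyTable2x2(fn, tn, tp, fp))
            assert p1 == pytest.approx(p2)

    def test_matches_hypergeometric_enumeration(self, rng):
        from math import comb

        for _ in range(10):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 10, size=4))
            n = tp + fp + fn + tn
            if n == 0:
                continue
            r1, c1 = tp + fp, tp + fn
            denom = comb(n, c1)
            def prob(a):
                b = r1 - a
                if b < 0 or a > c1 or (c1 - a) > n - r1:
                    return 0.0
                return comb(r1, a) * comb(n - r1, c1 - a) / denom
            p_obs = prob(tp)
            enumerated = sum(
                prob(a) for a in range(0, min(r1, c1) + 1) if prob(a) <= p_obs * (1 + 1e-9)
            )
            assert fisher_exact_test(ContingencyTable2x2(tp, fp, fn, tn)) == pytest.approx(
                enumerated
            )


class TestFeatureFrequencies:
    def _frame(self, rows):
        cols = [
            "pathology", "grade", "shape", "boundary", "internal_echo",
            "posterior_echo", "flow_grade", "elasticity_score", "ceus_pattern",
        ]
        return pd.DataFrame(rows, columns=cols)

    def test_single_lesion_is_100_percent(self):
        frame = self._frame(
            [("malignant", "poor", "irregular", "unclear", "inhomogeneous",
              "unchanged_or_enhanced", 3, 5, "FFFO")]
        )
        table = feature_frequency_table(frame)
        assert (table["percent"] == 100.0).all()
        assert (table["n_lesions"] == 1).all()

    def test_binary_attribute_percentages_complement(self):
        frame = self._frame(
            [
                ("malignant", "poor", "irregular", "clear", "homogeneous",
                 "attenuated", 0, 1, "other"),
                ("malignant", "poor", "regular", "unclear", "inhomogeneous",
                 "unchanged_or_enhanced", 3, 5, "FFFO"),
            ]
        )
        table = feature_frequency_table(frame).set_index("feature")
        assert table.loc["shape=irregular", "percent"] == 50.0
        assert table.loc["boundary=unclear", "percent"] == 50.0

    def test_ungraded_malignant_rejected(self):
        frame = self._frame(
            [("malignant", None, "irregular", "unclear", "inhomogeneous",
              "unchanged_or_enhanced", 3, 5, "FFFO")]
        )
        with pytest.raises(ValueError):
            feature_frequency_table(frame)


def test_round_half_up_matches_printed_convention():
    assert round_half_up(89.465) == 89.47
    assert round_half_up(0.125, 2) == 0.13
    assert math.isclose(round_half_up(61.538461 * 1, 2), 61.54)
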