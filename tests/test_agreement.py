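"""Confusion matrices, Cohen's kappa (incl. weighted) and agreement reports."""

import numpy as np
import pandas as pd
import pytest

from fibroscore.agreement import (
    ConfusionMatrix,
    agreement_report,
    cohen_kappa,
    confusion_matrix,
    lins_ccc,
)


def brute_force_kappa(counts, weighting="none"):
    """Independent double-loop oracle for p_o / p_e and kappa."""
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    n = counts.sum()
    if weighting == "none":
        w = [[0.0 if i == j else 1.0 for j in range(k)] for i in range(k)]
    elif weighting == "linear":
        w = [[abs(i - j) / (k - 1) for j in range(k)] for i in range(k)]
    else:
        w = [[(abs(i - j) / (k - 1)) ** 2 for j in range(k)] for i in range(k)]
    p_o = 1.0
    p_e = 1.0
    for i in range(k):
        for j in range(k):
            p_o -= w[i][j] * counts[i, j] / n
            p_e -= w[i][j] * (counts[i].sum() / n) * (counts[:, j].sum() / n)
    if abs(1 - p_e) < 1e-15:
        return (1.0 if abs(1 - p_o) < 1e-15 else 0.0), p_o, p_e
    return (p_o - p_e) / (1 - p_e), p_o, p_e


class TestConfusionMatrix:
    def test_diagonal_tally(self):
        cm = confusion_matrix([0, 0, 8, 8], [0, 0, 8, 8], class_order=(0, 8))
        assert (cm.counts == np.diag([2, 2])).all()
        assert cm.n == 4

    def test_anti_diagonal(self):
        cm = confusion_matrix([0, 8], [8, 0], class_order=(0, 8))
        assert (cm.counts == np.array([[0, 1], [1, 0]])).all()

    def test_marginals_match_reference_counts_random(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            ref = rng.integers(0, 9, size=n)
            pred = rng.integers(0, 9, size=n)
            cm = confusion_matrix(list(ref), list(pred), class_order=tuple(range(9)))
            for g in range(9):
                assert cm.counts[g].sum() == (ref == g).sum()
                assert cm.counts[:, g].sum() == (pred == g).sum()

    def test_length_mismatch_and_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], class_order=(0, 1))
        with pytest.raises(ValueError):
            confusion_matrix([0, 7], [0, 7], class_order=(0, 1))


class TestCohenKappa:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([5, 5]), (0, 1))
        assert cohen_kappa(cm).kappa == pytest.approx(1.0)

    def test_chance_level_single_column(self):
        cm = ConfusionMatrix(np.array([[5, 0], [5, 0]]), (0, 1))
        res = cohen_kappa(cm)
        assert res.p_o == pytest.approx(0.5)
        assert res.p_e == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.0)

    def test_hand_computed_example(self):
        cm = ConfusionMatrix(np.array([[20, 5], [10, 15]]), (0, 1))
        res = cohen_kappa(cm)
        assert res.p_o == pytest.approx(0.7)
        assert res.p_e == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.4)

    @pytest.mark.parametrize("weighting", ["none", "linear", "quadratic"])
    def test_matches_brute_force_oracle_on_random_matrices(self, weighting):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            k = int(rng.integers(2, 10))
            counts = rng.integers(0, 20, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts, tuple(range(k)))
            res = cohen_kappa(cm, weighting)
            expect, p_o, p_e = brute_force_kappa(counts, weighting)
            assert abs(res.kappa - expect) < 1e-12
            assert abs(res.p_o - p_o) < 1e-12
            assert abs(res.p_e - p_e) < 1e-12

    def test_matches_sklearn_cross_check(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        for weighting, skw in (("none", None), ("linear", "linear"), ("quadratic", "quadratic")):
            ref = rng.integers(0, 5, size=200)
            pred = rng.integers(0, 5, size=200)
            cm = confusion_matrix(list(ref), list(pred), class_order=tuple(range(5)))
            ours = cohen_kappa(cm, weighting).kappa
            theirs = sklearn_metrics.cohen_kappa_score(ref, pred, weights=skw)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_bounded_and_permutation_invariant(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 15, size=(6, 6))
        counts[0, 0] += 1
        cm = ConfusionMatrix(counts, tuple(range(6)))
        k0 = cohen_kappa(cm).kappa
        assert -1.0 <= k0 <= 1.0
        perm = rng.permutation(6)
        cm_p = ConfusionMatrix(counts[np.ix_(perm, perm)], tuple(range(6)))
        assert cohen_kappa(cm_p).kappa == pytest.approx(k0, abs=1e-12)

    def test_two_class_linear_equals_unweighted(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(2, 2))
            counts[0, 0] += 1
            cm = ConfusionMatrix(counts, (0, 1))
            assert cohen_kappa(cm, "linear").kappa == pytest.approx(
                cohen_kappa(cm, "none").kappa, abs=1e-12
            )

    def test_degenerate_single_cell_flagged(self):
        cm = ConfusionMatrix(np.array([[7]]), (0,))
        res = cohen_kappa(cm)
        assert res.degenerate and res.kappa == 1.0


class TestAgreementReport:
    def _tile_table(self, labels):
        return pd.DataFrame(
            [
                {"ident": "s1", "row": i // 3, "col": i % 3, "label": lab}
                for i, lab in enumerate(labels)
            ]
        )

    def test_identical_tables_perfect_agreement(self):
        t = self._tile_table([0, 1, 2, 3, 4, 5])
        rep = agreement_report(t, t, level="tile")
        assert rep["kappa_none"]["kappa"] == pytest.approx(1.0)

    def test_constant_shift_reduces_kappa(self):
        man = pd.DataFrame({"ident": [f"m{i}" for i in range(8)], "score": np.arange(8) * 1.0})
        auto = pd.DataFrame({"ident": [f"m{i}" for i in range(8)], "score": np.arange(8) + 1.0})
        rep = agreement_report(man, auto, level="section")
        assert rep["kappa_none"]["kappa"] < 1.0
        assert rep["concordance_ccc"] < 1.0

    def test_section_level_rounding_and_ccc(self):
        man = pd.DataFrame({"ident": ["a", "b"], "score": [2.4, 6.5]})
        auto = pd.DataFrame({"ident": ["a", "b"], "score": [2.2, 6.6]})
        rep = agreement_report(man, auto, level="section")
        # 2.4->2, 6.5->7 (half-up) vs 2.2->2, 6.6->7: perfect after rounding
        assert rep["kappa_none"]["kappa"] == pytest.approx(1.0)
        assert 0 < rep["concordance_ccc"] <= 1.0

    def test_unmatched_idents_dropped_and_counted(self, caplog):
        man = self._tile_table([0, 1, 2])
        auto = self._tile_table([0, 1, 2, 3])
        with caplog.at_level("WARNING"):
            rep = agreement_report(man, auto, level="tile")
        assert rep["n_matched"] == 3
        assert rep["n_unmatched"] == 1

    def test_non_alveolar_excluded_by_default(self):
        man = self._tile_table([0, 1, "NA"])
        auto = self._tile_table([0, 1, "NA"])
        rep = agreement_report(man, auto, level="tile")
        assert sum(sum(r) for r in rep["confusion_matrix"]) == 2
        rep_inc = agreement_report(man, auto, level="tile", include_non_alveolar=True)
        assert sum(sum(r) for r in rep_inc["confusion_matrix"]) == 3

    def test_no_matches_rejected(self):
        man = pd.DataFrame({"ident": ["a"], "score": [1.0]})
        auto = pd.DataFrame({"ident": ["b"], "score": [1.0]})
        with pytest.raises(ValueError):
            agreement_report(man, auto, level="section")


class TestLinsCCC:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert lins_ccc(x, x) == pytest.approx(1.0)

    def test_shifted_below_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert lins_ccc(x, x + 1.0) < 1.0
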