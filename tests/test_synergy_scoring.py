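import itertools
import math

import numpy as np
import pandas as pd
import pytest

from combiscore import (
    DesignError,
    MonotherapyCurve,
    SimSpec,
    SynergyResult,
    bliss_cell,
    consensus_label,
    evaluate_s_scores,
    hsa_cell,
    loewe_cell,
    matrix_synergy,
    s_scores,
    score_block,
    simulate_matrix_grid,
    ss_prioritize,
    zip_cell,
)
from combiscore.synergy_scoring import (
    ANTAGONISTIC,
    NON_INTERACTIVE,
    SYNERGISTIC,
    fit_matrix_monotherapies,
)

from conftest import matrix_from_grid


def flat_mono(value, conc_range=(-2.0, 2.0)):
    """Monotherapy curve constant at `value` (b -> 0 limit, a = 2 * value)."""
    return MonotherapyCurve(a=2.0 * value, b=0.0, c=0.0, conc_range=conc_range)


def make_result(block_id, s_sum=0.0, consensus=NON_INTERACTIVE, css=50.0, **kw):
    return SynergyResult(
        block_id=block_id, s_sum=s_sum, s_max=kw.get("s_max", s_sum),
        s_mean=kw.get("s_mean", s_sum), auc1_pct=0.0, auc2_pct=0.0,
        hsa=0.0, bliss=0.0, loewe=0.0, zip_score=0.0,
        consensus=consensus, css=css)


class TestSScores:
    def test_arithmetic(self):
        # normalized monotherapy AUCs of 30 and 20 via constant curves:
        # constant 0.37 -> (0.37 - 0.1)/0.9 = 0.30; constant 0.28 -> 0.20
        mono1, mono2 = flat_mono(0.37), flat_mono(0.28)
        s_sum, s_max, s_mean = s_scores(60.0, mono1, mono2, inh_min=0.10)
        assert s_sum == pytest.approx(10.0, abs=1e-9)
        assert s_max == pytest.approx(30.0, abs=1e-9)
        assert s_mean == pytest.approx(35.0, abs=1e-9)

    def test_zero_monotherapy_aucs(self):
        mono = flat_mono(0.0)
        assert s_scores(42.0, mono, mono) == pytest.approx((42.0, 42.0, 42.0))

    def test_additivity_boundary(self):
        mono = flat_mono(0.325)  # normalized AUC 25
        s_sum, s_max, s_mean = s_scores(50.0, mono, mono)
        assert s_sum == pytest.approx(0.0, abs=1e-9)
        assert s_max == pytest.approx(25.0, abs=1e-9)
        assert s_mean == pytest.approx(25.0, abs=1e-9)

    def test_ordering_invariant(self, rng):
        for _ in range(50):
            mono1 = flat_mono(rng.uniform(0, 0.5))
            mono2 = flat_mono(rng.uniform(0, 0.5))
            css = rng.uniform(0, 100)
            s_sum, s_max, s_mean = s_scores(css, mono1, mono2)
            assert s_sum <= s_max + 1e-12
            assert s_max <= s_mean + 1e-12


class TestCellScores:
    @pytest.mark.parametrize("args,expected", [
        ((0.6, 0.5, 0.3), 0.1), ((0.5, 0.5, 0.2), 0.0), ((0.2, 0.5, 0.3), -0.3)])
    def test_hsa(self, args, expected):
        assert hsa_cell(*args) == pytest.approx(expected)

    @pytest.mark.parametrize("args,expected", [
        ((0.75, 0.5, 0.5), 0.0), ((0.5, 0.2, 0.3), 0.06), ((0.4, 0.0, 0.0), 0.4)])
    def test_bliss(self, args, expected):
        assert bliss_cell(*args) == pytest.approx(expected)

    def test_loewe_self_combination(self):
        mono = MonotherapyCurve(a=0.9, b=1.0, c=0.0, conc_range=(-2, 2))
        x1, x2 = 0.5, 0.5
        y_c = float(mono.predict_conc(x1 + x2))
        assert loewe_cell(y_c, x1, x2, mono, mono) == pytest.approx(0.0, abs=1e-12)

    def test_loewe_flat_zero_monotherapies(self):
        mono = flat_mono(0.0)
        assert loewe_cell(0.33, 1.0, 2.0, mono, mono) == pytest.approx(0.33)

    def test_loewe_label_swap_symmetry(self):
        mono1 = MonotherapyCurve(a=0.8, b=1.5, c=0.2, conc_range=(-2, 2))
        mono2 = MonotherapyCurve(a=0.6, b=0.7, c=-0.3, conc_range=(-2, 2))
        for x1, x2, y_c in [(0.1, 2.0, 0.5), (1.0, 1.0, 0.7), (5.0, 0.2, 0.2)]:
            assert loewe_cell(y_c, x1, x2, mono1, mono2) == pytest.approx(
                loewe_cell(y_c, x2, x1, mono2, mono1), abs=1e-12)

    def test_cell_scores_shift_with_y_c(self):
        mono1 = MonotherapyCurve(a=0.8, b=1.0, c=0.0, conc_range=(-2, 2))
        delta = 0.07
        for y_c in (0.2, 0.5):
            assert hsa_cell(y_c + delta, 0.3, 0.4) - hsa_cell(y_c, 0.3, 0.4) \
                == pytest.approx(delta)
            assert bliss_cell(y_c + delta, 0.3, 0.4) - bliss_cell(y_c, 0.3, 0.4) \
                == pytest.approx(delta)
            assert loewe_cell(y_c + delta, 1.0, 1.0, mono1, mono1) \
                - loewe_cell(y_c, 1.0, 1.0, mono1, mono1) == pytest.approx(delta)


class TestZip:
    def test_bliss_matrix_zip_near_zero(self):
        spec = SimSpec(noise_sd=0.0, n_replicates=1)
        matrix = simulate_matrix_grid(spec)
        mono1, mono2 = fit_matrix_monotherapies(matrix)
        for x1, x2 in [(0.01, 1.0), (1.0, 1.0), (100.0, 0.1)]:
            assert abs(zip_cell(matrix, mono1, mono2, (x1, x2))) < 1e-3

    def test_uniform_potentiation_recovered(self):
        # sub-maximal monotherapies keep bliss + 0.1 away from the [0,1] clip
        spec = SimSpec(mono1=(0.5, 1.0, 0.0), mono2=(0.5, 1.0, 0.0),
                       noise_sd=0.0, n_replicates=1, delta=0.1)
        matrix = simulate_matrix_grid(spec)
        refs = matrix_synergy(matrix)
        assert refs.zip_score == pytest.approx(10.0, abs=0.01)

    def test_all_zero_matrix(self):
        concs = [0.0, 0.1, 1.0, 10.0]
        matrix = matrix_from_grid(concs, concs, np.zeros((4, 4)))
        mono1, mono2 = fit_matrix_monotherapies(matrix)
        assert zip_cell(matrix, mono1, mono2, (1.0, 1.0)) == pytest.approx(0.0, abs=1e-9)


class TestMatrixSynergy:
    def test_bliss_construction_zero(self):
        matrix = simulate_matrix_grid(SimSpec(noise_sd=0.0, n_replicates=1))
        refs = matrix_synergy(matrix)
        assert abs(refs.bliss) < 1e-6

    def test_all_zero_inhibition(self):
        concs = [0.0, 0.1, 1.0, 10.0]
        matrix = matrix_from_grid(concs, concs, np.zeros((4, 4)))
        refs = matrix_synergy(matrix)
        for score in refs.as_tuple():
            assert score == pytest.approx(0.0, abs=1e-9)

    def test_hsa_uniform_offset(self):
        spec = SimSpec(mono1=(0.5, 1.0, 0.0), mono2=(0.5, 1.0, 0.0),
                       interaction_model="hsa", delta=0.10,
                       noise_sd=0.0, n_replicates=1)
        refs = matrix_synergy(simulate_matrix_grid(spec))
        assert refs.hsa == pytest.approx(10.0, abs=1e-6)

    def test_missing_margins_is_design_error(self):
        concs = [0.1, 1.0, 10.0]
        matrix = matrix_from_grid(concs, concs, np.full((3, 3), 40.0))
        with pytest.raises(DesignError):
            matrix_synergy(matrix)

    def test_transpose_symmetry(self):
        spec = SimSpec(mono1=(0.9, 1.4, 0.1), mono2=(0.55, 0.8, -0.2),
                       delta=0.08, noise_sd=0.03, seed=3)
        records = list(__import__("combiscore").simulate_matrix(spec))
        from combiscore import ResponseRecord, build_matrix
        matrix = build_matrix(records)
        swapped = build_matrix([
            ResponseRecord(r.block_id, r.drug_col, r.drug_row, r.conc_col,
                           r.conc_row, r.response, r.cell_line, r.replicate)
            for r in records])
        a = matrix_synergy(matrix)
        b = matrix_synergy(swapped)
        for x, y in zip(a.as_tuple(), b.as_tuple()):
            assert x == pytest.approx(y, abs=1e-6)


class TestConsensusLabel:
    @pytest.mark.parametrize("scores,label", [
        ((6, 7, 8, 9), SYNERGISTIC),
        ((-6, -7, -8, -9), ANTAGONISTIC),
        ((6, -2, 8, 9), NON_INTERACTIVE),
        ((5, 7, 8, 9), NON_INTERACTIVE),     # boundary: strictly greater
        ((-5, -7, -8, -9), NON_INTERACTIVE),
    ])
    def test_labels(self, scores, label):
        assert consensus_label(scores, 5.0) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            consensus_label((math.nan, 1, 2, 3))


class TestEvaluateSScores:
    def test_perfect_separation(self):
        results = [make_result(f"s{i}", s_sum=10 + i, consensus=SYNERGISTIC)
                   for i in range(3)]
        results += [make_result(f"a{i}", s_sum=-10 - i, consensus=ANTAGONISTIC)
                    for i in range(3)]
        out = evaluate_s_scores(results)
        for variant in ("sum", "max", "mean"):
            auroc, auprc = out[variant]
            assert auroc == 1.0
            assert auprc == 1.0

    def test_all_tied_gives_half(self):
        results = [make_result("s", s_sum=1.0, consensus=SYNERGISTIC),
                   make_result("a", s_sum=1.0, consensus=ANTAGONISTIC)]
        assert evaluate_s_scores(results)["sum"][0] == 0.5

    def test_pair_counting_oracle(self):
        # 3 synergistic {10, 8, 6}, 1 antagonistic {7}
        results = [make_result(f"s{i}", s_sum=v, consensus=SYNERGISTIC)
                   for i, v in enumerate((10.0, 8.0, 6.0))]
        results.append(make_result("a", s_sum=7.0, consensus=ANTAGONISTIC))
        # oracle: exhaustive pair counting with tie credit 1/2
        pos = [10.0, 8.0, 6.0]
        neg = [7.0]
        wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
                   for p, n in itertools.product(pos, neg))
        oracle = wins / (len(pos) * len(neg))
        assert oracle == pytest.approx(2.0 / 3.0)
        assert evaluate_s_scores(results)["sum"][0] == pytest.approx(oracle)

    def test_single_class_rejected(self):
        results = [make_result("s", consensus=SYNERGISTIC)]
        with pytest.raises(ValueError):
            evaluate_s_scores(results)

    def test_non_interactive_excluded(self):
        results = [make_result("s", s_sum=1.0, consensus=SYNERGISTIC),
                   make_result("a", s_sum=0.0, consensus=ANTAGONISTIC),
                   make_result("n", s_sum=99.0, consensus=NON_INTERACTIVE)]
        assert evaluate_s_scores(results)["sum"][0] == 1.0


class TestSsPrioritize:
    def test_quantile_arithmetic(self):
        df = pd.DataFrame({"css": [10.0, 20, 30, 40], "s_sum": [1.0, 2, 3, 4]})
        out = ss_prioritize(df, quantile=0.75)
        assert out["css_threshold"].iloc[0] == pytest.approx(32.5)
        assert out["s_threshold"].iloc[0] == pytest.approx(3.25)
        assert out["hit"].sum() == 1
        assert out.loc[out["hit"], "css"].iloc[0] == 40.0

    def test_degenerate_all_identical(self):
        df = pd.DataFrame({"css": [50.0] * 4, "s_sum": [2.0] * 4})
        assert ss_prioritize(df).hit.all()

    def test_anticorrelated_may_be_empty(self):
        df = pd.DataFrame({"css": [10.0, 20, 30, 40], "s_sum": [4.0, 3, 2, 1]})
        assert ss_prioritize(df).hit.sum() == 0

    def test_accepts_results(self):
        results = [make_result(f"b{i}", s_sum=float(i), css=float(10 * i))
                   for i in range(4)]
        out = ss_prioritize(results)
        assert out["hit"].sum() == 1


class TestScoreBlock:
    def test_label_swap_invariance(self):
        spec = SimSpec(mono1=(0.85, 1.2, 0.1), mono2=(0.6, 0.9, -0.1),
                       delta=0.1, noise_sd=0.02, seed=11)
        from combiscore import ResponseRecord, build_matrix, simulate_matrix
        records = simulate_matrix(spec)
        matrix = build_matrix(records)
        swapped = build_matrix([
            ResponseRecord(r.block_id, r.drug_col, r.drug_row, r.conc_col,
                           r.conc_row, r.response, r.cell_line, r.replicate)
            for r in records])
        a = score_block(matrix)
        b = score_block(swapped)
        assert b.css == pytest.approx(a.css, abs=1e-6)
        assert b.s_sum == pytest.approx(a.s_sum, abs=1e-6)
        assert b.auc1_pct == pytest.approx(a.auc2_pct, abs=1e-6)
        assert b.consensus == a.consensus

    def test_s_ordering_on_scored_blocks(self):
        for seed in range(4):
            spec = SimSpec(delta=0.05 * (seed - 2), noise_sd=0.05, seed=seed)
            res = score_block(simulate_matrix_grid(spec))
            assert res.s_sum <= res.s_max + 1e-9
            assert res.s_max <= res.s_mean + 1e-9
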