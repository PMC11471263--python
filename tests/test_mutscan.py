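import json

import numpy as np
import pandas as pd
import pytest

from fabkit.errors import ArgumentError, ParseError, ScaleError
from fabkit.fixtures import FixtureSpec, make_score_fixture
from fabkit.mutscan import (AA20, ScoreMatrix, isotype_sensitivity,
                            multi_mutant_score, parse_scores, scale_to_wt,
                            write_scores)


def _matrix(scores_by_pos, wt_by_pos, tag="antiberty_pll", scaled=False):
    positions = list(scores_by_pos)
    df = pd.DataFrame([scores_by_pos[p] for p in positions],
                      index=positions, columns=AA20, dtype=float)
    wt = pd.Series({p: wt_by_pos[p] for p in positions})
    return ScoreMatrix(scores=df, wt=wt, scorer_tag=tag, scaled=scaled)


def _uniform(val, n=20):
    return dict(zip(AA20, [val] * n))


def _write_long_csv(path, rows):
    with open(path, "w") as fh:
        fh.write("position_label,wt_aa,mut_aa,score\n")
        for r in rows:
            fh.write(",".join(map(str, r)) + "\n")


class TestParseScores:
    def test_two_position_fixture_pivots_to_2x20(self, tmp_path):
        rows = [(p, "A", aa, 0.1 * i) for p in ("1", "2")
                for i, aa in enumerate(AA20)]
        p = tmp_path / "s.csv"
        _write_long_csv(p, rows)
        m = parse_scores(p, "antiberty_pll")
        assert m.scores.shape == (2, 20)
        assert not m.scaled
        assert m.wt["1"] == "A"

    def test_duplicate_row_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        _write_long_csv(p, [("1", "A", "C", 0.5), ("1", "A", "C", 0.7)])
        with pytest.raises(ParseError, match="duplicate"):
            parse_scores(p, "x")

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("position_label,wt_aa,score\n1,A,0.5\n")
        with pytest.raises(ParseError, match="mut_aa"):
            parse_scores(p, "x")

    def test_non_numeric_score_rejected(self, tmp_path):
        p = tmp_path / "nan.csv"
        _write_long_csv(p, [("1", "A", "C", "high")])
        with pytest.raises(ParseError, match="non-numeric"):
            parse_scores(p, "x")

    def test_write_parse_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        m = _matrix({"1": dict(zip(AA20, rng.normal(size=20))),
                     "12a": dict(zip(AA20, rng.normal(size=20)))},
                    {"1": "C", "12a": "W"})
        path = tmp_path / "rt.csv"
        write_scores(m, path)
        back = parse_scores(path, m.scorer_tag)
        assert back.positions == m.positions
        assert np.allclose(back.scores.values, m.scores.values, atol=1e-5)
        assert (back.wt == m.wt).all()


class TestScaleToWt:
    def test_wt_relative_arithmetic(self):
        m = _matrix({"1": {**_uniform(0.0), "A": -1.3, "C": -0.5}}, {"1": "A"})
        scaled = scale_to_wt(m)
        assert scaled.scores.at["1", "C"] == pytest.approx(0.8)
        assert scaled.scores.at["1", "A"] == 0.0
        assert scaled.scaled

    def test_constant_row_becomes_zeros(self):
        m = _matrix({"1": _uniform(2.5)}, {"1": "G"})
        assert (scale_to_wt(m).scores.loc["1"] == 0.0).all()

    def test_double_scaling_guarded(self):
        m = _matrix({"1": _uniform(1.0)}, {"1": "G"})
        with pytest.raises(ScaleError, match="already"):
            scale_to_wt(scale_to_wt(m))

    def test_missing_wt_score_names_position(self):
        m = _matrix({"7": {**_uniform(1.0), "G": float("nan")}}, {"7": "G"})
        with pytest.raises(ScaleError, match="7"):
            scale_to_wt(m)

    def test_all_wt_cells_exactly_zero(self, tmp_path):
        _, _, p_ctrl, _ = make_score_fixture(FixtureSpec(seed=3), tmp_path,
                                             n_positions=10)
        scaled = scale_to_wt(parse_scores(p_ctrl, "rosetta_pmut"))
        for pos in scaled.positions:
            assert scaled.scores.at[pos, scaled.wt[pos]] == 0.0


class TestMultiMutantScore:
    def _scaled(self):
        m = _matrix({"1": {**_uniform(0.0), "C": 1.2},
                     "2": {**_uniform(0.0), "D": -0.3},
                     "3": {**_uniform(0.0), "E": 0.5}},
                    {"1": "A", "2": "A", "3": "A"}, scaled=True)
        return m

    def test_sums_scaled_scores(self):
        total = multi_mutant_score(self._scaled(), [("1", "C"), ("2", "D"), ("3", "E")])
        assert total == pytest.approx(1.4)

    def test_empty_mutation_list_is_wt_baseline(self):
        assert multi_mutant_score(self._scaled(), []) == 0.0

    def test_permutation_invariant(self):
        muts = [("1", "C"), ("2", "D"), ("3", "E")]
        assert multi_mutant_score(self._scaled(), muts) == \
            multi_mutant_score(self._scaled(), muts[::-1])

    def test_single_mutation_equals_cell_value(self):
        m = self._scaled()
        assert multi_mutant_score(m, [("1", "C")]) == m.scores.at["1", "C"]

    def test_duplicate_position_rejected(self):
        with pytest.raises(ArgumentError, match="duplicate"):
            multi_mutant_score(self._scaled(), [("1", "C"), ("1", "D")])

    def test_unknown_label_rejected(self):
        with pytest.raises(ArgumentError, match="unknown position"):
            multi_mutant_score(self._scaled(), [("99", "C")])

    def test_wt_mutation_rejected(self):
        with pytest.raises(ArgumentError, match="wild-type"):
            multi_mutant_score(self._scaled(), [("1", "A")])

    def test_non_additive_scorer_refused_unless_forced(self):
        m = self._scaled()
        m.scorer_tag = "rosetta_pmut"
        with pytest.raises(ArgumentError, match="not additive"):
            multi_mutant_score(m, [("1", "C")])
        assert multi_mutant_score(m, [("1", "C")], force=True) == pytest.approx(1.2)

    def test_unscaled_matrix_refused(self):
        m = self._scaled()
        m.scaled = False
        with pytest.raises(ArgumentError, match="scaled"):
            multi_mutant_score(m, [("1", "C")])

    def test_quintuple_mutant_pattern(self):
        """A five-mutation combination with three preferable singles can sum
        to a positive (stabilising) total."""
        m = _matrix({str(i): {**_uniform(0.0), "C": v} for i, v in
                     enumerate([0.9, 0.6, 0.4, -0.3, -0.2], start=1)},
                    {str(i): "A" for i in range(1, 6)}, scaled=True)
        muts = [(str(i), "C") for i in range(1, 6)]
        singles = [multi_mutant_score(m, [mu]) for mu in muts]
        assert sum(1 for s in singles if s > 0) == 3
        assert multi_mutant_score(m, muts) == pytest.approx(1.4)
        assert multi_mutant_score(m, muts) > 0


class TestIsotypeSensitivity:
    def _noise(self, rng, n_pos, sigma=0.5):
        scores, wt = {}, {}
        for i in range(n_pos):
            pos = str(i + 1)
            scores[pos] = dict(zip(AA20, rng.normal(0, sigma, 20)))
            wt[pos] = AA20[rng.integers(20)]
        return scores, wt

    def test_identical_matrices_give_null_effects(self):
        rng = np.random.default_rng(10)
        scores, wt = self._noise(rng, 10)
        m = _matrix(scores, wt)
        res = isotype_sensitivity(m, m, m)
        assert np.allclose(res["effect"], 0.0)
        assert (res["p_value"] == 1.0).all()
        assert not (res["q_value"] < 0.05).any()

    def test_planted_shift_dominates_effect_and_q(self):
        rng = np.random.default_rng(61)
        n_pos = 50
        scores_b, wt = self._noise(rng, n_pos)
        scores_c = {p: dict(zip(AA20, rng.normal(0, 0.5, 20))) for p in scores_b}
        scores_a = {p: dict(zip(AA20, rng.normal(0, 0.5, 20))) for p in scores_b}
        target = "17"
        for aa in AA20:
            if aa != wt[target]:
                scores_a[target][aa] += 2.0
        res = isotype_sensitivity(_matrix(scores_a, wt), _matrix(scores_b, wt),
                                  _matrix(scores_c, wt))
        res = res.set_index("position")
        assert res["effect"].abs().idxmax() == target
        assert res["q_value"].idxmin() == target
        assert res.loc[target, "effect"] > 0  # shift favours isotype B (positive)

    def test_swapping_isotypes_flips_planted_sign(self):
        rng = np.random.default_rng(12)
        scores_b, wt = self._noise(rng, 20)
        scores_c = {p: dict(zip(AA20, rng.normal(0, 0.5, 20))) for p in scores_b}
        scores_a = {p: dict(zip(AA20, rng.normal(0, 0.5, 20))) for p in scores_b}
        target = "5"
        for aa in AA20:
            if aa != wt[target]:
                scores_a[target][aa] += 2.0
        a, b, c = (_matrix(s, wt) for s in (scores_a, scores_b, scores_c))
        fwd = isotype_sensitivity(a, b, c).set_index("position")
        rev = isotype_sensitivity(b, a, c).set_index("position")
        assert np.sign(fwd.loc[target, "effect"]) == -np.sign(rev.loc[target, "effect"])

    def test_mismatched_wt_rejected(self):
        rng = np.random.default_rng(13)
        scores, wt = self._noise(rng, 3)
        wt2 = dict(wt)
        wt2["2"] = "W" if wt["2"] != "W" else "Y"
        with pytest.raises(ArgumentError, match="WT"):
            isotype_sensitivity(_matrix(scores, wt), _matrix(scores, wt2),
                                _matrix(scores, wt))

    def test_sparse_position_skipped_with_note(self):
        rng = np.random.default_rng(14)
        scores, wt = self._noise(rng, 2)
        a = _matrix(scores, wt)
        a.scores.loc["1", [aa for aa in AA20 if aa != wt["1"]][1:]] = np.nan
        res = isotype_sensitivity(a, _matrix(scores, wt), _matrix(scores, wt))
        row = res.set_index("position").loc["1"]
        assert "skipped" in row["note"]
        assert np.isnan(row["p_value"])

    def test_qvalues_bound_pvalues_below(self):
        rng = np.random.default_rng(15)
        sa, wt = self._noise(rng, 30)
        sb = {p: dict(zip(AA20, rng.normal(0, 0.5, 20))) for p in sa}
        sc = {p: dict(zip(AA20, rng.normal(0, 0.5, 20))) for p in sa}
        res = isotype_sensitivity(_matrix(sa, wt), _matrix(sb, wt), _matrix(sc, wt))
        ok = res["p_value"].notna()
        assert (res.loc[ok, "q_value"] >= res.loc[ok, "p_value"] - 1e-12).all()

    def test_type_one_error_calibrated_under_null(self, tmp_path):
        """Three i.i.d. noise scans: the raw p < 0.05 fraction stays near
        the nominal level."""
        spec = FixtureSpec(seed=67)
        pa, pb, pc, _ = make_score_fixture(spec, tmp_path, n_positions=200,
                                           n_planted=0, shift=0.0)
        res = isotype_sensitivity(parse_scores(pa, "rosetta_pmut"),
                                  parse_scores(pb, "rosetta_pmut"),
                                  parse_scores(pc, "rosetta_pmut"))
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.02 <= frac <= 0.09

    def test_planted_fixture_positions_rank_top_by_effect(self, tmp_path):
        spec = FixtureSpec(seed=79)
        pa, pb, pc, truth_path = make_score_fixture(spec, tmp_path)
        truth = json.loads(open(truth_path).read())
        res = isotype_sensitivity(parse_scores(pa, "rosetta_pmut"),
                                  parse_scores(pb, "rosetta_pmut"),
                                  parse_scores(pc, "rosetta_pmut"))
        top3 = set(res.reindex(res["effect"].abs().sort_values(
            ascending=False).index)["position"].head(3))
        assert top3 == set(truth["planted_positions"])
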