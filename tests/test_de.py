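"""Expression filtering, SNR collapse, and the SAM-style permutation test."""

import numpy as np
import pandas as pd
import pytest

from mirseedcost import (
    DEGeneSets,
    ExpressionMatrix,
    de_gene_sets,
    de_overlap,
    drop_unannotated,
    permutation_fdr,
    presence_filter,
    quantile_normalize,
    sam_statistic,
    snr_collapse,
)
from mirseedcost.simulate import gen_expression

SAMPLES = ["t1", "t2", "t3", "c1", "c2", "c3"]
GROUPS = pd.Series(["treated"] * 3 + ["control"] * 3, index=SAMPLES)


def matrix_from(rows: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(rows, orient="index", columns=SAMPLES),
        groups=GROUPS,
    )


class TestPresenceFilter:
    def _calls(self, rows: dict[str, list[bool]]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index", columns=SAMPLES)

    def test_strict_less_than_half_removed(self):
        mat = matrix_from({"f1": [1] * 6, "f2": [1] * 6})
        calls = self._calls(
            {"f1": [True] * 2 + [False] * 4, "f2": [True] * 3 + [False] * 3}
        )
        kept = presence_filter(mat, calls)
        # 2/6 < 50% removed; exactly 3/6 kept
        assert list(kept.values.index) == ["f2"]

    def test_all_present_unchanged(self):
        mat = matrix_from({"f1": [1] * 6, "f2": [2] * 6})
        calls = self._calls({"f1": [True] * 6, "f2": [True] * 6})
        assert presence_filter(mat, calls).values.equals(mat.values)

    def test_pma_letters_marginal_is_absent(self):
        mat = matrix_from({"f1": [1] * 6})
        calls = pd.DataFrame([["P", "P", "M", "M", "M", "A"]], index=["f1"], columns=SAMPLES)
        assert len(presence_filter(mat, calls).values) == 0  # 2/6 present

    def test_shape_mismatch_raises(self):
        mat = matrix_from({"f1": [1] * 6})
        calls = self._calls({"f1": [True] * 6, "f2": [True] * 6})
        with pytest.raises(ValueError, match="shape"):
            presence_filter(mat, calls)


class TestAnnotationAndCollapse:
    def test_unannotated_dropped(self):
        mat = matrix_from({f"p{i}": [float(i)] * 6 for i in range(10)})
        pmap = {f"p{i}": f"G{i}" for i in range(7)}
        assert len(drop_unannotated(mat, pmap).values) == 7

    def test_empty_map_empties_matrix_with_warning(self, caplog):
        mat = matrix_from({"p1": [1.0] * 6})
        with caplog.at_level("WARNING"):
            out = drop_unannotated(mat, {})
        assert len(out.values) == 0 and "every feature" in caplog.text

    def test_highest_snr_probe_wins(self):
        # probe_a: mean 5, sd 1 -> SNR 5; probe_b: mean 4, sd 2 -> SNR 2
        mat = matrix_from(
            {"probe_a": [4, 5, 6, 4, 5, 6], "probe_b": [2, 4, 6, 2, 4, 6]}
        )
        pmap = {"probe_a": "GENE", "probe_b": "GENE"}
        out = snr_collapse(mat, pmap)
        assert list(out.values.index) == ["GENE"]
        assert out.values.loc["GENE"].tolist() == [4, 5, 6, 4, 5, 6]

    def test_single_probe_gene_kept(self):
        mat = matrix_from({"p1": [1, 2, 3, 1, 2, 3]})
        assert len(snr_collapse(mat, {"p1": "G1"}).values) == 1

    def test_zero_sd_probe_wins_as_infinite_snr(self, caplog):
        mat = matrix_from({"flat": [5.0] * 6, "noisy": [50, 1, 70, 2, 60, 3]})
        with caplog.at_level("WARNING"):
            out = snr_collapse(mat, {"flat": "G", "noisy": "G"})
        assert out.values.loc["G"].tolist() == [5.0] * 6

    def test_snr_tie_breaks_lexicographically(self):
        mat = matrix_from({"pB": [1, 2, 3, 1, 2, 3], "pA": [1, 2, 3, 1, 2, 3]})
        out = snr_collapse(mat, {"pA": "G", "pB": "G"})
        assert out.values.loc["G"].name == "G"  # relabeled
        # identical SNR -> smallest probe id (pA) chosen; rows identical anyway
        assert len(out.values) == 1

    def test_pipeline_row_order_invariance(self):
        rng = np.random.default_rng(1)
        rows = {f"p{i:02d}": list(rng.normal(8, 1, 6)) for i in range(20)}
        pmap = {f"p{i:02d}": f"G{i % 7}" for i in range(20)}
        mat1 = matrix_from(rows)
        mat2 = matrix_from(dict(reversed(list(rows.items()))))
        out1 = snr_collapse(mat1, pmap)
        out2 = snr_collapse(mat2, pmap)
        assert out1.values.equals(out2.values)


class TestSamStatistic:
    def test_equal_means_zero(self):
        d = sam_statistic(matrix_from({"g": [1, 2, 3, 1, 2, 3]}), s0=1.0)
        assert d["g"] == 0.0

    def test_hand_example_zero_variance_with_s0(self):
        d = sam_statistic(matrix_from({"g": [2, 2, 2, 0, 0, 0]}), s0=1.0)
        assert d["g"] == pytest.approx(2.0)  # (2-0)/(0+1)

    def test_antisymmetric_under_label_swap(self):
        mat = matrix_from({"g": [5, 6, 7, 1, 2, 3]})
        swapped = ExpressionMatrix(
            values=mat.values,
            groups=pd.Series(["control"] * 3 + ["treated"] * 3, index=SAMPLES),
        )
        assert sam_statistic(mat, s0=0.5)["g"] == -sam_statistic(swapped, s0=0.5)["g"]

    def test_zero_variance_with_zero_s0_raises(self):
        with pytest.raises(ValueError, match="s0"):
            sam_statistic(matrix_from({"g": [2, 2, 2, 0, 0, 0]}), s0=0.0)

    def test_auto_s0_is_median_pooled_se(self):
        mat, _, _ = gen_expression(50, 3, 0.0, 0.0, rng_seed=4)
        from mirseedcost.de import _group_indices, _pooled_se

        idx_t, idx_c = _group_indices(mat)
        se = _pooled_se(mat.values.to_numpy(), idx_t, idx_c)
        d_auto = sam_statistic(mat, s0="auto")
        d_manual = sam_statistic(mat, s0=float(np.median(se)))
        assert np.allclose(d_auto, d_manual)


class TestPermutationFdr:
    def test_infinite_delta_empty_set(self):
        mat, _, _ = gen_expression(100, 3, 0.1, 3.0, rng_seed=0)
        res = permutation_fdr(mat, fdr_target=None, delta=np.inf, rng_seed=0)
        assert res.significant.sum() == 0

    def test_triplicates_enumerate_all_twenty_permutations(self):
        mat, _, _ = gen_expression(50, 3, 0.0, 0.0, rng_seed=1)
        res = permutation_fdr(mat, n_permutations=200, rng_seed=1)
        assert res.n_permutations == 20

    def test_deterministic_given_seed(self):
        mat, _, _ = gen_expression(200, 4, 0.1, 3.0, rng_seed=2)
        r1 = permutation_fdr(mat, n_permutations=50, rng_seed=7)
        r2 = permutation_fdr(mat, n_permutations=50, rng_seed=7)
        assert r1.delta == r2.delta and r1.significant.equals(r2.significant)

    def test_too_few_samples_raise(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["t1", "c1"])
        groups = pd.Series(["treated", "control"], index=["t1", "c1"])
        with pytest.raises(ValueError):
            permutation_fdr(ExpressionMatrix(values, groups))

    def test_null_data_calls_almost_nothing(self):
        fracs = []
        for s in range(5):
            mat, _, _ = gen_expression(1000, 3, 0.0, 3.0, rng_seed=50 + s)
            res = permutation_fdr(mat, rng_seed=s)
            fracs.append(res.significant.mean())
        assert max(fracs) <= 0.05

    def test_recall_increases_with_effect_size(self):
        recalls = {}
        for effect in (0.0, 3.0, 8.0):
            mat, _, truth = gen_expression(800, 4, 0.1, effect, rng_seed=9)
            res = permutation_fdr(mat, n_permutations=70, rng_seed=9)
            planted = set(truth.de_direction)
            called = set(res.significant.index[res.significant])
            recalls[effect] = len(called & planted) / len(planted)
        assert recalls[0.0] <= 0.05  # no effect: planted set is indistinguishable
        assert recalls[8.0] >= 0.95  # strong effects recovered essentially fully
        assert recalls[0.0] <= recalls[3.0] <= recalls[8.0]


class TestDeGeneSetsAndOverlap:
    def _sam(self, seed=3):
        mat, _, _ = gen_expression(500, 3, 0.1, 6.0, rng_seed=seed)
        return permutation_fdr(mat, rng_seed=seed)

    def test_up_down_partition_significant(self):
        res = self._sam()
        sets = de_gene_sets(res)
        assert sets.up.isdisjoint(sets.down)
        assert sets.up | sets.down == set(res.significant.index[res.significant])
        assert all(res.d[g] > 0 for g in sets.up)

    def test_empty_result_two_empty_lists(self):
        mat, _, _ = gen_expression(100, 3, 0.1, 3.0, rng_seed=5)
        res = permutation_fdr(mat, fdr_target=None, delta=np.inf, rng_seed=5)
        sets = de_gene_sets(res)
        assert sets.up == set() and sets.down == set()

    def test_identical_sets_overlap_one(self):
        s = DEGeneSets("c1", up={"a", "b"}, down={"c"})
        assert de_overlap(s, s) == 1.0
        assert de_overlap(s, s, mode="directional") == 1.0

    def test_disjoint_sets_overlap_zero(self):
        a = DEGeneSets("c1", up={"a"}, down={"b"})
        b = DEGeneSets("c2", up={"x"}, down={"y"})
        assert de_overlap(a, b) == 0.0

    def test_directional_mode_distinguishes_sign(self):
        a = DEGeneSets("c1", up={"g1"}, down=set())
        b = DEGeneSets("c2", up=set(), down={"g1"})
        assert de_overlap(a, b, mode="all") == 1.0
        assert de_overlap(a, b, mode="directional") == 0.0

    def test_known_shared_count_matches_formula(self):
        a = DEGeneSets("c1", up={"g1", "g2", "g3"}, down={"g4"})
        b = DEGeneSets("c2", up={"g1"}, down={"g4", "g5"})
        # shared {g1, g4}; |A|=4, |B|=3
        assert de_overlap(a, b) == pytest.approx(2 / np.sqrt(12))

    def test_empty_sets_raise(self):
        with pytest.raises(ValueError):
            de_overlap(DEGeneSets("a"), DEGeneSets("b"))


def test_two_contrast_planted_overlap_recovered():
    """With fully recoverable effects, DE-set overlap matches the planted
    overlap fraction of two contrasts' DE truth to within 0.05."""
    rng = np.random.default_rng(0)
    n_genes, n_de, n_shared = 5000, 500, 250
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    picks = rng.choice(n_genes, size=2 * n_de - n_shared, replace=False)
    planted_a = [genes[i] for i in picks[:n_de]]
    planted_b = [genes[i] for i in picks[n_de - n_shared :]]
    called = []
    for seed, planted in ((11, planted_a), (12, planted_b)):
        mat, _, _ = gen_expression(n_genes, 3, effect_size=8.0, rng_seed=seed, de_genes=planted)
        called.append(de_gene_sets(permutation_fdr(mat, rng_seed=seed)))
    assert de_overlap(*called) == pytest.approx(n_shared / n_de, abs=0.05)


def test_quantile_normalize_equalizes_column_distributions():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(100, 4)) * [1, 2, 3, 4] + [0, 5, 1, 2])
    out = quantile_normalize(df)
    ref = np.sort(out.iloc[:, 0].values)
    for c in out.columns[1:]:
        assert np.allclose(np.sort(out[c].values), ref)
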