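import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bhlhsurvey.expression import (
    cluster_blocks,
    ddct,
    filter_expressed,
    hormone_response,
    log_heat,
    tissue_specific,
    welch_test,
)
from bhlhsurvey.synthetic import gen_expression


def matrix(rows: dict[str, list[float]], samples=None) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    if samples:
        df.columns = samples
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


class TestFilter:
    def test_sub_threshold_gene_excluded(self):
        m = matrix({"lo": [0.5, 0.5, 0.5], "hi": [0.2, 5.0, 0.1]})
        kept, excluded = filter_expressed(m)
        assert excluded == ["lo"] and list(kept.index) == ["hi"]

    def test_boundary_exactly_one_retained(self):
        m = matrix({"edge": [0.0, 1.0, 0.3], "lo": [0.9, 0.99, 0.0]})
        kept, excluded = filter_expressed(m)
        assert "edge" in kept.index and excluded == ["lo"]

    def test_five_gene_fixture_counts(self):
        rows = {f"g{i}": [2.0, 3.0] for i in range(4)}
        rows["weak"] = [0.4, 0.6]
        kept, excluded = filter_expressed(matrix(rows))
        assert len(kept) == 4 and excluded == ["weak"]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed(matrix({"g": [-1.0, 2.0]}))


class TestLogHeat:
    def test_anchor_values(self):
        m = matrix({"g": [0.0, 1.0, 7.0]})
        out = log_heat(m)
        assert list(out.loc["g"]) == pytest.approx([0.0, 1.0, 3.0])

    def test_monotone(self):
        m = matrix({"g": list(np.linspace(0, 50, 20))})
        out = log_heat(m).loc["g"].to_numpy()
        assert (np.diff(out) > 0).all()


class TestClusterBlocks:
    def test_two_planted_programs_split_perfectly(self):
        expr = gen_expression(n_per_block=(15, 15), n_spike=0,
                              n_subthreshold=0, responder_spec=(), seed=5)
        truth = expr.truth.set_index("gene_id")["block"]
        asn = cluster_blocks(expr.tissue, k=2)
        mapping = {}
        for gene, b in asn.blocks.items():
            mapping.setdefault(truth[gene], set()).add(b)
        assert all(len(v) == 1 for v in mapping.values())
        assert mapping[1.0] != mapping[2.0]

    def test_duplicate_rows_share_a_block(self):
        m = matrix({
            "a": [1.0, 5.0, 9.0], "a2": [1.0, 5.0, 9.0],
            "b": [9.0, 1.0, 2.0], "c": [8.0, 2.0, 1.0],
        })
        asn = cluster_blocks(m, k=2)
        assert asn.blocks["a"] == asn.blocks["a2"]

    def test_k_equals_n_gives_singletons(self):
        m = matrix({
            "a": [1.0, 5.0, 9.0], "b": [9.0, 1.0, 2.0], "c": [5.0, 9.0, 1.0],
        })
        asn = cluster_blocks(m, k=3)
        assert sorted(asn.blocks.values()) == [1, 2, 3]

    def test_constant_row_assigned_by_fallback(self):
        m = matrix({
            "a": [1.0, 5.0, 9.0], "b": [1.2, 5.1, 8.8],
            "c": [9.0, 5.0, 1.0], "d": [8.8, 4.9, 1.2],
            "flat": [5.0, 5.0, 5.0],
        })
        asn = cluster_blocks(m, k=2)
        assert "flat" in asn.euclidean_fallback
        assert asn.blocks["flat"] in {1, 2}

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_blocks(matrix({"a": [1.0, 2.0]}), k=2)

    def test_invariant_to_row_permutation(self):
        expr = gen_expression(n_per_block=(8, 8), n_spike=0,
                              n_subthreshold=0, responder_spec=(), seed=6)
        m = expr.tissue
        asn1 = cluster_blocks(m, k=2)
        perm = m.iloc[::-1]
        asn2 = cluster_blocks(perm, k=2)
        # same partition, modulo block numbering
        part1 = {}
        part2 = {}
        for g in m.index:
            part1.setdefault(asn1.blocks[g], set()).add(g)
            part2.setdefault(asn2.blocks[g], set()).add(g)
        assert sorted(map(sorted, part1.values())) == \
            sorted(map(sorted, part2.values()))


class TestTissueSpecific:
    def test_constant_row_never_flagged(self):
        m = matrix({"flat": [4.0] * 10})
        call = tissue_specific(m)
        assert call.flagged == {}
        assert (call.z.loc["flat"] == 0).all()

    def test_z_exactly_three_not_flagged(self):
        # engineered integer row: mean 2, sd 5 (exact), max z exactly 3.0
        row = [17.0] + [1.0] * 5 + [0.0] * 5
        vals = np.array(row)
        assert vals.std(ddof=1) == 5.0 and vals.mean() == 2.0
        call = tissue_specific(matrix({"edge": row}))
        assert call.z.loc["edge"].max() == 3.0
        assert call.flagged == {}

    def test_planted_spikes_all_flagged(self):
        expr = gen_expression(n_per_block=(10,), n_spike=8,
                              n_subthreshold=0, responder_spec=(), seed=7)
        kept, _ = filter_expressed(expr.tissue)
        call = tissue_specific(kept)
        spikes = expr.truth[expr.truth["role"] == "spike"]
        for r in spikes.itertuples():
            assert r.spike_sample in call.flagged.get(r.gene_id, [])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            tissue_specific(matrix({"g": [1.0]}))


class TestHormoneResponse:
    def frame(self, genes, cols, value):
        return pd.DataFrame(value, index=genes, columns=cols)

    def test_no_change_is_none(self):
        genes = ["a", "b"]
        control = pd.Series([4.0, 9.0], index=genes)
        treated = {
            "IAA": pd.DataFrame({"1h": [4.0, 9.0], "6h": [4.0, 9.0]},
                                index=genes)
        }
        resp = hormone_response(control, treated)
        assert (resp.calls == "none").all().all()
        assert resp.multi_hormone_count == 0

    def test_threefold_induction_called_up(self):
        genes = ["a"]
        control = pd.Series([1.0], index=genes)
        treated = {"ABA": pd.DataFrame({"6h": [7.0]}, index=genes)}
        resp = hormone_response(control, treated)
        assert resp.calls.loc["a", "ABA"] == "up"
        assert resp.max_log2fc.loc["a", "ABA"] == pytest.approx(
            np.log2(8.0 / 2.0)
        )

    def test_direction_matches_sign(self):
        genes = ["dn"]
        control = pd.Series([40.0], index=genes)
        treated = {"GA3": pd.DataFrame({"1h": [5.0]}, index=genes)}
        resp = hormone_response(control, treated)
        assert resp.calls.loc["dn", "GA3"] == "down"
        assert resp.max_log2fc.loc["dn", "GA3"] < 0

    def test_planted_two_hormone_responders_counted_exactly(self):
        expr = gen_expression(
            n_per_block=(10,), n_spike=0, n_subthreshold=0,
            responder_spec=((6, ("IAA", "ABA")),), seed=8,
        )
        resp = hormone_response(expr.control, expr.treated)
        want = set(expr.truth.loc[expr.truth["role"] == "responder", "gene_id"])
        assert set(resp.multi_hormone_genes) == want
        for g in want:
            assert resp.calls.loc[g, "IAA"] == "up"
            assert resp.calls.loc[g, "ABA"] == "up"
            assert resp.calls.loc[g, "GA3"] == "none"

    def test_mismatched_gene_sets_rejected(self):
        control = pd.Series([1.0], index=["a"])
        treated = {"IAA": pd.DataFrame({"1h": [2.0]}, index=["b"])}
        with pytest.raises(ValueError, match="gene set"):
            hormone_response(control, treated)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        t, df, p = welch_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0214, abs=2e-4)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(0, 1, size=int(rng.integers(3, 10)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 10)))
            t, df, p = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_equal_sizes_equal_variance_matches_pooled(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t, _, _ = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)

    def test_zero_variance_conventions(self):
        t, _, p = welch_test([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0
        t, _, p = welch_test([2.0, 2.0], [3.0, 3.0])
        assert np.isinf(t) and p == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestDdct:
    def ct(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "condition", "replicate", "ct_target",
                           "ct_reference"]
        )

    def test_one_cycle_shift_doubles_rq(self):
        rows = [["g", "CK", r, 20.0, 15.0] for r in (1, 2, 3)]
        rows += [["g", "T", r, 19.0, 15.0] for r in (1, 2, 3)]
        res = {r.condition: r for r in ddct(self.ct(rows), "CK")}
        assert res["T"].delta_delta_ct == pytest.approx(-1.0)
        assert res["T"].rq == pytest.approx(2.0)

    def test_control_is_unity_with_p_one(self):
        rows = [["g", "CK", r, 20.0 + 0.1 * r, 15.0] for r in (1, 2, 3)]
        res = {r.condition: r for r in ddct(self.ct(rows), "CK")}
        assert res["CK"].rq == 1.0
        assert res["CK"].welch_t == 0.0 and res["CK"].p_two_sided == 1.0

    def test_welch_on_replicate_dct_sets(self):
        rows = [["g", "CK", r, 15.0 + r, 15.0] for r in (1, 2, 3)]  # dct 1,2,3
        rows += [["g", "T", r, 18.0 + r, 15.0] for r in (1, 2, 3)]  # dct 4,5,6
        res = {r.condition: r for r in ddct(self.ct(rows), "CK")}
        assert abs(res["T"].welch_t) == pytest.approx(3.674, abs=1e-3)
        assert res["T"].df == pytest.approx(4.0)
        assert res["T"].p_two_sided == pytest.approx(0.0214, abs=2e-4)
        assert res["T"].stars == "*"

    def test_single_replicate_skips_test(self):
        rows = [["g", "CK", 1, 20.0, 15.0], ["g", "T", 1, 19.0, 15.0]]
        res = {r.condition: r for r in ddct(self.ct(rows), "CK")}
        assert res["T"].rq == pytest.approx(2.0)
        assert res["T"].p_two_sided is None and res["T"].stars == ""

    def test_missing_control_rejected(self):
        rows = [["g", "T", 1, 19.0, 15.0]]
        with pytest.raises(ValueError, match="control"):
            ddct(self.ct(rows), "CK")
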