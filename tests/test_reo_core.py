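from itertools import product

import numpy as np
import pandas as pd
import pytest

from stemreo import (
    DirectedGenePair,
    InputError,
    binomial_reo_p,
    find_stable_pairs,
    intersect_cohort_reversals,
    reversal_pairs,
)
from stemreo.datatypes import StablePairSet
from conftest import rankwise_monotone


def enumerate_binomial_tail(k: int, s: int) -> float:
    """P(X >= s) by exhaustive enumeration of all 2^k coin-flip sequences."""
    hits = sum(1 for bits in range(2 ** k) if bin(bits).count("1") >= s)
    return hits / 2 ** k


class TestBinomialReoP:
    @pytest.mark.parametrize("k,s,expected", [
        (10, 10, 0.0009765625),   # 0.5**10
        (1, 1, 0.5),
        (10, 5, 0.623046875),     # brute-force binomial mass summation
        (5, 0, 1.0),
    ])
    def test_known_values(self, k, s, expected):
        assert binomial_reo_p(k, s) == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_enumeration_small_k(self):
        for k in range(1, 9):
            for s in range(k + 1):
                assert binomial_reo_p(k, s) == pytest.approx(
                    enumerate_binomial_tail(k, s), abs=1e-12)

    def test_monotone_in_s(self):
        for k in (1, 5, 12):
            ps = [binomial_reo_p(k, s) for s in range(k + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("k,s", [(0, 0), (3, 4), (3, -1)])
    def test_invalid_inputs(self, k, s):
        with pytest.raises(InputError):
            binomial_reo_p(k, s)


def _matrix(rows: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


class TestFindStablePairs:
    def test_unanimous_pair_retained(self):
        expr = _matrix({"a": [5.0 + i for i in range(20)],
                        "b": [1.0 + i for i in range(20)]})
        res = find_stable_pairs(expr)
        assert len(res) == 1
        row = res.table.iloc[0]
        assert (row.gene_a, row.gene_b, row.direction) == ("a", "b", "a_gt_b")
        assert row.p_value == pytest.approx(0.5 ** 20, rel=1e-12)

    def test_even_split_not_retained(self):
        vals_a = [2.0] * 10 + [0.0] * 10
        expr = _matrix({"a": vals_a, "b": [1.0] * 20})
        res = find_stable_pairs(expr)
        assert len(res) == 0
        # p of the 10/20 split equals the binomial oracle
        assert binomial_reo_p(20, 10) == pytest.approx(0.588099, abs=1e-6)

    def test_ties_reduce_effective_k(self):
        # 8 decisive samples (all a>b) + 4 exact ties
        vals_a = [2.0] * 8 + [1.0] * 4
        vals_b = [1.0] * 12
        expr = _matrix({"a": vals_a, "b": vals_b})
        res = find_stable_pairs(expr, fdr_threshold=0.5)
        row = res.table.iloc[0]
        assert row.k == 8 and row.s == 8
        assert row.p_value == pytest.approx(0.5 ** 8, rel=1e-12)

    def test_gene_order_canonical(self):
        expr = _matrix({"b": [1.0] * 10, "a": [2.0] * 10})
        res = find_stable_pairs(expr, fdr_threshold=0.5)
        res2 = find_stable_pairs(expr.iloc[::-1], fdr_threshold=0.5)
        pd.testing.assert_frame_equal(res.table, res2.table)
        assert list(res.table.gene_a) == ["a"]

    def test_candidate_pair_subset(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(6, 15)),
                            index=list("abcdef"),
                            columns=[f"s{i}" for i in range(15)])
        full = find_stable_pairs(expr, fdr_threshold=1.0)
        sub = find_stable_pairs(expr, fdr_threshold=1.0,
                                candidate_pairs=[("c", "a"), ("e", "f")])
        assert set(zip(sub.table.gene_a, sub.table.gene_b)) == {("a", "c"), ("e", "f")}
        merged = sub.table.merge(full.table, on=["gene_a", "gene_b"])
        assert (merged.k_x == merged.k_y).all() and (merged.s_x == merged.s_y).all()

    def test_self_pair_rejected(self):
        expr = _matrix({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(InputError):
            find_stable_pairs(expr, candidate_pairs=[("a", "a")])

    def test_empty_sample_subset_rejected(self):
        expr = _matrix({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(InputError):
            find_stable_pairs(expr, samples=[])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(12, 25)),
                            index=[f"g{i:02d}" for i in range(12)],
                            columns=[f"s{i}" for i in range(25)])
        before = find_stable_pairs(expr, fdr_threshold=0.2)
        after = find_stable_pairs(rankwise_monotone(expr, rng), fdr_threshold=0.2)
        pd.testing.assert_frame_equal(before.table, after.table)


def _stable(subtype, rows):
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "direction"])
    table["k"] = 10
    table["s"] = 10
    table["p_value"] = 0.5 ** 10
    table["fdr"] = 1e-3
    return StablePairSet(subtype=subtype, table=table, n_tested=len(rows),
                         fdr_threshold=0.05)


class TestReversalPairs:
    def test_opposite_directions_detected(self):
        hi = _stable("high", [("a", "b", "a_gt_b")])
        lo = _stable("low", [("a", "b", "a_lt_b")])
        assert reversal_pairs(hi, lo) == [DirectedGenePair("a", "b")]

    def test_same_direction_ignored(self):
        hi = _stable("high", [("a", "b", "a_gt_b")])
        lo = _stable("low", [("a", "b", "a_gt_b")])
        assert reversal_pairs(hi, lo) == []

    def test_orientation_follows_high_risk_pattern(self):
        hi = _stable("high", [("a", "b", "a_lt_b")])
        lo = _stable("low", [("a", "b", "a_gt_b")])
        assert reversal_pairs(hi, lo) == [DirectedGenePair("b", "a")]


class TestIntersectCohorts:
    def test_identical_lists(self):
        pairs = [DirectedGenePair("a", "b"), DirectedGenePair("c", "d")]
        consistent, conc, p = intersect_cohort_reversals(pairs, list(pairs))
        assert consistent == sorted(pairs)
        assert conc == pytest.approx(1.0)

    def test_flipped_orientations(self):
        a = [DirectedGenePair("a", "b")]
        b = [DirectedGenePair("b", "a")]
        consistent, conc, p = intersect_cohort_reversals(a, b)
        assert consistent == [] and conc == pytest.approx(0.0)

    def test_binomial_p_matches_enumeration(self):
        """10 shared pairs, 9 concordant: two-sided exact binomial tail
        2*P(X>=9) = 22/1024."""
        shared = [DirectedGenePair(f"g{i}", f"h{i}") for i in range(10)]
        flipped = shared[:9] + [DirectedGenePair("h9", "g9")]
        consistent, conc, p = intersect_cohort_reversals(shared, flipped)
        assert conc == pytest.approx(0.9)
        assert len(consistent) == 9
        assert p == pytest.approx(0.021484375, abs=1e-12)

    def test_no_overlap(self):
        consistent, conc, p = intersect_cohort_reversals(
            [DirectedGenePair("a", "b")], [DirectedGenePair("c", "d")])
        assert consistent == [] and np.isnan(conc) and p == 1.0


def test_planted_reversals_recovered(bulk_small):
    """Two cohorts, delta = 3*sigma: at least 80% of planted pairs appear
    among orientation-consistent cross-cohort reversals, correctly oriented."""
    _, exprs, records, truth = bulk_small
    from stemreo import median_split, ssgsea_score
    revs = []
    for expr in exprs:
        assign = median_split(ssgsea_score(expr, truth.stem_gene_ids), "c")
        hi = find_stable_pairs(expr, samples=list(assign.high_samples), subtype="high")
        lo = find_stable_pairs(expr, samples=list(assign.low_samples), subtype="low")
        revs.append(reversal_pairs(hi, lo))
    consistent, conc, _ = intersect_cohort_reversals(*revs)
    cons = set(consistent)
    hit = sum(p in cons for p in truth.planted_pairs)
    assert hit >= 0.8 * len(truth.planted_pairs)
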