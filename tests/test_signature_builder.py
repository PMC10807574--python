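from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stemreo import (
    DirectedGenePair,
    InputError,
    Signature,
    SurvivalRecord,
    c_index,
    classify,
    classify_matrix,
    evaluate_signature,
    filter_prognostic_pairs,
    forward_search,
    half_vote_labels,
    vote_matrix,
)
from conftest import rankwise_monotone


def votes_to_expr(votes: np.ndarray) -> tuple[pd.DataFrame, list[DirectedGenePair]]:
    """Build an expression matrix realizing a prescribed vote pattern.

    Row k of ``votes`` (values in {0,1}) becomes gene pair (hk, lk) where
    hk > lk in samples voting 1 and hk < lk otherwise.
    """
    n_pairs, n_samples = votes.shape
    rows = {}
    pairs = []
    for k in range(n_pairs):
        hi, lo = f"h{k:02d}", f"l{k:02d}"
        pairs.append(DirectedGenePair(hi, lo))
        base = 10.0 * (k + 1)
        rows[hi] = base + np.where(votes[k] == 1, 1.0, -1.0)
        rows[lo] = np.full(n_samples, base)
    expr = pd.DataFrame(rows).T
    expr.columns = [f"s{i:03d}" for i in range(n_samples)]
    return expr, pairs


def _records(times, events, surgery=None):
    surgery = surgery if surgery is not None else [True] * len(times)
    return [SurvivalRecord(f"s{i:03d}", float(t), int(e), surgery_only=bool(s))
            for i, (t, e, s) in enumerate(zip(times, events, surgery))]


class TestVotesAndClassify:
    def test_vote_matrix_values(self):
        votes = np.array([[1, 0, 1], [0, 0, 1]])
        expr, pairs = votes_to_expr(votes)
        vm = vote_matrix(expr, pairs)
        np.testing.assert_array_equal(vm.to_numpy(), votes.astype(float))

    def test_half_vote_rule_boundary(self):
        """2 of 4 pairs voting high is 'at least half' -> high; 1 of 4 -> low."""
        sig_votes = np.array([[1], [1], [0], [0]])
        expr, pairs = votes_to_expr(sig_votes)
        sig = Signature(pairs=pairs, c_index_train=0.0)
        assert classify(expr.iloc[:, 0], sig).label == "high"

        sig_votes2 = np.array([[1], [0], [0], [0]])
        expr2, pairs2 = votes_to_expr(sig_votes2)
        sig2 = Signature(pairs=pairs2, c_index_train=0.0)
        assert classify(expr2.iloc[:, 0], sig2).label == "low"

    def test_unanimous_high(self):
        votes = np.ones((47, 1))
        expr, pairs = votes_to_expr(votes)
        sig = Signature(pairs=pairs, c_index_train=0.0)
        res = classify(expr.iloc[:, 0], sig)
        assert res.label == "high" and res.votes_high == res.votes_total == 47

    def test_missing_genes_reduce_total_and_unclassifiable(self):
        votes = np.array([[1], [0]])
        expr, pairs = votes_to_expr(votes)
        sig = Signature(pairs=pairs + [DirectedGenePair("absent1", "absent2")],
                        c_index_train=0.0)
        res = classify(expr.iloc[:, 0], sig)
        assert res.votes_total == 2  # the missing pair is skipped
        empty = pd.Series(dtype=float, name="s000")
        res2 = classify(empty, sig)
        assert res2.label is None and not res2.classifiable

    def test_tied_pair_values_skip_vote(self):
        expr = pd.DataFrame({"s0": [2.0, 2.0, 5.0, 1.0]},
                            index=["a", "b", "c", "d"])
        sig = Signature(pairs=[DirectedGenePair("a", "b"), DirectedGenePair("c", "d")],
                        c_index_train=0.0)
        res = classify(expr["s0"], sig)
        assert res.votes_total == 1 and res.label == "high"

    def test_individuality(self):
        """A sample's label never depends on the surrounding matrix."""
        rng = np.random.default_rng(0)
        votes = rng.integers(0, 2, (5, 20))
        expr, pairs = votes_to_expr(votes)
        sig = Signature(pairs=pairs, c_index_train=0.0)
        target = "s007"
        ref = classify(expr[target], sig).label
        subset = classify_matrix(expr[[target, "s001"]], sig).loc[target, "label"]
        perm = classify_matrix(expr[list(rng.permutation(expr.columns))], sig
                               ).loc[target, "label"]
        aug = expr.copy()
        aug["extra"] = rng.normal(size=expr.shape[0])
        augmented = classify_matrix(aug, sig).loc[target, "label"]
        assert ref == subset == perm == augmented

    def test_labels_invariant_under_monotone_and_gene_permutation(self):
        rng = np.random.default_rng(1)
        votes = rng.integers(0, 2, (6, 15))
        expr, pairs = votes_to_expr(votes)
        sig = Signature(pairs=pairs, c_index_train=0.0)
        before = classify_matrix(expr, sig)["label"]
        after = classify_matrix(rankwise_monotone(expr, rng), sig)["label"]
        shuffled = classify_matrix(expr.iloc[rng.permutation(expr.shape[0])], sig)["label"]
        pd.testing.assert_series_equal(before, after)
        pd.testing.assert_series_equal(before, shuffled)


class TestFilterPrognosticPairs:
    def _prognostic_setup(self, rng, n=250, n_noise=6):
        # pair 0 tracks a strong hazard; noise pairs are independent coin flips
        risk = rng.integers(0, 2, n)
        votes = np.vstack([risk, rng.integers(0, 2, (n_noise, n))])
        t = rng.exponential(1.0 / np.exp(np.log(3.0) * risk))
        c = rng.uniform(0, 3, n)
        times = np.maximum(np.minimum(t, c), 1e-9)
        events = (t <= c).astype(int)
        expr, pairs = votes_to_expr(votes)
        return expr, pairs, _records(times, events)

    def test_prognostic_pair_retained_noise_rejected(self):
        rng = np.random.default_rng(42)
        expr, pairs, recs = self._prognostic_setup(rng)
        cand = filter_prognostic_pairs(pairs, expr, recs)
        kept = {(p.gene_high, p.gene_low) for p in cand.pairs}
        assert ("h00", "l00") in kept
        assert cand.table.iloc[0]["c_index"] > 0.6
        assert len(cand) <= 3  # the 6 null pairs essentially never all pass

    def test_empty_result_status(self):
        rng = np.random.default_rng(0)
        votes = rng.integers(0, 2, (3, 60))
        t = rng.exponential(1.0, 60)
        expr, pairs = votes_to_expr(votes)
        cand = filter_prognostic_pairs(pairs, expr, _records(t, np.ones(60)))
        assert cand.status in ("ok", "no_candidates")
        empty = filter_prognostic_pairs([], expr, _records(t, np.ones(60)))
        assert empty.status == "no_candidates" and len(empty) == 0

    def test_deterministic_tie_break(self):
        # two identical pairs: ordering falls back to lexicographic ids
        rng = np.random.default_rng(7)
        risk = rng.integers(0, 2, 100)
        votes = np.vstack([risk, risk])
        t = rng.exponential(1.0 / np.exp(1.2 * risk))
        expr, pairs = votes_to_expr(votes)
        cand = filter_prognostic_pairs(pairs, expr, _records(t, np.ones(100)))
        assert [p.gene_high for p in cand.pairs] == ["h00", "h01"]

    def test_surgery_only_restriction(self):
        rng = np.random.default_rng(3)
        expr, pairs, recs = self._prognostic_setup(rng)
        surgery = [i % 2 == 0 for i in range(len(recs))]
        for r, s in zip(recs, surgery):
            r.surgery_only = s
        cand_all = filter_prognostic_pairs(pairs, expr, recs, surgery_only=False)
        cand_surg = filter_prognostic_pairs(pairs, expr, recs, surgery_only=True)
        assert cand_all.n_tested == cand_surg.n_tested  # same pairs screened
        # but fits differ because the sample set differs
        assert not cand_all.table.equals(cand_surg.table)


class TestForwardSearch:
    def _toy(self, seed=0, n_pairs=8, n=30):
        rng = np.random.default_rng(seed)
        risk = rng.integers(0, 2, n)
        votes = np.vstack([np.where(rng.random(n) < 0.85, risk, 1 - risk)
                           for _ in range(n_pairs)])
        t = rng.exponential(1.0 / np.exp(1.5 * risk))
        c = rng.uniform(0, 3, n)
        times = np.maximum(np.minimum(t, c), 1e-9)
        events = (t <= c).astype(int)
        expr, pairs = votes_to_expr(votes)
        recs = _records(times, events)
        # rank candidates by their single-pair C-index, descending
        cis = [c_index(recs, votes[k].astype(float)) for k in range(n_pairs)]
        order = np.argsort([-x for x in cis], kind="stable")
        return expr, [pairs[i] for i in order], recs, votes, order, cis

    def test_single_perfect_candidate(self):
        times = [1.0, 2.0, 3.0, 4.0]
        votes = np.array([[1, 1, 0, 0]])
        expr, pairs = votes_to_expr(votes)
        recs = _records(times, [1, 1, 1, 1])
        sig = forward_search(pairs, expr, recs)
        assert len(sig) == 1 and sig.c_index_train == pytest.approx(5 / 6)

    def test_bounded_by_exhaustive_optimum(self):
        """Greedy C-index is at least the best single pair's and at most
        the exhaustive best over all 2^8 - 1 subsets."""
        expr, ranked, recs, votes, order, cis = self._toy(seed=11)
        sig = forward_search(ranked, expr, recs)

        def subset_c(idx):
            sub = votes[list(idx)].astype(float)
            usable = sub.shape[0]
            lab = (2 * sub.sum(axis=0) >= usable).astype(float)
            return c_index(recs, lab)

        all_subsets = [subset_c(comb) for r in range(1, 9)
                       for comb in combinations(range(8), r)]
        assert max(cis) - 1e-12 <= sig.c_index_train <= max(all_subsets) + 1e-12
        assert all(b > a for a, b in zip(sig.c_index_path, sig.c_index_path[1:]))

    def test_noise_pairs_do_not_hurt(self):
        rng = np.random.default_rng(5)
        risk = rng.integers(0, 2, 60)
        t = rng.exponential(1.0 / np.exp(2.0 * risk))
        good = risk[None, :]
        noise = rng.integers(0, 2, (5, 60))
        votes = np.vstack([good, noise])
        expr, pairs = votes_to_expr(votes)
        recs = _records(np.maximum(t, 1e-9), np.ones(60))
        sig = forward_search(pairs, expr, recs)
        top_only = c_index(recs, votes[0].astype(float))
        assert sig.c_index_train >= top_only - 1e-12

    def test_deterministic(self):
        expr, ranked, recs, *_ = self._toy(seed=23)
        s1 = forward_search(ranked, expr, recs)
        s2 = forward_search(list(ranked), expr.copy(), list(recs))
        assert s1.pairs == s2.pairs and s1.c_index_path == s2.c_index_path


class TestSignatureSerialization:
    def test_round_trip(self, tmp_path):
        sig = Signature(pairs=[DirectedGenePair("a", "b"), DirectedGenePair("d", "c")],
                        c_index_train=0.71, c_index_path=[0.65, 0.71],
                        provenance={"seed": 1})
        path = tmp_path / "sig.json"
        sig.to_json(path)
        back = Signature.from_json(path)
        assert back.pairs == sig.pairs
        assert back.c_index_train == sig.c_index_train
        assert back.provenance == sig.provenance

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(InputError):
            Signature(pairs=[DirectedGenePair("a", "b"), DirectedGenePair("b", "a")],
                      c_index_train=0.5)


class TestEvaluate:
    def test_training_self_consistency(self):
        rng = np.random.default_rng(19)
        risk = rng.integers(0, 2, 80)
        votes = np.vstack([np.where(rng.random(80) < 0.9, risk, 1 - risk)
                           for _ in range(3)])
        t = rng.exponential(1.0 / np.exp(1.5 * risk))
        expr, pairs = votes_to_expr(votes)
        recs = _records(np.maximum(t, 1e-9), np.ones(80))
        sig = forward_search(pairs, expr, recs, surgery_only=True)
        rep = evaluate_signature(sig, expr, recs)
        assert rep.c_index == pytest.approx(sig.c_index_train, abs=1e-12)

    def test_report_invariant_under_monotone_distortion(self):
        rng = np.random.default_rng(29)
        risk = rng.integers(0, 2, 50)
        votes = np.vstack([risk, 1 - risk, rng.integers(0, 2, 50)])
        t = rng.exponential(1.0 / np.exp(1.0 * risk))
        expr, pairs = votes_to_expr(votes)
        recs = _records(np.maximum(t, 1e-9), np.ones(50))
        sig = Signature(pairs=pairs, c_index_train=0.0)
        rep1 = evaluate_signature(sig, expr, recs)
        rep2 = evaluate_signature(sig, rankwise_monotone(expr, rng), recs)
        pd.testing.assert_frame_equal(rep1.labels, rep2.labels)
        assert rep1.logrank_p == rep2.logrank_p
        assert rep1.c_index == rep2.c_index
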