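"""Recovery evaluation: cluster matching, ARI, coefficient correlation,
precision/recall."""

from itertools import permutations
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from ccpls.evaluate import evaluate_recovery, match_clusters
from ccpls.simulate import SimulatedTruth


def _series(labels, genes=None):
    genes = genes or [f"g{j}" for j in range(len(labels))]
    return pd.Series(labels, index=genes)


def _truth(W, clusters, genes, types=("A", "B", "C", "D")):
    return SimulatedTruth(
        W_true=pd.DataFrame(W, index=list(types), columns=genes),
        cluster_labels=pd.Series(clusters, index=genes),
        sigma=pd.Series(1.0, index=genes),
        noise=None,
        alpha=1.0,
        vp=0.7,
        scores={},
    )


class TestMatchClusters:
    def test_identity_mapping(self):
        est = _series([1, 1, 2, 2, 3, 3])
        true = _series([1, 1, 2, 2, 3, 3])
        assert match_clusters(est, true) == {1: "1", 2: "2", 3: "3"}

    def test_permuted_ids_inverted(self):
        est = _series([3, 3, 1, 1, 2, 2])
        true = _series([1, 1, 2, 2, 3, 3])
        assert match_clusters(est, true) == {3: "1", 1: "2", 2: "3"}

    def test_unmatched_cluster_goes_to_others(self):
        est = _series([1, 1, 2, 2, 5, 5])
        true = _series([1, 1, 2, 2, 4, 4])
        mapping = match_clusters(est, true)
        assert mapping[5] == "others"

    def test_total_overlap_equals_brute_force_maximum(self, rng):
        genes = [f"g{j}" for j in range(40)]
        est = _series(rng.integers(1, 5, size=40), genes)
        true = _series(rng.integers(1, 5, size=40), genes)
        mapping = match_clusters(est, true)
        achieved = sum(
            ((est == e) & (true.astype(str) == q)).sum()
            for e, q in mapping.items() if q != "others"
        )
        est_ids = sorted(est.unique())
        best = 0
        for perm in permutations(["1", "2", "3", None],
                                 min(4, len(est_ids))):
            total = sum(
                ((est == e) & (true.astype(str) == q)).sum()
                for e, q in zip(est_ids, perm) if q is not None
            )
            best = max(best, total)
        assert achieved == best


class TestEvaluateRecovery:
    def _perfect_result(self, truth):
        genes = truth.W_true.columns
        reported = truth.cluster_labels[truth.cluster_labels <= 3]
        return SimpleNamespace(
            coefficients=truth.W_true.copy(),
            cluster_table=pd.DataFrame(
                {"gene": reported.index, "cluster": reported.values}
            ),
        )

    def test_perfect_recovery_scores_one_everywhere(self, rng):
        genes = [f"g{j}" for j in range(40)]
        clusters = np.repeat([1, 2, 3, 4], 10)
        W = np.zeros((4, 40))
        pattern = {1: [0, 2], 2: [1], 3: [2], 4: []}
        for j, c in enumerate(clusters):
            W[pattern[c], j] = 1.0
        truth = _truth(W, clusters, genes)
        report = evaluate_recovery(self._perfect_result(truth), truth)
        vals = report.indexes()
        assert len(vals) == 10
        assert all(v == pytest.approx(1.0) for v in vals.values())

    def test_ari_matches_contingency_closed_form(self):
        genes = [f"g{j}" for j in range(9)]
        true = np.array([1, 1, 1, 2, 2, 2, 4, 4, 4])
        est_cluster = [1, 1, 2, 2, 2, 2]  # genes g0..g5 reported
        W = np.zeros((4, 9))
        W[0, :6] = 1.0
        truth = _truth(W, true, genes)
        res = SimpleNamespace(
            coefficients=truth.W_true.copy(),
            cluster_table=pd.DataFrame(
                {"gene": genes[:6], "cluster": est_cluster}
            ),
        )
        report = evaluate_recovery(res, truth)

        # independent closed-form ARI from the contingency table
        est_final = report_labels = None
        mapping = report.mapping
        est = ["others"] * 9
        for g, c in zip(genes[:6], est_cluster):
            est[genes.index(g)] = mapping[c]
        tru = ["others" if t == 4 else str(t) for t in true]

        def comb2(x):
            return x * (x - 1) / 2

        cats_e, cats_t = sorted(set(est)), sorted(set(tru))
        nij = np.array([[sum(1 for e, t in zip(est, tru) if e == a and t == b)
                         for b in cats_t] for a in cats_e])
        a_ = nij.sum(1)
        b_ = nij.sum(0)
        idx = comb2(nij).sum()
        exp = comb2(a_).sum() * comb2(b_).sum() / comb2(9)
        mx = (comb2(a_).sum() + comb2(b_).sum()) / 2
        assert report.ari == pytest.approx((idx - exp) / (mx - exp))

    def test_ari_invariant_to_label_permutation(self, rng):
        genes = [f"g{j}" for j in range(30)]
        clusters = rng.integers(1, 5, size=30)
        W = np.zeros((4, 30))
        W[0, clusters < 4] = 1.0
        truth = _truth(W, clusters, genes)
        reported = [g for g, c in zip(genes, clusters) if c < 4]
        labs = [int(c) for c in clusters[clusters < 4]]
        relabel = {1: 3, 2: 1, 3: 2}
        r1 = evaluate_recovery(SimpleNamespace(
            coefficients=truth.W_true.copy(),
            cluster_table=pd.DataFrame({"gene": reported, "cluster": labs}),
        ), truth)
        r2 = evaluate_recovery(SimpleNamespace(
            coefficients=truth.W_true.copy(),
            cluster_table=pd.DataFrame(
                {"gene": reported, "cluster": [relabel[c] for c in labs]}
            ),
        ), truth)
        assert r1.ari == pytest.approx(r2.ari)

    def test_pearson_counts_unreported_genes_as_zero(self):
        genes = ["g0", "g1", "g2", "g3"]
        clusters = [1, 2, 3, 4]
        W = np.zeros((4, 4))
        W[0, 0] = W[1, 1] = W[2, 2] = 1.0
        truth = _truth(W, clusters, genes)
        # estimate reports only g0; others contribute (0, w_true) pairs
        est_W = truth.W_true.copy()
        est_W.loc[:, ["g1", "g2", "g3"]] = 0.0
        res = SimpleNamespace(
            coefficients=est_W,
            cluster_table=pd.DataFrame({"gene": ["g0"], "cluster": [1]}),
        )
        report = evaluate_recovery(res, truth)
        v_est = est_W.values.ravel()
        v_true = truth.W_true.values.ravel()
        expected = np.corrcoef(v_est, v_true)[0, 1]
        assert report.pearson_r == pytest.approx(expected)

    def test_empty_estimated_cluster_precision_is_missing(self):
        genes = [f"g{j}" for j in range(8)]
        clusters = [1, 1, 2, 2, 3, 3, 4, 4]
        W = np.zeros((4, 8))
        W[0, :6] = 1.0
        truth = _truth(W, clusters, genes)
        res = SimpleNamespace(
            coefficients=truth.W_true.copy(),
            cluster_table=pd.DataFrame(
                {"gene": genes[:4], "cluster": [1, 1, 2, 2]}
            ),
        )
        report = evaluate_recovery(res, truth)
        assert report.precision["3"] is None
        assert report.recall["3"] == 0.0
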