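"""Similarity matrices, Ward clustering, gap statistic and cluster summaries."""

import numpy as np
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from lateralis import ontology as onto
from lateralis import phenoclust as pc
from lateralis import synthdata as synth


@pytest.fixture(scope="module")
def mini_closed(mini_graph):
    raw = synth.reference_cohort_annotations()
    return pc.apply_exclusions(raw, synth.EXCLUDED_NONSPECIFIC_TERMS, mini_graph)


@pytest.fixture(scope="module")
def mini_ic(mini_closed, mini_graph):
    return onto.compute_ic(mini_closed, mini_graph)


class TestExclusions:
    def test_excluded_terms_removed(self, mini_graph):
        raw = {"p1": {"CP:0000050", "CP:0000022"}, "p2": {"CP:0000027"}}
        closed = pc.apply_exclusions(raw, ["CP:0000050"], mini_graph)
        assert "CP:0000050" not in closed["p1"]
        assert "CP:0000022" in closed["p1"]

    def test_exclusion_by_name(self, mini_graph):
        raw = {"p1": {"CP:0000050", "CP:0000022"}}
        closed = pc.apply_exclusions(raw, ["ventricular septal defect"], mini_graph)
        assert "CP:0000050" not in closed["p1"]

    def test_empty_exclusion_is_identity_closure(self, mini_graph):
        raw = {"p1": {"CP:0000022"}, "p2": {"CP:0000027"}}
        closed = pc.apply_exclusions(raw, [], mini_graph)
        assert closed["p1"] == onto.annotation_closure({"CP:0000022"}, mini_graph)

    def test_fully_excluded_proband_raises(self, mini_graph):
        raw = {"p1": {"CP:0000050"}}
        with pytest.raises(pc.EmptyPhenotypeError, match="p1"):
            pc.apply_exclusions(raw, ["CP:0000050"], mini_graph)

    def test_unresolvable_exclusion_raises(self, mini_graph):
        with pytest.raises(KeyError):
            pc.apply_exclusions({"p1": {"CP:0000022"}}, ["no such term"],
                                mini_graph)


class TestSimilarityMatrix:
    def test_invariants(self, mini_closed, mini_ic, mini_graph):
        s = pc.build_similarity_matrix(mini_closed, mini_ic, mini_graph)
        assert np.allclose(s.values, s.values.T)
        assert np.allclose(np.diag(s.values), 1.0)
        assert s.values.min() >= 0.0 and s.values.max() <= 1.0

    def test_identical_sets_score_one(self, toy_graph, toy_ic):
        ann = {"a": onto.annotation_closure({"T:B"}, toy_graph),
               "b": onto.annotation_closure({"T:B"}, toy_graph)}
        s = pc.build_similarity_matrix(ann, toy_ic, toy_graph)
        assert s.values[0, 1] == 1.0

    def test_disjoint_branches_score_zero(self, toy_graph, toy_ic):
        ann = {"a": onto.annotation_closure({"T:B"}, toy_graph),
               "b": onto.annotation_closure({"T:E"}, toy_graph)}
        s = pc.build_similarity_matrix(ann, toy_ic, toy_graph)
        # shared closure terms are only the zero-IC root
        assert s.values[0, 1] < 0.5

    def test_single_proband_rejected(self, toy_graph, toy_ic):
        with pytest.raises(onto.OntologyError):
            pc.build_similarity_matrix(
                {"a": onto.annotation_closure({"T:B"}, toy_graph)},
                toy_ic, toy_graph)

    def test_distance_transform(self):
        s = pc.SimilarityMatrix(ids=["a", "b"],
                                values=np.array([[1.0, 0.25], [0.25, 1.0]]))
        d = pc.similarity_to_distance(s)
        assert d.values[0, 1] == 0.75
        assert d.values[0, 0] == 0.0


class TestWard:
    def test_two_points(self):
        d = np.array([[0.0, 0.6], [0.6, 0.0]])
        z = pc.ward_linkage(d)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.6)

    def test_matches_scipy_on_euclidean_data(self):
        """Independent oracle: scipy's Ward on tie-free Euclidean data."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.normal(size=(12, 3))
            cond = pdist(pts)
            z_ref = sch.linkage(cond, method="ward")
            z_own = pc.ward_linkage(squareform(cond))
            assert np.allclose(np.sort(z_own[:, 2]), np.sort(z_ref[:, 2]))
            for k in (2, 3, 4, 5):
                ref = sch.fcluster(z_ref, k, criterion="maxclust")
                own = pc.cut_clusters(z_own, list(range(12)), k)
                got = np.array([own.labels[i] for i in range(12)])
                # identical partitions up to label renaming
                pairs = {(a, b) for a, b in zip(ref, got)}
                assert len({a for a, _ in pairs}) == len(pairs) == \
                    len({b for _, b in pairs})

    def test_two_blobs_merge_internally_first(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(5, 0.1, (4, 2))])
        z = pc.ward_linkage(squareform(pdist(pts)))
        # the first 6 merges stay within blobs: both blobs complete before
        # the final cross-blob merge
        labels = pc.cut_clusters(z, list(range(8)), 2).labels
        assert len({labels[i] for i in range(4)}) == 1
        assert len({labels[i] for i in range(4, 8)}) == 1
        assert z[-1, 2] == max(z[:, 2])

    def test_heights_monotone(self, mini_closed, mini_ic, mini_graph):
        s = pc.build_similarity_matrix(mini_closed, mini_ic, mini_graph)
        z = pc.ward_linkage(pc.similarity_to_distance(s).values)
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pc.ward_linkage(d)

    def test_permutation_invariance_of_labels(self, mini_closed, mini_ic,
                                              mini_graph):
        s1 = pc.build_similarity_matrix(mini_closed, mini_ic, mini_graph)
        shuffled = dict(reversed(list(mini_closed.items())))
        s2 = pc.build_similarity_matrix(shuffled, mini_ic, mini_graph)
        a1 = pc.cut_clusters(pc.ward_linkage(
            pc.similarity_to_distance(s1).values), s1.ids, 5)
        a2 = pc.cut_clusters(pc.ward_linkage(
            pc.similarity_to_distance(s2).values), s2.ids, 5)
        assert a1.labels == a2.labels


class TestGapStatistic:
    def test_four_blobs_elbow_at_four(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]])
        pts = np.vstack([c + rng.normal(0, 0.4, size=(8, 2)) for c in centers])
        curve = pc.gap_statistic(squareform(pdist(pts)), kmax=10, n_refs=50,
                                 seed=1)
        assert pc.select_k(curve) == 4

    def test_single_cluster_prefers_k1(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, size=(25, 2))
        curve = pc.gap_statistic(squareform(pdist(pts)), kmax=8, n_refs=50,
                                 seed=2)
        assert pc.select_k(curve, rule="one_se") == 1
        # no pronounced gap increase after k=1
        assert curve.gap.max() - curve.gap[0] < 3 * curve.se.max()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        d = squareform(pdist(rng.normal(size=(15, 2))))
        c1 = pc.gap_statistic(d, kmax=6, n_refs=20, seed=9)
        c2 = pc.gap_statistic(d, kmax=6, n_refs=20, seed=9)
        assert np.array_equal(c1.gap, c2.gap) and np.array_equal(c1.se, c2.se)

    def test_kmax_bounds(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            pc.gap_statistic(d, kmax=4, n_refs=10, seed=0)


class TestSelectK:
    def _curve(self, gap):
        gap = np.asarray(gap, dtype=float)
        n = len(gap)
        return pc.GapCurve(k=np.arange(1, n + 1), log_w=np.zeros(n),
                           e_log_w=gap, gap=gap, se=np.full(n, 0.05),
                           n_refs=50, seed=0)

    def test_sharp_elbow(self):
        gap = [min(k, 4) + 0.05 * max(k - 4, 0) for k in range(1, 11)]
        assert pc.select_k(self._curve(gap)) == 4

    def test_linear_curve_warns_and_picks_smallest(self):
        with pytest.warns(UserWarning, match="elbow"):
            assert pc.select_k(self._curve(np.arange(10.0))) == 2

    def test_override(self):
        assert pc.select_k(self._curve(np.arange(10.0)), override=5) == 5


@pytest.fixture(scope="module")
def assignment(mini_closed, mini_ic, mini_graph):
    s = pc.build_similarity_matrix(mini_closed, mini_ic, mini_graph)
    z = pc.ward_linkage(pc.similarity_to_distance(s).values)
    return pc.cut_clusters(z, s.ids, 5), s


class TestCutAndSummaries:
    def test_k_extremes(self, assignment):
        a, s = assignment
        n = len(s.ids)
        one = pc.cut_clusters(a.linkage, s.ids, 1)
        assert set(one.labels.values()) == {1}
        alln = pc.cut_clusters(a.linkage, s.ids, n)
        assert len(set(alln.labels.values())) == n
        with pytest.raises(ValueError):
            pc.cut_clusters(a.linkage, s.ids, n + 1)

    def test_exactly_k_nonempty_clusters(self, assignment):
        a, _ = assignment
        assert sorted(set(a.labels.values())) == [1, 2, 3, 4, 5]

    def test_leaf_order_covers_all(self, assignment):
        a, s = assignment
        assert sorted(a.leaf_order) == sorted(s.ids)

    def test_term_frequencies(self, assignment, mini_closed):
        a, _ = assignment
        freqs = pc.cluster_term_frequencies(a, mini_closed)
        assert ((freqs.values >= 0) & (freqs.values <= 1)).all()
        # a term carried by every member of some cluster scores exactly 1
        lab = a.labels["CVG0006"]
        assert freqs.loc[lab, "CP:0000063"] == 1.0

    def test_cocluster_count(self, assignment):
        a, _ = assignment
        assert pc.cocluster_count(a, []) == 0
        members = a.members(a.labels["LAT0108"])
        assert pc.cocluster_count(a, members[:2]) == 2
        with pytest.raises(KeyError):
            pc.cocluster_count(a, ["NOPE"])

    def test_newick_export(self, assignment):
        a, s = assignment
        nwk = pc.linkage_to_newick(a.linkage, s.ids)
        assert nwk.endswith(";")
        import io
        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(s.ids)

    def test_heatmap_row_order_is_leaf_order(self, assignment, tmp_path):
        a, s = assignment
        order = pc.export_heatmap(s, a, tmp_path / "heat.png")
        assert order == a.leaf_order


class TestRecovery:
    def test_archetype_recovery_ari(self, mini_graph):
        """Synthetic 5-archetype cohorts are recovered nearly perfectly."""
        from sklearn.metrics import adjusted_rand_score

        for seed in (0, 1, 2):
            spec = synth.CohortSpec(n_probands=33, dropout=0.15, spurious=0.1,
                                    seed=seed)
            ann, truth = synth.gen_phenotype_cohort(spec)
            closed = {p: onto.annotation_closure(t, mini_graph)
                      for p, t in ann.items()}
            ic = onto.compute_ic(closed, mini_graph)
            s = pc.build_similarity_matrix(closed, ic, mini_graph)
            z = pc.ward_linkage(pc.similarity_to_distance(s).values)
            a = pc.cut_clusters(z, s.ids, 5)
            ari = adjusted_rand_score([truth[p] for p in s.ids],
                                      [a.labels[p] for p in s.ids])
            assert ari >= 0.9
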