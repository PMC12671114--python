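import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from gutcompass import (
    DistanceMatrix,
    GutcompassError,
    calinski_harabasz,
    enterotype_pipeline,
    jsd_distance,
    pam,
    pcoa,
)
from gutcompass.enterotypes import JSD_MAX
from gutcompass.io import collapse_to_rank
from gutcompass.simulate import enterotype_benchmark_spec, simulate_cohorts
from tests.test_transforms import make_table


def exhaustive_pam_cost(d, k):
    n = d.shape[0]
    return min(d[:, list(c)].min(axis=1).sum()
               for c in itertools.combinations(range(n), k))


class TestJsd:
    def test_identical_rows_give_zero(self):
        D = jsd_distance(make_table([[30, 70], [30, 70]]))
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_support_hits_upper_bound(self):
        D = jsd_distance(make_table([[100, 0], [0, 100]]))
        assert D.values[0, 1] == pytest.approx(np.sqrt(np.log(2)), abs=1e-9)

    def test_hand_evaluated_entropies(self):
        # P=(.5,.5), Q=(1,0): H(M)=0.56233, H(P)=ln 2, d=sqrt(0.21576)
        D = jsd_distance(make_table([[50, 50], [100, 0]]))
        assert D.values[0, 1] == pytest.approx(np.sqrt(0.215761), abs=1e-5)

    def test_metric_axioms_on_random_triples(self, rng):
        P = rng.dirichlet(np.ones(10), size=3000).reshape(1000, 3, 10)
        for triple in P[:1000]:
            d = squareform(pdist(triple, metric="jensenshannon"))
            assert np.allclose(d, d.T)
            assert (np.diag(d) == 0).all()
            assert (d <= JSD_MAX + 1e-12).all()
            assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12


class TestPam:
    def test_line_example(self):
        pts = np.array([0, 0.1, 0.2, 10, 10.1, 10.2])
        d = np.abs(pts[:, None] - pts[None, :])
        medoids, assign, cost = pam(d, 2, restarts=1, seed=0)
        assert set(pts[medoids]) == {0.1, 10.1}
        assert set(assign[:3]) != set(assign[3:])
        assert cost == pytest.approx(0.4)

    def test_matches_exhaustive_optimum(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 9))
            k = int(rng.choice([2, 3]))
            pts = rng.standard_normal((n, 2))
            d = squareform(pdist(pts))
            _, _, cost = pam(d, k, restarts=10, seed=rng)
            assert cost == pytest.approx(exhaustive_pam_cost(d, k), abs=1e-9)

    def test_all_zero_distances_degenerate(self):
        d = np.zeros((5, 5))
        medoids, assign, cost = pam(d, 2, restarts=1, seed=0)
        assert cost == 0.0
        assert len(medoids) == 2

    def test_invalid_k_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(GutcompassError):
            pam(d, 4, restarts=1, seed=0)

    def test_deterministic_given_seed(self, rng):
        pts = rng.standard_normal((30, 2))
        d = squareform(pdist(pts))
        r1 = pam(d, 3, restarts=10, seed=11)
        r2 = pam(d, 3, restarts=10, seed=11)
        assert (r1[0] == r2[0]).all() and (r1[1] == r2[1]).all()


class TestCalinskiHarabasz:
    def test_scale_invariance_and_relabeling(self, rng):
        coords = rng.standard_normal((40, 3))
        labels = rng.integers(0, 3, 40)
        ch = calinski_harabasz(coords, labels)
        assert calinski_harabasz(coords * 2, labels) == pytest.approx(ch)
        relabeled = (labels + 1) % 3
        assert calinski_harabasz(coords, relabeled) == pytest.approx(ch)

    def test_separated_clusters_peak_at_true_k(self, rng):
        centers = np.array([[0, 0], [50, 0], [0, 50]])
        labels = np.repeat([0, 1, 2], 30)
        coords = centers[labels] + rng.standard_normal((90, 2))
        d = squareform(pdist(coords))
        chs = {}
        for k in range(2, 6):
            _, assign, _ = pam(d, k, restarts=5, seed=0)
            chs[k] = calinski_harabasz(coords, assign)
        assert max(chs, key=chs.get) == 3

    def test_singletons_rejected(self, rng):
        coords = rng.standard_normal((4, 2))
        with pytest.raises(GutcompassError):
            calinski_harabasz(coords, np.arange(4))


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        D = DistanceMatrix(["a", "b", "c"], d, "euclidean")
        coords, eigval = pcoa(D)
        pos = eigval[eigval > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        rec = squareform(pdist(coords.to_numpy()))
        assert np.allclose(rec, d, atol=1e-9)

    def test_euclidean_exactness(self, rng):
        pts = rng.standard_normal((12, 4))
        d = squareform(pdist(pts))
        D = DistanceMatrix(list(map(str, range(12))), d, "euclidean")
        coords, _ = pcoa(D)
        assert np.allclose(squareform(pdist(coords.to_numpy())), d, atol=1e-9)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.standard_normal((10, 3))
        d = squareform(pdist(pts))
        D = DistanceMatrix(list(map(str, range(10))), d, "euclidean")
        coords, eigval = pcoa(D)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        npos = coords.shape[1]
        assert np.allclose(np.sort(eigval[:npos]),
                           np.sort(ref.eigvals.to_numpy()[:npos]), atol=1e-8)

    def test_truncation_warning(self, rng):
        d = np.ones((3, 3)) - np.eye(3)
        D = DistanceMatrix(["a", "b", "c"], d, "euclidean")
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords, _ = pcoa(D, m=3)
        assert coords.shape[1] == 2


class TestEnterotypePipeline:
    def test_planted_recovery_and_forced_k(self):
        spec = enterotype_benchmark_spec(seed=2)
        table, _, truth = simulate_cohorts(spec)
        genus = collapse_to_rank(table, "genus")
        res = enterotype_pipeline(genus, k_range=range(2, 6), restarts=5, seed=0)
        assert res.chosen_k == 3
        ari = adjusted_rand_score(truth.enterotype_labels.to_numpy(),
                                  res.assignments.to_numpy())
        assert ari >= 0.9
        forced = enterotype_pipeline(genus, k_range=range(2, 6), restarts=5,
                                     seed=0, force_k=5)
        assert forced.assignments.nunique() == 5
        assert forced.ch_by_k == res.ch_by_k

    def test_top_genus_is_planted_driver(self):
        spec = enterotype_benchmark_spec(seed=4)
        table, _, truth = simulate_cohorts(spec)
        genus = collapse_to_rank(table, "genus")
        res = enterotype_pipeline(genus, k_range=range(2, 5), restarts=5, seed=0)
        top1 = res.top_genera[res.top_genera["rank"] == 1]
        # each recovered cluster's dominant genus should dominate its
        # members' profiles (the planted driver structure)
        for _, row in top1.iterrows():
            members = genus.data.loc[res.assignments == row["cluster"]]
            assert members.median(axis=0).idxmax() == row["genus"]
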