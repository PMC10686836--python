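"""Pattern scoring, weighted-median selection, clustering and embedding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from swarmspec.basis import evaluate_design
from swarmspec.domain import ScaledCoordinate
from swarmspec.patterns import (
    PatternScores,
    cluster,
    cosine_similarity,
    elbow_curve,
    mds_embed,
    neighbor_functions,
    rescale,
    scores,
    select,
)


@pytest.fixture(scope="module")
def design(basis6):
    rs = np.random.default_rng(11)
    t = rs.uniform(0, 2.0, 90)
    p = rs.uniform(0, 1, 90) * np.exp(t)
    return evaluate_design(basis6, [ScaledCoordinate(a, b, True) for a, b in zip(t, p)])


def fit_rows(G, design):
    return np.linalg.lstsq(design, G.T, rcond=None)[0].T


class TestRescale:
    def test_constant_gene_flagged_and_k_zero(self, basis6, design):
        G = np.vstack([np.full(90, 6.0), design @ [1, 2, 0, 0, 0, 0]])
        c = fit_rows(G, design)
        r = rescale(c, G, basis6.p0)
        assert r.constant[0] and not r.constant[1]
        assert np.allclose(r.k[0], 0.0)
        # mean-equal gene: k0 = c0 - mu/p0 = 0 exactly
        assert r.k[1][0] == pytest.approx(
            (c[1, 0] - G[1].mean() / basis6.p0) / G[1].std())

    def test_scaling_expression_leaves_k_unchanged(self, basis6, design, rng):
        G = rng.normal(5, 1, (4, 90))
        c = fit_rows(G, design)
        r1 = rescale(c, G, basis6.p0)
        r2 = rescale(fit_rows(3.0 * G, design), 3.0 * G, basis6.p0)
        assert np.allclose(r1.k, r2.k, atol=1e-10)

    def test_shift_leaves_higher_modes_unchanged(self, basis6, design, rng):
        G = rng.normal(5, 1, (4, 90))
        r1 = rescale(fit_rows(G, design), G, basis6.p0)
        r2 = rescale(fit_rows(G + 2.5, design), G + 2.5, basis6.p0)
        assert np.allclose(r1.k[:, 1:], r2.k[:, 1:], atol=1e-10)
        assert np.allclose(r1.k[:, 0], r2.k[:, 0], atol=1e-10)


class TestScores:
    def test_exact_basis_pattern_gets_infinite_sentinel(self, basis6, design):
        mu, sd = 5.0, 1.3
        G = (mu + sd * design @ [0, 1, 0, 0, 0, 0])[None, :]
        r = rescale(fit_rows(G, design), G, basis6.p0)
        sc = scores(G, r, design)
        assert np.isinf(sc.R[0])

    def test_flat_gene_scores_zero(self, basis6, design):
        G = np.full((1, 90), 4.0)
        r = rescale(fit_rows(G, design), G, basis6.p0)
        sc = scores(G, r, design)
        assert sc.P[0] == 0.0 and sc.R[0] == 0.0

    def test_noise_gene_has_small_pattern_score(self, basis6, design, rng):
        G = rng.normal(0, 1, (1, 90))
        r = rescale(fit_rows(G, design), G, basis6.p0)
        sc = scores(G, r, design)
        assert sc.P[0] < 0.5 and sc.R[0] < 0.1

    def test_affine_invariance_of_ranking(self, basis6, design, rng):
        G = rng.normal(5, 1, (6, 90))
        base = scores(G, rescale(fit_rows(G, design), G, basis6.p0), design)
        for _ in range(5):
            a = rng.uniform(0.2, 5.0)
            b = rng.uniform(-10, 10)
            H = a * G + b
            sc = scores(H, rescale(fit_rows(H, design), H, basis6.p0), design)
            assert np.allclose(sc.R, base.R, rtol=1e-8)


def brute_force_select(R):
    """Direct enumeration of the weighted-median rule."""
    order = np.argsort(R, kind="stable")
    total = R.sum()
    n_c = 0
    for j in range(1, len(R) + 1):
        if R[order[:j]].sum() / total <= 0.5:
            n_c = j
    sel = np.zeros(len(R), bool)
    sel[order[n_c:]] = True
    return sel


class TestSelect:
    @pytest.mark.parametrize("R,expected_n", [
        ((1.0, 1.0, 1.0, 1.0), 2),
        ((0.0, 0.0, 0.0, 10.0), 1),
        ((1.0,), 1),
        ((0.3, 0.3, 0.4), 2),   # cumulative fractions 0.3, 0.6 -> N_c = 1
        ((5.0, 1.0, 1.0, 1.0, 1.0, 1.0), 1),
    ])
    def test_matches_brute_force_enumeration(self, R, expected_n):
        R = np.array(R)
        sc = PatternScores(E=np.ones_like(R), P=R, R=R,
                           gene_ids=[f"g{i}" for i in range(len(R))])
        sel = select(sc)
        assert sel.sum() == expected_n
        assert np.array_equal(sel, brute_force_select(R))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1e6,
                              allow_nan=False), min_size=1, max_size=30))
    def test_any_nonnegative_vector_matches_brute_force(self, values):
        R = np.array(values)
        sc = PatternScores(E=np.ones_like(R), P=R, R=R,
                           gene_ids=[str(i) for i in range(len(R))])
        assert np.array_equal(select(sc), brute_force_select(R) if R.sum() > 0
                              else np.zeros(len(R), bool))

    def test_random_vectors_match_brute_force(self, rng):
        for _ in range(25):
            R = rng.gamma(1.0, 1.0, rng.integers(2, 40))
            sc = PatternScores(E=np.ones_like(R), P=R, R=R,
                               gene_ids=[str(i) for i in range(len(R))])
            assert np.array_equal(select(sc), brute_force_select(R))

    def test_selected_mass_at_least_half(self, rng):
        R = rng.gamma(0.5, 2.0, 200)
        sc = PatternScores(E=np.ones_like(R), P=R, R=R,
                           gene_ids=[str(i) for i in range(200)])
        sel = select(sc)
        assert R[sel].sum() / R.sum() >= 0.5

    def test_all_zero_scores_select_nothing(self):
        sc = PatternScores(E=np.ones(3), P=np.zeros(3), R=np.zeros(3),
                           gene_ids=list("abc"))
        assert select(sc).sum() == 0

    def test_infinite_sentinels_always_selected(self):
        R = np.array([np.inf, 0.1, 0.1, 0.1, np.inf])
        sc = PatternScores(E=np.ones(5), P=R, R=R, gene_ids=list("abcde"))
        sel = select(sc)
        assert sel[0] and sel[4]


class TestCosineSimilarity:
    def test_identical_opposite_orthogonal(self):
        k = np.array([[0, 1, 0, 0], [0, 1, 0, 0], [0, -1, 0, 0], [0, 0, 1, 0]])
        d = cosine_similarity(k)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 2] == pytest.approx(-1.0)
        assert d[0, 3] == pytest.approx(0.0)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 1.0)

    def test_constant_mode_excluded(self):
        k = np.array([[5.0, 1, 0], [-7.0, 1, 0]])
        assert cosine_similarity(k)[0, 1] == pytest.approx(1.0)

    def test_zero_vector_warns_and_nans(self):
        k = np.array([[1.0, 0, 0], [0, 1, 0]])
        with pytest.warns(RuntimeWarning):
            d = cosine_similarity(k)
        assert np.isnan(d[0, 1])


def family_sim(rng, n_per=12, n_fam=3, jitter=0.05):
    ks = []
    labels = []
    for f in range(n_fam):
        tpl = np.zeros(5)
        tpl[f] = 1.0
        for _ in range(n_per):
            ks.append(np.concatenate([[0.0], tpl + rng.normal(0, jitter, 5)]))
            labels.append(f)
    k = np.array(ks)
    return cosine_similarity(k), np.array(labels), k


class TestClustering:
    def test_two_separated_families_recovered_exactly(self, rng):
        sim, labels, _ = family_sim(rng, n_fam=2)
        cl = cluster(sim, 2, seed=0)
        assert adjusted_rand_score(labels, cl.labels) == 1.0

    def test_duplicate_gene_co_clusters(self, rng):
        sim, labels, k = family_sim(rng, n_fam=3)
        k2 = np.vstack([k, k[0]])
        sim2 = cosine_similarity(k2)
        cl = cluster(sim2, 3, seed=0)
        assert cl.labels[-1] == cl.labels[0]

    def test_medoid_minimizes_summed_distance(self, rng):
        sim, labels, _ = family_sim(rng)
        cl = cluster(sim, 3, seed=0)
        dist = 1.0 - sim
        for ci, m in enumerate(cl.medoids):
            members = np.flatnonzero(cl.labels == ci)
            best = min(members, key=lambda j: dist[np.ix_(members, [j])].sum())
            assert dist[np.ix_(members, [m])].sum() <= dist[np.ix_(members, [best])].sum() + 1e-12

    def test_cost_non_increasing_in_k(self, rng):
        sim, _, _ = family_sim(rng, n_per=8)
        costs = elbow_curve(sim, range(2, 10), seed=0)
        vals = [costs[k] for k in sorted(costs)]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_cost_zero_at_k_equals_n(self, rng):
        sim, _, _ = family_sim(rng, n_per=3, n_fam=2)
        n = sim.shape[0]
        assert cluster(sim, n, seed=0).cost == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        sim, _, _ = family_sim(rng)
        cl1 = cluster(sim, 3, seed=0)
        perm = rng.permutation(sim.shape[0])
        cl2 = cluster(sim[np.ix_(perm, perm)], 3, seed=0)
        assert adjusted_rand_score(cl1.labels[perm], cl2.labels) == 1.0

    def test_too_many_clusters_rejected(self, rng):
        sim, _, _ = family_sim(rng, n_per=2, n_fam=2)
        with pytest.raises(ValueError):
            cluster(sim, 10, seed=0)


class TestMDS:
    def test_identical_items_coincide(self, rng):
        k = np.array([[0, 1, 0.0], [0, 1, 0.0], [0, 0, 1.0]])
        sim = cosine_similarity(k)
        coords, _ = mds_embed(sim, seed=0)
        assert np.linalg.norm(coords[0] - coords[1]) < 1e-6

    def test_three_equidistant_items_form_equilateral_triangle(self):
        sim = np.full((3, 3), 0.5)
        np.fill_diagonal(sim, 1.0)
        coords, _ = mds_embed(sim, seed=0)
        d = [np.linalg.norm(coords[i] - coords[j])
             for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(d, d[0], rtol=1e-4)

    def test_distance_rank_correlation_on_families(self, rng):
        sim, _, _ = family_sim(rng)
        coords, _ = mds_embed(sim, seed=0)
        n = sim.shape[0]
        iu = np.triu_indices(n, 1)
        emb = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
        rho = spearmanr((1 - sim)[iu], emb).statistic
        assert rho > 0.8

    def test_deterministic_given_seed(self, rng):
        sim, _, _ = family_sim(rng)
        c1, s1 = mds_embed(sim, seed=3)
        c2, s2 = mds_embed(sim, seed=3)
        assert np.array_equal(c1, c2) and s1 == s2


class TestNeighborFunctions:
    def test_single_nearest_neighbor_category(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0]])
        table = {"a": "metabolism", "b": "motility", "c": "motility"}
        counts = neighbor_functions(coords, [0.1, 0.0], ["a", "b", "c"], table,
                                    n=1, min_category_size=1)
        assert counts == {"metabolism": 1}

    def test_counts_sum_to_n_and_small_categories_merge(self, rng):
        coords = rng.normal(size=(60, 2))
        ids = [f"g{i}" for i in range(60)]
        table = {g: ("metabolism" if i < 40 else f"rare{i}") for i, g in enumerate(ids)}
        counts = neighbor_functions(coords, [0, 0], ids, table, n=50)
        assert sum(counts.values()) == 50
        assert set(counts) <= {"metabolism", "other"}

    def test_modal_category_of_adjacent_cluster(self, rng):
        near = rng.normal(0, 0.1, (30, 2))
        far = rng.normal(5, 0.1, (30, 2))
        coords = np.vstack([near, far])
        ids = [f"g{i}" for i in range(60)]
        table = {g: ("metabolism" if i < 30 else "motility") for i, g in enumerate(ids)}
        counts = neighbor_functions(coords, [0, 0], ids, table, n=30)
        assert max(counts, key=counts.get) == "metabolism"

    def test_n_exceeding_gene_count_rejected(self):
        with pytest.raises(ValueError):
            neighbor_functions(np.zeros((3, 2)), [0, 0], list("abc"), {}, n=5)
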