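import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from sigstrat import (
    SENTINEL,
    ClusteringConfig,
    MixtureSpec,
    ParameterError,
    ValidationError,
    cluster,
    compute_delta,
    compute_rho,
    select_prototypes,
    simulate_mixture,
)


# ---------------------------------------------------------------------------
# brute-force oracles, kept deliberately dumb and independent of the package

def oracle_rho(D, dc, kernel):
    n = len(D)
    rho = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if kernel == "hard":
                rho[i] += 1.0 if D[i, j] < dc else 0.0
            else:
                rho[i] += np.exp(-((D[i, j] / dc) ** 2))
    return rho


def oracle_delta(D, rho):
    # total density order: rho desc, index asc
    n = len(D)
    delta = np.zeros(n)
    nearest = np.zeros(n, dtype=int)
    def denser(j, i):
        return rho[j] > rho[i] or (rho[j] == rho[i] and j < i)
    for i in range(n):
        best, who = np.inf, SENTINEL
        for j in range(n):
            if j != i and denser(j, i) and (D[i, j] < best):
                best, who = D[i, j], j
        if who == SENTINEL:
            best = max(D[i, j] for j in range(n) if j != i)
        delta[i], nearest[i] = best, who
    return delta, nearest


def triangle_distances():
    # three points mutually at distance 1
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    return squareform(pdist(pts))


class TestComputeRho:
    def test_all_within_radius(self):
        D = triangle_distances()
        cfg = ClusteringConfig(dc_mode="absolute", dc_value=1.5)
        np.testing.assert_array_equal(compute_rho(D, cfg), [2.0, 2.0, 2.0])

    def test_none_within_radius(self):
        D = triangle_distances()
        cfg = ClusteringConfig(dc_mode="absolute", dc_value=0.5)
        np.testing.assert_array_equal(compute_rho(D, cfg), [0.0, 0.0, 0.0])

    @pytest.mark.parametrize("kernel", ["hard", "gaussian"])
    def test_matches_oracle(self, rng, kernel):
        X = rng.normal(size=(50, 2))
        D = squareform(pdist(X))
        cfg = ClusteringConfig(kernel=kernel)
        from sigstrat.density_peaks import resolve_dc

        dc = resolve_dc(D, cfg)
        np.testing.assert_allclose(compute_rho(D, cfg), oracle_rho(D, dc, kernel),
                                   rtol=0, atol=1e-12)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            compute_rho(D, ClusteringConfig())

    def test_negative_rejected(self):
        D = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValidationError):
            compute_rho(D, ClusteringConfig())

    def test_permutation_equivariant(self, rng):
        X = rng.normal(size=(40, 3))
        D = squareform(pdist(X))
        cfg = ClusteringConfig(kernel="gaussian")
        rho = compute_rho(D, cfg)
        perm = rng.permutation(40)
        rho_p = compute_rho(D[np.ix_(perm, perm)], cfg)
        np.testing.assert_allclose(rho_p, rho[perm], atol=1e-12)


class TestComputeDelta:
    def test_global_max_gets_max_distance(self, rng):
        X = rng.normal(size=(20, 2))
        D = squareform(pdist(X))
        rho = compute_rho(D, ClusteringConfig(kernel="gaussian"))
        delta, nearest = compute_delta(D, rho)
        top = int(np.argmax(rho))
        assert nearest[top] == SENTINEL
        assert delta[top] == D[top].max()

    def test_two_points(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        delta, nearest = compute_delta(D, np.array([5.0, 1.0]))
        np.testing.assert_array_equal(delta, [3.0, 3.0])
        assert nearest[0] == SENTINEL and nearest[1] == 0

    def test_rho_tie_breaks_by_index(self):
        D = triangle_distances()
        delta, nearest = compute_delta(D, np.zeros(3))
        assert nearest[0] == SENTINEL  # lowest index treated as densest
        assert nearest[1] == 0 and nearest[2] == 0

    def test_matches_oracle(self, rng):
        X = rng.normal(size=(50, 3))
        D = squareform(pdist(X))
        rho = compute_rho(D, ClusteringConfig())
        delta, nearest = compute_delta(D, rho)
        od, on = oracle_delta(D, rho)
        np.testing.assert_allclose(delta, od, atol=1e-12)
        np.testing.assert_array_equal(nearest, on)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_delta(triangle_distances(), np.zeros(2))


class TestSelectPrototypes:
    def test_fixed_k_takes_top_gamma(self, rng):
        rho = rng.random(30)
        delta = rng.random(30)
        cfg = ClusteringConfig(selection="fixed_k", k=3)
        chosen = select_prototypes(rho, delta, cfg)
        from sigstrat.density_peaks import _minmax

        gamma = _minmax(rho) * _minmax(delta)
        assert chosen == list(np.argsort(-gamma)[:3])

    def test_fixed_k_too_large(self):
        with pytest.raises(ParameterError):
            select_prototypes(np.ones(3), np.ones(3), ClusteringConfig(selection="fixed_k", k=4))

    def test_identical_points_single_prototype(self):
        X = np.zeros((10, 2))
        res = cluster(X, ClusteringConfig())
        assert res.n_clusters == 1
        assert set(res.labels) == {0}

    def test_two_blob_gap_detection(self):
        hits = 0
        for seed in range(100):
            cohort, truth = simulate_mixture(
                MixtureSpec(n_points=100, n_dims=2, n_clusters=2, separation=10.0, seed=seed)
            )
            res = cluster(cohort.matrix("t1"), ClusteringConfig())
            if res.n_clusters == 2 and len({truth[p] for p in res.prototypes}) == 2:
                hits += 1
        assert hits >= 95

    def test_at_least_one_prototype(self, rng):
        rho = rng.random(12)
        delta = rng.random(12)
        for cfg in (ClusteringConfig(), ClusteringConfig(selection="threshold",
                                                         threshold_multiplier=100.0)):
            assert len(select_prototypes(rho, delta, cfg)) >= 1


class TestCluster:
    def test_two_distant_pairs(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
        res = cluster(X, ClusteringConfig(selection="fixed_k", k=2))
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]
        # brute-force nearest-prototype check
        for i in range(4):
            dists = [np.linalg.norm(X[i] - X[p]) for p in res.prototypes]
            assert res.labels[i] == int(np.argmin(dists))

    def test_duplicated_points_same_partition(self, rng):
        X = rng.normal(size=(12, 2))
        X[6:] = X[:6] + np.array([8.0, 0.0])  # two clear groups
        cfg = ClusteringConfig(selection="fixed_k", k=2)
        base = cluster(X, cfg)
        dup = cluster(np.vstack([X, X]), cfg)
        proto_coords = {tuple(np.round(X[p], 9)) for p in base.prototypes}
        dup_coords = {tuple(np.round(np.vstack([X, X])[p], 9)) for p in dup.prototypes}
        assert proto_coords == dup_coords
        np.testing.assert_array_equal(dup.labels[:12], dup.labels[12:])
        # same partition as the original up to label names
        for a in range(12):
            for b in range(12):
                assert (base.labels[a] == base.labels[b]) == (dup.labels[a] == dup.labels[b])

    def test_deterministic(self, rng):
        X = rng.normal(size=(60, 4))
        r1 = cluster(X, ClusteringConfig())
        r2 = cluster(X, ClusteringConfig())
        np.testing.assert_array_equal(r1.rho, r2.rho)
        np.testing.assert_array_equal(r1.delta, r2.delta)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.prototypes == r2.prototypes
        assert r1.dc == r2.dc

    def test_labels_partition_and_prototype_ownership(self, rng):
        X = rng.normal(size=(80, 3))
        res = cluster(X, ClusteringConfig(selection="fixed_k", k=4))
        assert len(res.labels) == 80
        assert set(res.labels) == set(range(res.n_clusters))
        for rank, p in enumerate(res.prototypes):
            assert res.labels[p] == rank

    def test_nonprototype_delta_below_lowest_prototype_delta(self):
        # fixed_k on well-separated blobs with continuous densities (no ties)
        cohort, _ = simulate_mixture(
            MixtureSpec(n_points=80, n_dims=2, n_clusters=2, separation=12.0, seed=5)
        )
        X = cohort.matrix("t1")
        res = cluster(X, ClusteringConfig(kernel="gaussian", selection="fixed_k", k=2))
        # strict gamma ordering at the top (no ties among candidate peaks)
        top = np.sort(res.gamma)[-10:]
        assert len(set(top)) == len(top)
        proto_delta = min(res.delta[p] for p in res.prototypes)
        others = [i for i in range(len(X)) if i not in res.prototypes]
        assert max(res.delta[i] for i in others) <= proto_delta

    def test_chain_assignment_agrees_on_spherical_blobs(self):
        cohort, truth = simulate_mixture(
            MixtureSpec(n_points=100, n_dims=2, n_clusters=2, separation=12.0, seed=3)
        )
        X = cohort.matrix("t1")
        near = cluster(X, ClusteringConfig(selection="fixed_k", k=2))
        chain = cluster(X, ClusteringConfig(selection="fixed_k", k=2, assign="chain"))
        agree = np.mean(near.labels == chain.labels)
        assert agree >= 0.95

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            cluster(np.zeros((1, 2)), ClusteringConfig())

    def test_nonfinite_rejected(self):
        X = np.zeros((3, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValidationError):
            cluster(X, ClusteringConfig())


class TestConfigValidation:
    def test_fraction_out_of_range(self):
        with pytest.raises(ParameterError):
            ClusteringConfig(dc_value=1.5)

    def test_absolute_nonpositive(self):
        with pytest.raises(ParameterError):
            ClusteringConfig(dc_mode="absolute", dc_value=0.0)

    def test_k_requires_fixed_k(self):
        with pytest.raises(ParameterError):
            ClusteringConfig(k=3)

    def test_fixed_k_requires_k(self):
        with pytest.raises(ParameterError):
            ClusteringConfig(selection="fixed_k")
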