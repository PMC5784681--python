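import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from contactfold.fixtures import FixtureSpec, make_native, true_contacts
from contactfold.io_formats import Contact, Model, SequenceRecord
from contactfold.selection import (
    ScoredModel,
    cluster_models,
    filter_pool,
    satisfaction_score,
    select_by_satisfaction_only,
    select_top5,
    tm_score,
    tm_d0,
)


def lr_contacts(pairs, probs=None):
    probs = probs or [0.9] * len(pairs)
    cs = [Contact(i=i, j=j, lower=0, upper=8, prob=p)
          for (i, j), p in zip(pairs, probs)]
    return sorted(cs, key=lambda c: (-c.prob, c.i, c.j))


def model_with_pair_distances(L, pair_dists):
    """Chain-agnostic model where cb[i], cb[j] sit at given distances."""
    seq = SequenceRecord(id="m", residues="A" * L)
    ca = np.zeros((L, 3))
    ca[:, 0] = np.arange(L) * 50.0  # residues far apart by default
    cb = ca.copy()
    for (i, j), d in pair_dists.items():
        cb[j - 1] = cb[i - 1] + (d, 0.0, 0.0)
    return Model(seq, ca, cb)


class TestSatisfactionScore:
    def test_all_satisfied(self):
        L = 50
        contacts = lr_contacts([(1, 30), (2, 40), (3, 45)])
        m = model_with_pair_distances(L, {(1, 30): 5.0, (2, 40): 5.0, (3, 45): 5.0})
        assert satisfaction_score(m, contacts, L) == 1.0

    def test_half_satisfied(self):
        L = 50
        contacts = lr_contacts([(1, 30), (2, 40)])
        m = model_with_pair_distances(L, {(1, 30): 5.0, (2, 40): 20.0})
        assert satisfaction_score(m, contacts, L) == 0.5

    def test_window_size_is_ceil_L_over_5(self, bundle):
        L = 100
        pairs = [(i, i + 30) for i in range(1, 60)]
        probs = list(np.linspace(0.99, 0.4, len(pairs)))
        contacts = lr_contacts(pairs, probs)
        # model satisfying only the top 20: score must be exactly 1.0,
        # proving only ceil(100/5) = 20 are evaluated
        sat_pairs = {(c.i, c.j): 5.0 for c in contacts[:20]}
        m = model_with_pair_distances(L, sat_pairs)
        assert satisfaction_score(m, contacts, L) == 1.0

    def test_no_long_range_contacts_returns_zero(self):
        L = 50
        contacts = lr_contacts([(1, 10)])  # separation 9 < 24
        m = model_with_pair_distances(L, {})
        assert satisfaction_score(m, contacts, L) == 0.0

    def test_window_L_over_2(self):
        L = 100
        pairs = [(i, i + 40) for i in range(1, 56)]
        contacts = lr_contacts(pairs, list(np.linspace(0.99, 0.4, len(pairs))))
        sat_pairs = {(c.i, c.j): 5.0 for c in contacts[:50]}
        m = model_with_pair_distances(L, sat_pairs)
        assert satisfaction_score(m, contacts, L, window=2.0) == 1.0


class TestTmScore:
    def test_identical_models(self, bundle):
        _, native, _ = bundle
        assert tm_score(native, native) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_rigid_motion_invariance(self, bundle, seed):
        _, native, _ = bundle
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        t = rng.normal(0, 30, 3)
        moved = Model(native.sequence, native.ca @ R.T + t, native.cb @ R.T + t)
        assert tm_score(native, moved) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry(self, bundle):
        _, native, _ = bundle
        rng = np.random.default_rng(1)
        other = Model(native.sequence,
                      native.ca + rng.normal(0, 2.0, native.ca.shape), native.cb)
        assert tm_score(native, other) == pytest.approx(tm_score(other, native), abs=1e-6)

    def test_d0_formula(self):
        assert tm_d0(48) == pytest.approx(1.24 * 33 ** (1 / 3) - 1.8)
        assert tm_d0(10) == 0.5  # floored for tiny chains

    def test_length_mismatch(self, bundle):
        _, native, _ = bundle
        short = Model(SequenceRecord(id="s", residues="AAA"),
                      np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            tm_score(native, short)

    def test_agrees_with_global_search_oracle(self, bundle):
        """Independent oracle: multi-start local optimization over rigid
        motions maximizing the TM objective directly."""
        from scipy.optimize import minimize

        _, native, _ = bundle
        L = len(native)
        d0 = tm_d0(L)
        rng = np.random.default_rng(0)

        def oracle(ma, mb, n_starts=12, seed=0):
            P = ma.ca - ma.ca.mean(0)
            Q = mb.ca - mb.ca.mean(0)

            def neg_tm(x):
                R = Rotation.from_rotvec(x[:3]).as_matrix()
                d2 = np.sum((P @ R.T + x[3:] - Q) ** 2, axis=1)
                return -np.mean(1.0 / (1.0 + d2 / d0**2))

            best = 0.0
            for s in range(n_starts):
                x0 = np.concatenate([
                    Rotation.random(random_state=np.random.RandomState(seed * 100 + s)).as_rotvec(),
                    np.zeros(3)])
                res = minimize(neg_tm, x0, method="Powell",
                               options={"maxiter": 1500, "xtol": 1e-6, "ftol": 1e-9})
                best = max(best, -res.fun)
            return best

        for k, sigma in enumerate((0.5, 1.5, 3.0)):
            other = Model(native.sequence,
                          native.ca + rng.normal(0, sigma, native.ca.shape), native.cb)
            mine = tm_score(native, other)
            ref = oracle(native, other, seed=k)
            assert mine == pytest.approx(ref, abs=0.01)


def make_planted_groups(L=40, n_groups=5, per_group=6, noise=0.5, seed=0):
    """Well-separated conformations with tight within-group ensembles."""
    from contactfold.folding import initialize_chain

    rng = np.random.default_rng(seed)
    models, labels = [], []
    order = 0
    for g in range(n_groups):
        base = initialize_chain(L, seed=1000 + 37 * g)
        for d in range(per_group):
            ca = base.ca + rng.normal(0, noise, base.ca.shape)
            m = Model(base.sequence, ca, ca.copy(), label=f"g{g}d{d}")
            models.append(ScoredModel(model=m, e_contact=float(g), order=order))
            labels.append(g)
            order += 1
    return models, labels


class TestClusterModels:
    def test_recovers_planted_partition(self):
        models, labels = make_planted_groups()
        res = cluster_models(models, k=5)
        # adjusted agreement must be exact: same partition up to relabelling
        from collections import defaultdict

        by_cluster = defaultdict(set)
        for idx, cid in enumerate(res.assignments):
            by_cluster[cid].add(labels[idx])
        assert all(len(v) == 1 for v in by_cluster.values())
        assert len(by_cluster) == 5

    def test_centroids_belong_to_their_cluster(self):
        models, _ = make_planted_groups()
        res = cluster_models(models, k=5)
        for cid, centroid_idx in enumerate(res.centroids, start=1):
            assert res.assignments[centroid_idx] == cid

    def test_similarity_matrix_properties(self):
        models, _ = make_planted_groups(n_groups=2, per_group=3)
        res = cluster_models(models, k=2)
        np.testing.assert_allclose(res.similarity, res.similarity.T, atol=1e-6)
        np.testing.assert_allclose(np.diag(res.similarity), 1.0)

    def test_k_one_gives_medoid_of_all(self):
        models, _ = make_planted_groups(n_groups=2, per_group=3)
        res = cluster_models(models, k=1)
        assert len(res.centroids) == 1
        sim = res.similarity
        assert res.centroids[0] == int(np.argmax(sim.mean(axis=1)))

    def test_k_equals_n(self):
        models, _ = make_planted_groups(n_groups=1, per_group=5)
        res = cluster_models(models, k=5)
        assert sorted(res.centroids) == list(range(5))

    def test_fewer_models_than_k_reduces(self):
        models, _ = make_planted_groups(n_groups=1, per_group=3)
        res = cluster_models(models, k=5)
        assert res.k == 3


class TestFilterPool:
    def test_keeps_best_and_dominates_discarded(self, bundle, bundle_contacts):
        _, native, _ = bundle
        L = len(native)
        rng = np.random.default_rng(2)
        pool = []
        for k in range(30):
            ca = native.ca + rng.normal(0, rng.uniform(0.1, 6.0), native.ca.shape)
            m = Model(native.sequence, ca, ca + (native.cb - native.ca))
            pool.append(ScoredModel(model=m, e_contact=float(k), order=k))
        kept = filter_pool(pool, bundle_contacts, L, keep=10)
        assert len(kept) == 10
        kept_ids = {sm.order for sm in kept}
        discarded = [sm for sm in pool if sm.order not in kept_ids]
        assert min(sm.satisfaction for sm in kept) >= max(
            sm.satisfaction for sm in discarded)

    def test_ties_break_by_energy_then_order(self, bundle, bundle_contacts):
        _, native, _ = bundle
        L = len(native)
        pool = [ScoredModel(model=native, e_contact=e, order=k)
                for k, e in enumerate([3.0, 1.0, 2.0, 1.0])]
        kept = filter_pool(pool, bundle_contacts, L, keep=2)
        assert [sm.order for sm in kept] == [1, 3]  # equal satisfaction -> energy, order

    def test_small_pool_returned_whole(self, bundle, bundle_contacts):
        _, native, _ = bundle
        pool = [ScoredModel(model=native, e_contact=0.0, order=0)]
        assert len(filter_pool(pool, bundle_contacts, len(native), keep=50)) == 1


class TestSelectTop5:
    def test_ranked_by_satisfaction(self):
        models, _ = make_planted_groups()
        contacts = lr_contacts([(1, 30), (2, 35)])
        res = cluster_models(models, k=5)
        top = select_top5(res, contacts, 40)
        sats = [sm.satisfaction for sm in top]
        assert sats == sorted(sats, reverse=True)
        assert len(top) == 5

    def test_baseline_ignores_clustering(self, bundle, bundle_contacts):
        _, native, _ = bundle
        L = len(native)
        rng = np.random.default_rng(3)
        pool = []
        for k in range(12):
            ca = native.ca + rng.normal(0, rng.uniform(0.2, 5.0), native.ca.shape)
            m = Model(native.sequence, ca, ca + (native.cb - native.ca))
            pool.append(ScoredModel(model=m, e_contact=0.0, order=k))
        top = select_by_satisfaction_only(pool, bundle_contacts, L, n=5)
        assert len(top) == 5
        sats = [sm.satisfaction for sm in top]
        assert sats == sorted(sats, reverse=True)
        top_ids = {sm.order for sm in top}
        rest = [sm.satisfaction for sm in pool if sm.order not in top_ids]
        assert min(sats) >= max(rest)
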