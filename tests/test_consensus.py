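import numpy as np
import pytest

from somsite.consensus import (
    ConsensualCluster,
    UMatrix,
    compute_rcc,
    compute_umatrix,
    evaluate_target,
    extract_ccs,
    fit_gmm_threshold,
    precision,
    success_rates,
)
from somsite.som import SOMap
from somsite.structures import ReferenceLigand


def make_map(neurons, trained=True):
    neurons = np.asarray(neurons, dtype=float)
    return SOMap(neurons.shape[:3], neurons, trained=trained)


def umatrix_oracle(neurons):
    """Triple-loop neighbour enumeration, independent of the implementation."""
    I, J, K, _ = neurons.shape
    out = np.zeros((I, J, K))
    for i in range(I):
        for j in range(J):
            for k in range(K):
                ds = []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            if di == dj == dk == 0:
                                continue
                            a, b, c = i + di, j + dj, k + dk
                            if 0 <= a < I and 0 <= b < J and 0 <= c < K:
                                ds.append(np.linalg.norm(
                                    neurons[i, j, k] - neurons[a, b, c]))
                out[i, j, k] = np.mean(ds)
    return out


class TestUMatrix:
    def test_identical_neurons_give_zero(self):
        u = compute_umatrix(make_map(np.zeros((3, 3, 3, 3))))
        np.testing.assert_allclose(u.values, 0.0)

    def test_unit_cube_analytic_value(self):
        pts = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                        for k in (0, 1)], dtype=float)
        u = compute_umatrix(make_map(pts.reshape(2, 2, 2, 3)))
        want = (3 * 1 + 3 * np.sqrt(2) + np.sqrt(3)) / 7
        np.testing.assert_allclose(u.values, want, atol=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        neurons = rng.normal(size=(4, 4, 4, 3))
        u = compute_umatrix(make_map(neurons))
        np.testing.assert_allclose(u.values, umatrix_oracle(neurons), atol=1e-12)

    def test_untrained_or_thin_maps_rejected(self):
        with pytest.raises(ValueError):
            compute_umatrix(make_map(np.zeros((3, 3, 3, 3)), trained=False))
        with pytest.raises(ValueError):
            compute_umatrix(make_map(np.zeros((1, 3, 3, 3))))


class TestGmmThreshold:
    def test_constant_values_return_constant(self):
        t, summary = fit_gmm_threshold(np.full(100, 3.7))
        assert t == 3.7 and summary["n_components"] == 1

    def test_single_gaussian_gives_mean_plus_sd(self):
        rng = np.random.default_rng(1)
        t, _ = fit_gmm_threshold(rng.normal(5.0, 1.0, size=10_000), seed=0)
        assert t == pytest.approx(6.0, abs=0.05)

    def test_bimodal_selects_dominant_low_mode(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(1.0, 0.1, 9000),
                               rng.normal(5.0, 0.1, 1000)])
        t, summary = fit_gmm_threshold(vals, seed=0)
        assert t == pytest.approx(1.1, abs=0.05)
        assert t < 2.0

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(1.0, 0.2, 500),
                               rng.normal(3.0, 0.2, 200)])
        t0, _ = fit_gmm_threshold(vals, seed=0)
        t1, _ = fit_gmm_threshold(vals + 10.0, seed=0)
        assert t1 - t0 == pytest.approx(10.0, abs=0.05)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm_threshold(np.arange(5.0))


def cc_partition_oracle(mask):
    """Union-find over the below-threshold mask, 26-connectivity."""
    cells = {tuple(v): i for i, v in enumerate(np.argwhere(mask))}
    parent = list(range(len(cells)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for (x, y, z), i in cells.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    j = cells.get((x + dx, y + dy, z + dz))
                    if j is not None:
                        parent[find(i)] = find(j)
    groups = {}
    for key, i in cells.items():
        groups.setdefault(find(i), set()).add(key)
    return {frozenset(g) for g in groups.values()}


class TestExtractCcs:
    def _umatrix(self, values, t_u):
        u = UMatrix(np.asarray(values, dtype=float))
        u.t_u = t_u
        return u

    def test_all_above_threshold_gives_empty_list(self):
        som = make_map(np.zeros((3, 3, 3, 3)))
        assert extract_ccs(self._umatrix(np.ones((3, 3, 3)), 0.5), som) == []

    def test_two_blocks_ranked_by_size(self):
        vals = np.ones((5, 5, 5))
        vals[0:2, 0:5, 0] = 0.0            # block of 10
        vals[4, 0:2, 3:5] = 0.0            # block of 4
        som = make_map(np.zeros((5, 5, 5, 3)))
        ccs = extract_ccs(self._umatrix(vals, 0.5), som)
        assert [(c.rank, c.count) for c in ccs] == [(1, 10), (2, 4)]

    def test_random_masks_match_union_find_oracle(self):
        rng = np.random.default_rng(4)
        som = make_map(rng.normal(size=(5, 5, 5, 3)))
        for _ in range(20):
            vals = rng.random((5, 5, 5))
            ccs = extract_ccs(self._umatrix(vals, 0.3), som)
            ours = {frozenset(map(tuple, c.indices)) for c in ccs}
            assert ours == cc_partition_oracle(vals <= 0.3)

    def test_missing_threshold_rejected(self):
        som = make_map(np.zeros((3, 3, 3, 3)))
        with pytest.raises(ValueError):
            extract_ccs(UMatrix(np.ones((3, 3, 3))), som)


def chain_cluster(spacings):
    """A 1D chain of neurons along x whose consecutive gaps are `spacings`."""
    x = np.concatenate([[0.0], np.cumsum(spacings)])
    neurons = np.zeros((len(x), 1, 1, 3))
    neurons[:, 0, 0, 0] = x
    som = make_map(neurons)
    idx = np.array([[i, 0, 0] for i in range(len(x))])
    return ConsensualCluster(1, idx, len(x), centroid=neurons.mean(axis=(0, 1, 2))), som


class TestRcc:
    def test_regular_lattice_gives_spacing(self):
        cc, som = chain_cluster([0.7] * 10)
        assert compute_rcc(cc, som) == pytest.approx(0.7, abs=1e-9)

    def test_known_mixture_recovers_dominant_component(self):
        rng = np.random.default_rng(5)
        draws = np.concatenate([rng.normal(0.6, 0.05, 320),
                                rng.normal(1.5, 0.05, 80)])
        cc, som = chain_cluster(rng.permutation(draws))
        assert compute_rcc(cc, som, seed=0) == pytest.approx(0.65, abs=0.03)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        cc, som = chain_cluster(rng.uniform(0.5, 1.5, 30))
        r0 = compute_rcc(cc, som, seed=0)
        R = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        som.neurons = som.neurons @ R.T
        cc2 = ConsensualCluster(1, cc.indices, cc.count)
        assert compute_rcc(cc2, som, seed=0) == pytest.approx(r0, abs=1e-6)

    def test_isolated_neurons_rejected(self):
        neurons = np.zeros((4, 1, 1, 3))
        neurons[:, 0, 0, 0] = np.arange(4)
        som = make_map(neurons)
        cc = ConsensualCluster(1, np.array([[0, 0, 0], [2, 0, 0]]), 2)
        with pytest.raises(ValueError, match="neighbour"):
            compute_rcc(cc, som)


class TestPrecision:
    def test_atoms_at_neurons_give_one(self):
        cc, som = chain_cluster([1.0] * 5)
        cc.r_cc = 1.0
        lig = ReferenceLigand(cc.neuron_coords(som)[:3], np.ones(3, bool))
        assert precision(cc, som, lig) == 1.0

    def test_distant_atoms_give_zero(self):
        cc, som = chain_cluster([1.0] * 5)
        cc.r_cc = 1.0
        lig = ReferenceLigand(np.full((4, 3), 100.0), np.ones(4, bool))
        assert precision(cc, som, lig) == 0.0

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(7)
        cc, som = chain_cluster([1.0] * 10)
        lig = ReferenceLigand(rng.normal(scale=4.0, size=(50, 3)),
                              np.ones(50, bool))
        ps = [precision(cc, som, lig, radius=r) for r in (0.5, 1.0, 2.0, 4.0)]
        assert ps == sorted(ps)

    def test_empty_ligand_mode_rejected(self):
        cc, som = chain_cluster([1.0] * 5)
        cc.r_cc = 1.0
        lig = ReferenceLigand(np.zeros((2, 3)), np.zeros(2, bool))
        with pytest.raises(ValueError):
            precision(cc, som, lig, heavy_only=True)


def synthetic_ccs_with_ligand():
    """Three clusters engineered for precisions (0.1, 0.3, 0.0) in rank order."""
    neurons = np.zeros((3, 4, 2, 3))
    neurons[0, :, :] = [0.0, 0.0, 0.0]
    # ligand: 10 atoms on a line at y = 50
    lig_pts = np.array([[i * 5.0, 50.0, 0.0] for i in range(10)])
    lig = ReferenceLigand(lig_pts, np.ones(10, bool))
    som = make_map(neurons)

    def cluster(rank, member_xyz):
        idx = np.array([[rank - 1, j, 0] for j in range(len(member_xyz))])
        for row, xyz in zip(idx, member_xyz):
            som.neurons[tuple(row)] = xyz
        cc = ConsensualCluster(rank, idx, len(member_xyz))
        cc.r_cc = 0.5
        return cc

    cc1 = cluster(1, [lig_pts[0], [200.0, 0, 0], [210.0, 0, 0], [220.0, 0, 0]])
    cc2 = cluster(2, [lig_pts[1], lig_pts[2], lig_pts[3], [300.0, 0, 0]])
    cc3 = cluster(3, [[400.0, 0, 0], [410.0, 0, 0]])
    return [cc1, cc2, cc3], som, lig


class TestEvaluateTarget:
    def test_hit_rule_and_top_flags(self):
        ccs, som, lig = synthetic_ccs_with_ligand()
        ev = evaluate_target(ccs, som, lig, precision_threshold=0.25)
        assert ev.precisions == [0.1, 0.3, 0.0]
        assert ev.hit_rank == 2 and not ev.top1 and ev.top3
        assert ev.n_overlapping == 2 and ev.occurrence_failed

    def test_single_strong_cluster_is_top1(self):
        ccs, som, lig = synthetic_ccs_with_ligand()
        strong = ccs[1]
        strong.rank = 1
        ev = evaluate_target([strong], som, lig, precision_threshold=0.25)
        assert ev.top1 and ev.top3 and not ev.occurrence_failed

    def test_empty_cc_list_fails(self):
        _, som, lig = synthetic_ccs_with_ligand()
        ev = evaluate_target([], som, lig)
        assert ev.hit_rank is None and not ev.top1 and not ev.top3
        assert ev.occurrence_failed

    def test_fixed_radius_mode(self):
        ccs, som, lig = synthetic_ccs_with_ligand()
        ev = evaluate_target(ccs, som, lig, radius_mode="1.6")
        assert ev.radii == [1.6, 1.6, 1.6]


class TestSuccessRates:
    def test_all_successes(self):
        ccs, som, lig = synthetic_ccs_with_ligand()
        evs = [evaluate_target([ccs[1]], som, lig) for _ in range(3)]
        for e in evs:
            e.top1 = e.top3 = True
        s = success_rates(evs)
        assert s["top1_sr"] == 1.0 and s["top3_sr"] == 1.0

    def test_fractions(self):
        ccs, som, lig = synthetic_ccs_with_ligand()
        evs = []
        for i in range(50):
            e = evaluate_target(ccs, som, lig)
            e.top1 = i < 41
            e.top3 = True
            evs.append(e)
        s = success_rates(evs)
        assert s["top1_sr"] == pytest.approx(0.82)
        assert s["top3_sr"] == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            success_rates([])
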