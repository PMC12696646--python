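"""Block-coordinate descent: objective assembly, sweep monotonicity,
argmin correctness against brute force, initialization and determinism."""

import numpy as np
import pytest

from guidedcoc import (
    CellFeatureMatrix,
    ClusterAssignment,
    CoClusterState,
    Stage1Config,
    SyntheticSpec,
    ari,
    default_block_means,
    fit,
    generate,
    initialize,
    kl_cocluster_loss,
    normalize_joint,
    objective,
    update_cy,
    update_cz,
)

from conftest import random_clusters, random_joint


def _joints(R_t, A_t, R_s):
    return normalize_joint(R_t), normalize_joint(A_t), normalize_joint(R_s)


def _random_state(rng, n, q, n_s, N, K, Ns_clusters):
    return CoClusterState(
        cy=random_clusters(rng, n, N),
        cz=random_clusters(rng, q, K),
        cx=random_clusters(rng, n_s, Ns_clusters),
    )


class TestObjective:
    def test_reduces_to_single_matrix_loss_when_unweighted(self, rng):
        Pt = random_joint(rng, 8, 10)
        Pa = random_joint(rng, 8, 10)
        Ps = random_joint(rng, 6, 10)
        st = _random_state(rng, 8, 10, 6, 3, 4, 2)
        cfg = Stage1Config(n_target_clusters=3, k_features=4, alpha=0.0, beta=0.0)
        assert objective(Pt, Pa, Ps, st, cfg) == pytest.approx(
            kl_cocluster_loss(Pt, st.cy, st.cz), abs=1e-12
        )

    def test_identity_clusterings_give_zero(self, rng):
        Pt = random_joint(rng, 6, 8)
        Pa = random_joint(rng, 6, 8)
        Ps = random_joint(rng, 5, 8)
        st = CoClusterState(
            cy=ClusterAssignment(np.arange(6), 6),
            cz=ClusterAssignment(np.arange(8), 8),
            cx=ClusterAssignment(np.arange(5), 5),
        )
        cfg = Stage1Config(n_target_clusters=6, k_features=8)
        assert objective(Pt, Pa, Ps, st, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_term_sum_oracle(self, rng):
        Pt = random_joint(rng, 8, 10, zero_frac=0.3)
        Pa = random_joint(rng, 8, 10, zero_frac=0.3)
        Ps = random_joint(rng, 6, 10, zero_frac=0.3)
        st = _random_state(rng, 8, 10, 6, 3, 4, 2)
        cfg = Stage1Config(n_target_clusters=3, k_features=4, alpha=0.8, beta=1.0)
        expected = (
            kl_cocluster_loss(Pt, st.cy, st.cz)
            + 0.8 * kl_cocluster_loss(Pa, st.cy, st.cz)
            + 1.0 * kl_cocluster_loss(Ps, st.cx, st.cz)
        )
        assert objective(Pt, Pa, Ps, st, cfg) == pytest.approx(expected, abs=1e-12)


class TestUpdateCy:
    def test_block_structured_cells_snap_to_their_block(self, small_triple):
        R_s, R_t, A_t, cx, cy_p, cz_p = small_triple
        Pt, Pa, Ps = _joints(R_t, A_t, R_s)
        rng = np.random.default_rng(3)
        noisy = cy_p.labels.copy()
        flip = rng.permutation(len(noisy))[:10]
        noisy[flip] = rng.integers(0, 3, size=10)
        st = CoClusterState(cy=ClusterAssignment(noisy, 3), cz=cz_p, cx=cx)
        cfg = Stage1Config(n_target_clusters=3, k_features=3, alpha=0.0, beta=1.0)
        # one sweep from a mostly-correct state recovers the planted cells
        new = update_cy(Pt, Pa, st, cfg)
        assert ari(new.cy.labels, cy_p.labels) == pytest.approx(1.0)

    def test_alpha_crossover_flips_assignment(self):
        # cell 0: RNA profile matches cluster 0, activity profile matches
        # cluster 1; raising alpha flips the argmin.
        R = np.array([
            [8.0, 1.0], [8.0, 1.0],  # cluster 0 shape in RNA
            [1.0, 8.0], [1.0, 8.0],  # cluster 1 shape in RNA
        ])
        A = np.array([
            [1.0, 8.0], [8.0, 1.0],
            [1.0, 8.0], [1.0, 8.0],
        ])
        Pt, Pa = normalize_joint(CellFeatureMatrix(R)), normalize_joint(CellFeatureMatrix(A))
        st = CoClusterState(
            cy=ClusterAssignment(np.array([0, 0, 1, 1]), 2),
            cz=ClusterAssignment(np.arange(2), 2),
            cx=ClusterAssignment(np.zeros(1, int), 1),
        )
        lo = update_cy(Pt, Pa, st, Stage1Config(n_target_clusters=2, k_features=2, alpha=0.01))
        hi = update_cy(Pt, Pa, st, Stage1Config(n_target_clusters=2, k_features=2, alpha=50.0))
        assert lo.cy.labels[0] == 0
        assert hi.cy.labels[0] == 1

    def test_sweep_never_increases_objective(self, rng):
        for _ in range(5):
            Pt = random_joint(rng, 10, 12, zero_frac=0.3)
            Pa = random_joint(rng, 10, 12, zero_frac=0.3)
            Ps = random_joint(rng, 8, 12, zero_frac=0.3)
            st = _random_state(rng, 10, 12, 8, 3, 4, 2)
            cfg = Stage1Config(n_target_clusters=3, k_features=4, alpha=0.8, beta=1.0)
            before = objective(Pt, Pa, Ps, st, cfg)
            after = objective(Pt, Pa, Ps, update_cy(Pt, Pa, st, cfg), cfg)
            assert after <= before + 1e-9

    def test_clusters_stay_nonempty_after_sweep(self, rng):
        Pt = random_joint(rng, 8, 10)
        Pa = random_joint(rng, 8, 10)
        st = _random_state(rng, 8, 10, 5, 4, 3, 2)
        cfg = Stage1Config(n_target_clusters=4, k_features=3)
        new = update_cy(Pt, Pa, st, cfg)
        assert new.cy.empty_clusters().size == 0


class TestUpdateCz:
    def test_dominant_source_term_imposes_source_blocks(self, small_triple):
        R_s, R_t, A_t, cx, cy_p, cz_p = small_triple
        Pt, Pa, Ps = _joints(R_t, A_t, R_s)
        rng = np.random.default_rng(5)
        noisy = cz_p.labels.copy()
        flip = rng.permutation(len(noisy))[: len(noisy) // 5]
        noisy[flip] = rng.integers(0, 3, size=flip.size)
        st = CoClusterState(cy=cy_p, cz=ClusterAssignment(noisy, 3), cx=cx)
        cfg = Stage1Config(n_target_clusters=3, k_features=3, alpha=0.0, beta=1e6)
        for _ in range(5):
            st = update_cz(Pt, Pa, Ps, st, cfg)
        assert ari(st.cz.labels, cz_p.labels) == pytest.approx(1.0)

    def test_beta_zero_matches_single_matrix_update(self, rng):
        Pt = random_joint(rng, 10, 12, zero_frac=0.3)
        Pa = random_joint(rng, 10, 12, zero_frac=0.3)
        Ps = random_joint(rng, 8, 12, zero_frac=0.3)
        st = _random_state(rng, 10, 12, 8, 3, 4, 2)
        cfg0 = Stage1Config(n_target_clusters=3, k_features=4, alpha=0.0, beta=0.0)
        new = update_cz(Pt, Pa, Ps, st, cfg0)
        # brute-force single-matrix column argmin over candidate clusters
        from guidedcoc import conditional_kl_col

        for z in range(12):
            costs = [conditional_kl_col(Pt, z, j, st.cy, st.cz) for j in range(4)]
            assert new.cz.labels[z] == int(np.argmin(costs))

    def test_per_feature_argmin_matches_exhaustive_single_move(self, rng):
        Pt = random_joint(rng, 8, 10, zero_frac=0.3)
        Pa = random_joint(rng, 8, 10, zero_frac=0.3)
        Ps = random_joint(rng, 6, 10, zero_frac=0.3)
        st = _random_state(rng, 8, 10, 6, 3, 3, 2)
        cfg = Stage1Config(n_target_clusters=3, k_features=3, alpha=0.8, beta=1.0)
        from guidedcoc import conditional_kl_col

        new = update_cz(Pt, Pa, Ps, st, cfg)
        for z in range(10):
            costs = []
            for j in range(3):
                c = Pt.col_marginal[z] * conditional_kl_col(Pt, z, j, st.cy, st.cz)
                c += 0.8 * Pa.col_marginal[z] * conditional_kl_col(Pa, z, j, st.cy, st.cz)
                c += 1.0 * Ps.col_marginal[z] * conditional_kl_col(Ps, z, j, st.cx, st.cz)
                costs.append(c)
            assert new.cz.labels[z] == int(np.argmin(costs))

    def test_sweep_never_increases_objective(self, rng):
        for _ in range(5):
            Pt = random_joint(rng, 10, 12, zero_frac=0.3)
            Pa = random_joint(rng, 10, 12, zero_frac=0.3)
            Ps = random_joint(rng, 8, 12, zero_frac=0.3)
            st = _random_state(rng, 10, 12, 8, 3, 4, 2)
            cfg = Stage1Config(n_target_clusters=3, k_features=4, alpha=0.8, beta=1.0)
            before = objective(Pt, Pa, Ps, st, cfg)
            after = objective(Pt, Pa, Ps, update_cz(Pt, Pa, Ps, st, cfg), cfg)
            assert after <= before + 1e-9


class TestInitialize:
    def test_random_init_deterministic_and_nonempty(self, small_triple):
        R_s, R_t, A_t, cx, *_ = small_triple
        cfg = Stage1Config(n_target_clusters=3, k_features=3, seed=11, init_method="random")
        a = initialize(R_t, R_s, cx, cfg)
        b = initialize(R_t, R_s, cx, cfg)
        assert np.array_equal(a.cy.labels, b.cy.labels)
        assert np.array_equal(a.cz.labels, b.cz.labels)
        assert a.cy.empty_clusters().size == 0 and a.cz.empty_clusters().size == 0

    def test_random_init_pigeonhole(self):
        vals = np.eye(4) + 0.1
        R = CellFeatureMatrix(vals)
        cx = ClusterAssignment(np.zeros(4, int), 1)
        cfg = Stage1Config(n_target_clusters=4, k_features=4, seed=2, init_method="random")
        st = initialize(R, R, cx, cfg)
        assert sorted(st.cy.labels) == [0, 1, 2, 3]
        assert sorted(st.cz.labels) == [0, 1, 2, 3]

    def test_kmeans_init_beats_random_on_planted_data(self):
        km_scores, rnd_scores = [], []
        for seed in range(20):
            spec = SyntheticSpec(
                n_source=60, n_target=90, q=45, n_source_clusters=3, n_target_clusters=3,
                k_features=3, dropout=0.3, atac_distortion=0.0, seed=seed,
                block_means=default_block_means(3, 3, base=1.0, contrast=4.0),
            )
            R_s, R_t, A_t, cx, cy_p, _ = generate(spec)
            for method, out in (("kmeans", km_scores), ("random", rnd_scores)):
                cfg = Stage1Config(n_target_clusters=3, k_features=3, seed=seed, init_method=method)
                st = initialize(R_t, R_s, cx, cfg)
                out.append(ari(st.cy.labels, cy_p.labels))
        assert np.median(km_scores) > np.median(rnd_scores)

    def test_provided_labels_validated(self, small_triple):
        R_s, R_t, A_t, cx, *_ = small_triple
        cfg = Stage1Config(n_target_clusters=3, k_features=3, init_method="provided")
        with pytest.raises(ValueError):
            initialize(R_t, R_s, cx, cfg, cy_labels=np.full(R_t.n_cells, 9), cz_labels=np.zeros(R_t.n_features, int))


class TestFit:
    def test_recovers_planted_coclusters_noiseless(self, small_triple):
        R_s, R_t, A_t, cx, cy_p, cz_p = small_triple
        cfg = Stage1Config(n_target_clusters=3, k_features=3, seed=0)
        res = fit(R_t, A_t, R_s, cx, cfg)
        assert ari(res.state.cy.labels, cy_p.labels) == pytest.approx(1.0)
        assert ari(res.state.cz.labels, cz_p.labels) == pytest.approx(1.0)
        assert res.converged

    def test_no_single_move_improves_at_convergence(self, rng):
        spec = SyntheticSpec(
            n_source=12, n_target=12, q=12, n_source_clusters=3, n_target_clusters=3,
            k_features=3, dropout=0.2, atac_distortion=0.2, seed=4,
            block_means=default_block_means(3, 3, base=1.0, contrast=5.0),
        )
        R_s, R_t, A_t, cx, *_ = generate(spec)
        cfg = Stage1Config(n_target_clusters=3, k_features=3, seed=4, max_iter=60, tol=1e-12)
        res = fit(R_t, A_t, R_s, cx, cfg)
        Pt, Pa, Ps = _joints(R_t, A_t, R_s)
        base = objective(Pt, Pa, Ps, res.state, cfg)
        st = res.state
        for y in range(12):
            for i in range(3):
                if i == st.cy.labels[y]:
                    continue
                lab = st.cy.labels.copy(); lab[y] = i
                alt = st.replace(cy=st.cy.with_labels(lab))
                assert objective(Pt, Pa, Ps, alt, cfg) >= base - 1e-9
        for z in range(12):
            for j in range(3):
                if j == st.cz.labels[z]:
                    continue
                lab = st.cz.labels.copy(); lab[z] = j
                alt = st.replace(cz=st.cz.with_labels(lab))
                assert objective(Pt, Pa, Ps, alt, cfg) >= base - 1e-9

    def test_infinite_tol_stops_after_one_iteration(self, small_triple):
        R_s, R_t, A_t, cx, *_ = small_triple
        cfg = Stage1Config(n_target_clusters=3, k_features=3, seed=0, tol=np.inf)
        res = fit(R_t, A_t, R_s, cx, cfg)
        assert res.n_iter == 1 and len(res.objective_trace) == 1

    def test_same_seed_same_result(self, small_triple):
        R_s, R_t, A_t, cx, *_ = small_triple
        cfg = Stage1Config(n_target_clusters=3, k_features=3, seed=9, init_method="random")
        a = fit(R_t, A_t, R_s, cx, cfg)
        b = fit(R_t, A_t, R_s, cx, cfg)
        assert np.array_equal(a.state.cy.labels, b.state.cy.labels)
        assert np.array_equal(a.state.cz.labels, b.state.cz.labels)
        assert a.objective_trace == b.objective_trace

    def test_trace_is_monotone(self, small_triple):
        R_s, R_t, A_t, cx, *_ = small_triple
        cfg = Stage1Config(n_target_clusters=3, k_features=3, seed=1, init_method="random")
        res = fit(R_t, A_t, R_s, cx, cfg)
        tr = res.objective_trace
        assert all(tr[i + 1] <= tr[i] + 1e-9 for i in range(len(tr) - 1))

    def test_misaligned_inputs_rejected(self, small_triple):
        R_s, R_t, A_t, cx, *_ = small_triple
        cfg = Stage1Config(n_target_clusters=3, k_features=3)
        bad = CellFeatureMatrix(A_t.dense()[:-1], A_t.cell_ids[:-1], A_t.feature_ids)
        with pytest.raises(ValueError):
            fit(R_t, bad, R_s, cx, cfg)
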