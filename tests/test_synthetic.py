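import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from wmnet import (
    CohortConfig,
    characteristic_path_length,
    clustering,
    count_streamlines,
    expand_to_streamlines,
    generate_base_topology,
    generate_cohort,
    generate_subject_network,
    sample_counts,
    shortest_paths,
    threshold_network,
)


class TestBaseTopology:
    def test_zero_rewiring_gives_pure_ring(self):
        net = generate_base_topology(6, 2, 0.0, seed=0)
        expected = np.zeros((6, 6), dtype=np.int8)
        for i in range(6):
            expected[i, (i + 1) % 6] = expected[(i + 1) % 6, i] = 1
        np.testing.assert_array_equal(net.adjacency, expected)

    def test_lattice_degrees_exact(self):
        net = generate_base_topology(90, 6, 0.0, seed=0)
        assert set(net.degrees) == {6}

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_count_conserved_under_rewiring(self, seed):
        net = generate_base_topology(90, 6, 0.1, seed=seed)
        assert net.n_edges == 270
        assert np.array_equal(net.adjacency, net.adjacency.T)
        assert np.diag(net.adjacency).sum() == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_base_topology(10, 3, 0.1)
        with pytest.raises(ValueError, match=">= 4"):
            generate_base_topology(3, 2, 0.1)


class TestSubjectNetwork:
    def test_no_perturbation_is_identity(self):
        base = generate_base_topology(30, 4, 0.1, seed=1)
        out = generate_subject_network(base, 0.0, 0.0, {}, seed=2)
        np.testing.assert_array_equal(out.adjacency, base.adjacency)

    def test_deficit_halves_degree_before_noise(self):
        base = generate_base_topology(30, 6, 0.0, seed=0)
        out = generate_subject_network(base, 0.0, 0.0, {7: 0.5}, seed=3)
        assert out.degrees[7] == 3

    def test_deficit_node_out_of_range_rejected(self):
        base = generate_base_topology(10, 2, 0.0, seed=0)
        with pytest.raises(ValueError, match="deficit node"):
            generate_subject_network(base, 0.0, 0.0, {10: 0.5}, seed=0)

    def test_extra_rewiring_destroys_clustering(self):
        base = generate_base_topology(30, 6, 0.0, seed=0)
        _, cp_base = clustering(base)
        cps = []
        for seed in range(50):
            out = generate_subject_network(base, 0.3, 0.0, {}, seed=seed)
            cps.append(clustering(out)[1])
        assert np.mean(cps) < cp_base


class TestSampleCounts:
    def test_zero_absent_mean_leaves_nonedges_empty(self):
        net = generate_base_topology(20, 4, 0.0, seed=0)
        cm = sample_counts(net, 10.0, 0.0, seed=1)
        assert cm.counts[net.adjacency == 0].sum() == 0

    def test_diagonal_always_zero(self):
        net = generate_base_topology(20, 4, 0.2, seed=0)
        cm = sample_counts(net, 10.0, 1.0, seed=1)
        assert np.diag(cm.counts).sum() == 0

    def test_fn3_is_high_fidelity_edge_detector_at_defaults(self):
        # tail probabilities: P(Pois(20) < 3) ~ 5e-7, P(Pois(0.05) >= 3) ~ 2e-5
        net = generate_base_topology(90, 6, 0.1, seed=0)
        true_edges = net.adjacency == 1
        nonedges = (net.adjacency == 0) & ~np.eye(90, dtype=bool)
        recovered, admitted = [], []
        for seed in range(100):
            cm = sample_counts(net, 20.0, 0.05, seed=seed)
            rec = threshold_network(cm, 3)
            recovered.append((rec.adjacency[true_edges] == 1).mean())
            admitted.append((rec.adjacency[nonedges] == 1).mean())
        assert np.mean(recovered) >= 0.99
        assert np.mean(admitted) <= 0.01

    def test_false_edge_rate_matches_poisson_tail(self):
        # with spurious mean 0.5 the FN=3 false-edge rate is the Poisson
        # tail P(X >= 3) = 1.44e-2, an order of magnitude above 1e-3
        net = generate_base_topology(90, 6, 0.0, seed=0)
        nonedges = (net.adjacency == 0) & ~np.eye(90, dtype=bool)
        rates = [
            (threshold_network(sample_counts(net, 20.0, 0.5, seed=s), 3)
             .adjacency[nonedges] == 1).mean()
            for s in range(30)
        ]
        expected = sps.poisson.sf(2, 0.5)
        assert np.mean(rates) == pytest.approx(expected, rel=0.15)

    def test_invalid_means_rejected(self):
        net = generate_base_topology(10, 2, 0.0, seed=0)
        with pytest.raises(ValueError):
            sample_counts(net, 1.0, 2.0)


class TestStreamlineExpansion:
    def test_zero_counts_give_empty_table(self):
        net = generate_base_topology(10, 2, 0.0, seed=0)
        cm = sample_counts(net, 10.0, 0.0, seed=0)
        cm.counts[:] = 0
        assert len(expand_to_streamlines(cm)) == 0

    def test_single_pair_expands_to_count_rows(self):
        c = np.zeros((6, 6), dtype=int)
        c[2, 5] = c[5, 2] = 3
        from wmnet import ConnectivityCountMatrix

        tab = expand_to_streamlines(ConnectivityCountMatrix(c), "s")
        assert len(tab) == 3
        assert set(zip(tab["region_a"], tab["region_b"])) == {(2, 5)}

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(5)
        net = generate_base_topology(15, 4, 0.3, seed=2)
        cm = sample_counts(net, 8.0, 0.4, seed=3, subject_id="s9")
        back = count_streamlines(expand_to_streamlines(cm), 15)
        np.testing.assert_array_equal(back.counts, cm.counts)


class TestCohort:
    def test_row_count_and_groups(self):
        cfg = CohortConfig(n_controls=6, n_patients=9, seed=0)
        mats, table = generate_cohort(cfg)
        assert len(table) == 15 and len(mats) == 15
        assert (table["group"] == "HC").sum() == 6
        assert table.loc[table["group"] == "HC", "thi"].isna().all()
        assert table.loc[table["group"] == "SSNHL", "thi"].notna().all()
        assert table["age"].between(18, 80).all()
        assert table.loc[table["group"] == "SSNHL", "thi"].between(0, 100).all()

    def test_identical_seed_reproduces_cohort_exactly(self):
        cfg = CohortConfig(n_controls=4, n_patients=4, seed=7)
        m1, t1 = generate_cohort(cfg)
        m2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        for sid in m1:
            np.testing.assert_array_equal(m1[sid].counts, m2[sid].counts)

    def test_thi_coupling_hits_target_correlation(self):
        rs = []
        for seed in range(20):
            cfg = CohortConfig(
                n_controls=2, n_patients=145, thi_corr=0.6, seed=seed
            )
            mats, table = generate_cohort(cfg)
            pts = table[table["group"] == "SSNHL"]
            lps = []
            for sid in pts["subject_id"]:
                net = threshold_network(mats[sid], 3)
                _, lp, _ = characteristic_path_length(shortest_paths(net))
                lps.append(lp)
            r = np.corrcoef(lps, pts["thi"])[0, 1]
            rs.append(r)
            assert 0.4 <= r <= 0.8
        assert np.mean(rs) == pytest.approx(0.6, abs=0.08)

    def test_duration_coupling_sign_is_negative(self):
        cfg = CohortConfig(n_controls=2, n_patients=100, seed=4,
                           duration_corr=-0.5)
        mats, table = generate_cohort(cfg)
        pts = table[table["group"] == "SSNHL"]
        lps = []
        for sid in pts["subject_id"]:
            net = threshold_network(mats[sid], 3)
            _, lp, _ = characteristic_path_length(shortest_paths(net))
            lps.append(lp)
        assert np.corrcoef(lps, pts["duration"])[0, 1] < -0.2

    @pytest.mark.parametrize("seed", range(10))
    def test_randomization_shift_sign_pattern(self, seed):
        """Patient networks lose clustering and gain path length."""
        cfg = CohortConfig(n_controls=15, n_patients=15, seed=seed)
        mats, table = generate_cohort(cfg)
        groups = table.set_index("subject_id")["group"]
        cps = {"HC": [], "SSNHL": []}
        lps = {"HC": [], "SSNHL": []}
        for sid, cm in mats.items():
            net = threshold_network(cm, 3)
            cps[groups[sid]].append(clustering(net)[1])
            _, lp, _ = characteristic_path_length(shortest_paths(net))
            lps[groups[sid]].append(lp)
        assert np.mean(cps["SSNHL"]) < np.mean(cps["HC"])
        assert np.mean(lps["SSNHL"]) > np.mean(lps["HC"])

    def test_degree_deficit_detectable_at_planted_nodes(self):
        cfg = CohortConfig(n_controls=15, n_patients=15, seed=11)
        mats, table = generate_cohort(cfg)
        groups = table.set_index("subject_id")["group"]
        deficit = list(cfg.planted_deficit_nodes)
        mean_deg = {"HC": [], "SSNHL": []}
        for sid, cm in mats.items():
            net = threshold_network(cm, 3)
            mean_deg[groups[sid]].append(net.degrees[deficit].mean())
        assert np.mean(mean_deg["SSNHL"]) < np.mean(mean_deg["HC"])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="even"):
            CohortConfig(base_mean_degree=5).validate()
        with pytest.raises(ValueError, match="count_mean"):
            CohortConfig(count_mean_present=0.1, count_mean_absent=0.5).validate()
        with pytest.raises(ValueError, match="planted node"):
            CohortConfig(planted_hub_nodes=(95,)).validate()
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            CohortConfig(subject_edge_noise=1.5).validate()
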