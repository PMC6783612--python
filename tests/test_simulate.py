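import numpy as np
import pytest
import yaml

import connectokit as ck
from connectokit.errors import ConfigurationError
from connectokit.simulate import _subject_rng


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,field", [
        (dict(base_density=1.5), "base_density"),
        (dict(fa_mean=0.0), "fa_mean"),
        (dict(edge_removal_prob=-0.1), "edge_removal_prob"),
        (dict(kappa_target=2.0), "kappa_target"),
        (dict(clinical_rho=1.0), "clinical_rho"),
        (dict(n_nodes=20, planted_component=[(3, 3)]), "planted_component"),
        (dict(n_nodes=20, planted_component=[(0, 25)]), "planted_component"),
        (dict(n_nodes=20, degree_deficit_nodes=[21]), "degree_deficit_nodes"),
    ])
    def test_invalid_fields_are_named(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            ck.SimulationConfig(**kwargs)

    def test_default_planted_component_is_ten_edge_star(self):
        cfg = ck.SimulationConfig()
        edges = cfg.planted_edges
        assert len(edges) == 10
        nodes = {v for e in edges for v in e}
        assert len(nodes) == 11

    def test_null_config_has_no_effects(self):
        cfg = ck.SimulationConfig.null()
        assert cfg.planted_edges == [] and cfg.deficit_nodes == []
        assert cfg.fa_effect == 0.0 and cfg.edge_removal_prob == 0.0


class TestControlConnectome:
    def test_full_density_gives_complete_graph(self):
        cfg = ck.SimulationConfig.null(n_nodes=4, base_density=1.0)
        m = ck.generate_control_connectome(cfg, np.random.default_rng(0))
        assert ck.node_degree(m).tolist() == [3, 3, 3, 3]

    def test_zero_density_gives_empty_graph(self):
        cfg = ck.SimulationConfig.null(n_nodes=6, base_density=0.0)
        m = ck.generate_control_connectome(cfg, np.random.default_rng(0))
        assert m.n_edges == 0

    def test_mean_degree_matches_density(self):
        """Expected nodal degree is base_density * (N-1) (~110.8 at the
        default density for 164 nodes)."""
        cfg = ck.SimulationConfig.null(n_nodes=164, base_density=0.68)
        rng = np.random.default_rng(5)
        means = [ck.mean_degree(ck.generate_control_connectome(cfg, rng))
                 for _ in range(60)]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.68 * 163) < max(3 * se, 0.5)

    def test_weights_in_open_unit_interval(self, small_cohort):
        for s in small_cohort.cohort.subjects:
            w = s.matrix.weights
            vals = w[w > 0]
            assert vals.min() > 0 and vals.max() < 1


class TestPatientEffects:
    def test_identity_when_no_effects(self, rng):
        cfg = ck.SimulationConfig.null(n_nodes=20, degree_sd=4.0)
        m = ck.generate_control_connectome(cfg, rng)
        out = ck.apply_patient_effects(m, cfg, rng)
        assert np.array_equal(out.weights, m.weights)

    def test_full_removal_empties_deficit_node(self, rng):
        cfg = ck.SimulationConfig.null(n_nodes=20, degree_sd=4.0,
                                       degree_deficit_nodes=[3],
                                       edge_removal_prob=1.0)
        m = ck.generate_control_connectome(cfg, rng)
        out = ck.apply_patient_effects(m, cfg, rng)
        assert ck.node_degree(out)[3] == 0

    def test_planted_fa_reduction_matches_effect_size(self):
        """Mean patient-vs-control FA gap on planted edges ~ fa_effect."""
        diffs = []
        for seed in range(40):
            cfg = ck.SimulationConfig(
                n_nodes=20, n_patients=6, n_controls=6, degree_sd=4.0,
                planted_component=[(0, 1), (2, 3)], fa_effect=0.1,
                degree_deficit_nodes=[], edge_removal_prob=0.0,
                clinical_rho=0.0, subject_edge_noise=0.0, seed=seed)
            synth = ck.generate_cohort(cfg)
            stack = synth.cohort.stack()
            pat = synth.cohort.is_patient_mask()
            for i, j in cfg.planted_edges:
                diffs.append(stack[~pat, i, j].mean() - stack[pat, i, j].mean())
        assert np.mean(diffs) == pytest.approx(0.1, abs=0.01)

    def test_kappa_requires_reference(self, rng):
        cfg = ck.SimulationConfig.null(n_nodes=20, degree_sd=4.0,
                                       kappa_target=-0.5)
        m = ck.generate_control_connectome(cfg, rng)
        with pytest.raises(ConfigurationError, match="kappa_target"):
            ck.apply_patient_effects(m, cfg, rng)


class TestDeterminism:
    def test_same_seed_reproduces_bit_identically(self, small_config):
        a = ck.generate_cohort(small_config)
        b = ck.generate_cohort(small_config)
        for s0, s1 in zip(a.cohort.subjects, b.cohort.subjects):
            assert np.array_equal(s0.matrix.weights, s1.matrix.weights)
            if s0.clinical is not None:
                assert s0.clinical == s1.clinical

    def test_subject_substreams_stable_under_cohort_growth(self):
        cfg5 = ck.SimulationConfig.null(n_nodes=30, n_patients=4,
                                        n_controls=5, degree_sd=5.0, seed=3)
        cfg6 = ck.SimulationConfig.null(n_nodes=30, n_patients=4,
                                        n_controls=6, degree_sd=5.0, seed=3)
        a = ck.generate_cohort(cfg5)
        b = ck.generate_cohort(cfg6)
        assert np.array_equal(a.matrices["sub-C01"].weights,
                              b.matrices["sub-C01"].weights)

    def test_subject_streams_keyed_by_id(self):
        s1 = _subject_rng(7, "sub-P01").random(3)
        s2 = _subject_rng(7, "sub-P02").random(3)
        assert not np.array_equal(s1, s2)


class TestClinical:
    def test_controls_get_no_clinical_scores(self, small_cohort):
        assert all(s.clinical is None for s in small_cohort.cohort.controls)
        assert all(s.clinical is not None for s in small_cohort.cohort.patients)

    def test_progression_formula_holds_exactly(self, small_cohort):
        for s in small_cohort.cohort.patients:
            rate = (48 - s.clinical.alsfrs_r) / s.clinical.duration_months
            assert s.clinical.progression_rate == rate

    def test_zero_rho_gives_near_zero_correlation(self):
        rhos = []
        for seed in range(30):
            cfg = ck.SimulationConfig.null(n_nodes=30, n_patients=10,
                                           n_controls=4, degree_sd=5.0,
                                           clinical_rho=0.0, seed=seed)
            synth = ck.generate_cohort(cfg)
            node = cfg.clinical_node_index
            vals = [ck.node_degree(s.matrix)[node]
                    for s in synth.cohort.patients]
            rates = [s.clinical.progression_rate
                     for s in synth.cohort.patients]
            rho, _ = ck.spearman_correlation(vals, rates)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError, match="clinical_rho"):
            ck.SimulationConfig(clinical_rho=-1.0)


class TestTruthRecord:
    def test_truth_round_trips_through_yaml(self, tmp_path, small_cohort):
        ck.write_cohort(small_cohort.cohort, tmp_path,
                        truth=small_cohort.truth)
        with open(tmp_path / "truth.yaml") as fh:
            back = yaml.safe_load(fh)
        assert back["planted_edges"] == [list(e) for e in
                                         small_cohort.config.planted_edges]
        assert back["deficit_nodes"] == small_cohort.config.deficit_nodes
        assert back["seed"] == small_cohort.config.seed

    def test_truth_suffices_to_locate_planted_effects(self, small_cohort):
        truth = small_cohort.truth
        stack = small_cohort.cohort.stack()
        pat = small_cohort.cohort.is_patient_mask()
        gaps = [stack[~pat, i, j].mean() - stack[pat, i, j].mean()
                for i, j in truth["planted_edges"]]
        assert np.mean(gaps) > truth["fa_effect"] / 2
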