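import dataclasses

import numpy as np
import pandas as pd
import pytest

from circenet.network import CIRC, MRNA, build_circenet, triple_keys
from circenet.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genesets,
    simulate_interactions,
    simulate_known_lists,
    simulate_mirna_expression,
    simulate_study,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frac_de=-0.1),
            dict(frac_de=1.2),
            dict(background_edge_prob=2.0),
            dict(d0=0.0),
            dict(d0=float("nan")),
            dict(s0_sq=-1.0),
            dict(effect_mean=float("inf")),
            dict(n_features=0),
            dict(n_mrna=2000, n_features=100),
            dict(shared_pool=500, n_mir=100),
            dict(n_planted_circ=100, n_circ=10),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, **kwargs)


class TestExpression:
    def test_seeded_determinism(self, fast_config):
        a, _ = simulate_expression(fast_config)
        b, _ = simulate_expression(fast_config)
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da.values, db.values)
            assert da.tag == db.tag

    def test_no_signal_case(self, fast_config):
        cfg = dataclasses.replace(fast_config, frac_de=0.0, n_planted_circ=0)
        datasets, truth = simulate_expression(cfg)
        assert truth.de_features == set()
        # large-sample check that group means coincide per feature
        big = dataclasses.replace(cfg, n_case=200, n_control=200, n_datasets=1,
                                  n_features=50, n_mrna=50)
        ds = simulate_expression(big)[0][0]
        diff = ds.group_values("case").mean(axis=1) - ds.group_values("control").mean(axis=1)
        assert np.abs(diff).max() < 0.5

    def test_de_membership_shared_across_datasets(self, fast_config):
        datasets, truth = simulate_expression(fast_config)
        assert len(datasets) == fast_config.n_datasets
        assert len(truth.de_features) == round(fast_config.frac_de * fast_config.n_features)
        assert truth.planted_mrnas <= truth.de_features

    def test_variance_prior_roundtrip_through_estimator(self):
        """EB hyperparameter estimates on simulated data recover the
        generating prior."""
        from circenet.diffexpr import moderated_t

        d0s, s0s = [], []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_features=5000, n_datasets=1,
                                   n_case=3, n_control=3, frac_de=0.0,
                                   n_planted_circ=0, n_mrna=100)
            ds = simulate_expression(cfg)[0][0]
            ms = moderated_t(ds)
            d0s.append(ms.d0)
            s0s.append(ms.s0_sq)
        assert np.mean(d0s) == pytest.approx(4.0, rel=0.2)
        assert np.mean(s0s) == pytest.approx(0.05, rel=0.1)

    def test_simulated_variance_mean_matches_prior_moment(self):
        """Over many seeds, mean sigma^2 ~= s0^2 d0/(d0-2)."""
        means = []
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, n_features=1000, n_datasets=1,
                                   n_case=2, n_control=2, frac_de=0.0,
                                   n_planted_circ=0, n_mrna=100)
            ds = simulate_expression(cfg)[0][0]
            # residual variance estimate pools both groups
            v = (ds.group_values("case").var(axis=1, ddof=1)
                 + ds.group_values("control").var(axis=1, ddof=1)) / 2
            means.append(v.mean())
        expected = 0.05 * 4.0 / 2.0
        assert np.mean(means) == pytest.approx(expected, rel=0.1)


class TestInteractions:
    def test_forced_single_pair_counts(self):
        cfg = SimulationConfig(seed=3, n_planted_circ=1, n_pairs_per_circ=1,
                               shared_pool=5, background_edge_prob=0.0)
        iset, truth = simulate_interactions(cfg)
        assert len(iset) == 10
        assert sum(1 for e in iset.edges if e[2] == CIRC) == 5
        assert sum(1 for e in iset.edges if e[2] == MRNA) == 5

    def test_noise_free_enumeration_recovers_planted_exactly(self, fast_config):
        cfg = dataclasses.replace(fast_config, background_edge_prob=0.0)
        iset, truth = simulate_interactions(cfg)
        _, triples = build_circenet(iset, min_shared=5)
        assert triple_keys(triples) == truth.planted_triples

    def test_planted_subset_with_noise(self, fast_study):
        _, triples = build_circenet(fast_study.interactions, min_shared=5)
        assert fast_study.truth.planted_triples <= triple_keys(triples)

    def test_pool_larger_than_mir_universe_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, shared_pool=120, n_mir=100)


class TestKnownListsAndGenesets:
    def test_requested_counts_validated(self, fast_config):
        _, truth = simulate_interactions(fast_config)
        bad = dataclasses.replace(fast_config, n_known_genes=10**6)
        with pytest.raises(ValueError):
            simulate_known_lists(bad, truth)

    def test_empty_known_lists_give_zero_risk(self, fast_config):
        from circenet.disease import DiseaseAnnotation, flag_risk_triples

        cfg = dataclasses.replace(fast_config, n_known_genes=0, n_known_mirs=0)
        _, truth = simulate_interactions(cfg)
        truth = simulate_known_lists(cfg, truth)
        assert truth.known_genes == set() and truth.known_mirs == set()
        ann = DiseaseAnnotation.build(known_genes=truth.known_genes,
                                      known_mirs=truth.known_mirs)
        assert flag_risk_triples(truth.planted_triple_objects(), ann) == []

    def test_risk_circ_strictly_dominates_planted_risk_counts(self, fast_study):
        counts = fast_study.truth.risk_counts()
        top = counts.pop(fast_study.truth.planted_risk_circ)
        assert top > max(counts.values(), default=-1)

    def test_known_lists_deterministic(self, fast_config):
        _, t1 = simulate_interactions(fast_config)
        _, t2 = simulate_interactions(fast_config)
        t1 = simulate_known_lists(fast_config, t1)
        t2 = simulate_known_lists(fast_config, t2)
        assert t1.known_genes == t2.known_genes and t1.known_mirs == t2.known_mirs

    def test_geneset_bytes_deterministic(self, fast_config, tmp_path):
        from circenet.io import write_gmt

        _, truth = simulate_interactions(fast_config)
        paths = []
        for name in ("a.gmt", "b.gmt"):
            gs, _ = simulate_genesets(fast_config, truth)
            write_gmt(gs, tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_planted_set_is_exact_query_superset(self, fast_config):
        _, truth = simulate_interactions(fast_config)
        gs, truth = simulate_genesets(fast_config, truth)
        assert truth.enriched_term in gs.sets
        assert truth.planted_mrnas <= gs.sets[truth.enriched_term]

    def test_oversized_geneset_rejected(self, fast_config):
        cfg = dataclasses.replace(fast_config, geneset_size=10**5)
        _, truth = simulate_interactions(cfg)
        with pytest.raises(ValueError):
            simulate_genesets(cfg, truth)


class TestStudy:
    def test_component_streams_independent(self, fast_config):
        """Regenerating interactions does not perturb expression values."""
        ds_a, _ = simulate_expression(fast_config)
        simulate_interactions(fast_config)
        ds_b, _ = simulate_expression(fast_config)
        pd.testing.assert_frame_equal(ds_a[0].values, ds_b[0].values)

    def test_study_is_reproducible(self, fast_config):
        s1 = simulate_study(fast_config)
        s2 = simulate_study(fast_config)
        assert s1.truth.planted_risk_circ == s2.truth.planted_risk_circ
        assert s1.interactions.edges == s2.interactions.edges
        pd.testing.assert_frame_equal(s1.mir_dataset.values, s2.mir_dataset.values)

    def test_mirna_dataset_shape(self, fast_config):
        ds, truth = simulate_mirna_expression(fast_config)
        assert ds.n_case == fast_config.n_mir_case
        assert ds.n_control == fast_config.n_mir_control
        assert len(ds.values) == fast_config.n_mir
        assert truth.de_mirs <= set(ds.values.index)
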