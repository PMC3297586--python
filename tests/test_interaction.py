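"""Additive-neutrality model: cell-mean estimator, inference, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import giquant as gq
from giquant.errors import (
    DuplicateRecordError,
    IncompleteDesignError,
    InvalidInputError,
    MissingViabilityError,
)
from giquant.fitness import FitnessRecord

from conftest import make_config


def _rec(strain, fitness, plate="p1", temp=30.0):
    return FitnessRecord(strain=strain, plate_id=plate, temperature=temp,
                         fitness=fitness, normalized=True)


def _design(rng, n_queries, n_genes, reps, effects_scale=0.3, noise=0.05):
    """Random saturated design with known cell structure; returns records."""
    wt = 7.0
    alphas = {f"q{i}": float(rng.normal(0, effects_scale)) for i in range(n_queries)}
    betas = {f"g{j}": float(rng.normal(0, effects_scale)) for j in range(n_genes)}
    eps = {(q, g): float(rng.normal(0, effects_scale))
           for q in alphas for g in betas}
    records = []
    for _ in range(reps["wt"]):
        records.append(_rec(gq.StrainLabel.wild_type(), wt + float(rng.normal(0, noise))))
    for q, a in alphas.items():
        for _ in range(reps["single"]):
            records.append(_rec(gq.StrainLabel.query_single(q),
                                wt + a + float(rng.normal(0, noise))))
    for g, b in betas.items():
        for _ in range(reps["single"]):
            records.append(_rec(gq.StrainLabel.array_single(g),
                                wt + b + float(rng.normal(0, noise))))
    for (q, g), e in eps.items():
        for _ in range(reps["double"]):
            records.append(_rec(gq.StrainLabel.double(q, g),
                                wt + alphas[q] + betas[g] + e + float(rng.normal(0, noise))))
    return records


def _lstsq_epsilons(records):
    """Independent oracle: generic least-squares solve of the saturated design."""
    queries = sorted({r.strain.query_id for r in records if r.strain.query_id})
    genes = sorted({r.strain.gene_id for r in records if r.strain.gene_id})
    pairs = sorted({(r.strain.query_id, r.strain.gene_id)
                    for r in records if r.strain.role == "double"})
    cols = ["mu"] + [f"a_{q}" for q in queries] + [f"b_{g}" for g in genes] + [
        f"e_{q}_{g}" for q, g in pairs
    ]
    col_idx = {c: i for i, c in enumerate(cols)}
    design = np.zeros((len(records), len(cols)))
    y = np.zeros(len(records))
    for i, r in enumerate(records):
        design[i, 0] = 1.0
        if r.strain.query_id:
            design[i, col_idx[f"a_{r.strain.query_id}"]] = 1.0
        if r.strain.gene_id:
            design[i, col_idx[f"b_{r.strain.gene_id}"]] = 1.0
        if r.strain.role == "double":
            design[i, col_idx[f"e_{r.strain.query_id}_{r.strain.gene_id}"]] = 1.0
        y[i] = r.fitness
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return {pair: coef[col_idx[f"e_{pair[0]}_{pair[1]}"]] for pair in pairs}


class TestFit:
    def test_noise_free_null_gives_zero_epsilon(self, null_effects):
        curves, _ = gq.simulate_plate_set(make_config(null_effects, noise_sd=0.0))
        _fit, ests = gq.estimate_from_curves(curves, 30.0)
        assert len(ests) == 4
        for e in ests:
            assert abs(e.epsilon_hat) < 1e-9

    def test_recovery_matches_lstsq_oracle(self, small_effects):
        curves, _ = gq.simulate_plate_set(make_config(small_effects, seed=3, noise_sd=0.02))
        fits = [gq.log_fitness(c) for c in curves]
        normalized = gq.normalize_plates(fits)
        _fit, ests = gq.fit_interaction_model(normalized, 30.0)
        target = {(e.query_id, e.gene_id): e for e in ests}[("q1", "g1")]
        assert abs(target.epsilon_hat - (-0.4)) < 3 * target.se
        oracle = _lstsq_epsilons(normalized)
        for e in ests:
            assert e.epsilon_hat == pytest.approx(
                oracle[(e.query_id, e.gene_id)], abs=1e-8
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30)
    def test_cell_means_equal_lstsq_on_random_small_designs(self, seed):
        rng = np.random.default_rng(seed)
        records = _design(
            rng,
            n_queries=int(rng.integers(1, 5)),
            n_genes=int(rng.integers(1, 7)),
            reps={"wt": int(rng.integers(2, 6)),
                  "single": int(rng.integers(2, 4)),
                  "double": int(rng.integers(2, 4))},
        )
        _fit, ests = gq.fit_interaction_model(records, 30.0)
        oracle = _lstsq_epsilons(records)
        for e in ests:
            assert e.epsilon_hat == pytest.approx(
                oracle[(e.query_id, e.gene_id)], abs=1e-8
            )

    @given(st.floats(-5, 5))
    def test_epsilon_location_invariant(self, shift):
        rng = np.random.default_rng(99)
        records = _design(rng, 2, 2, {"wt": 4, "single": 3, "double": 3})
        _f1, base = gq.fit_interaction_model(records, 30.0)
        shifted = [
            FitnessRecord(r.strain, r.plate_id, r.temperature, r.fitness + shift, True)
            for r in records
        ]
        _f2, moved = gq.fit_interaction_model(shifted, 30.0)
        for a, b in zip(base, moved):
            assert b.epsilon_hat == pytest.approx(a.epsilon_hat, abs=1e-9)

    def test_bonferroni_monotone(self, small_effects):
        curves, _ = gq.simulate_plate_set(make_config(small_effects, seed=5, noise_sd=0.02))
        _fit, ests = gq.estimate_from_curves(curves, 30.0)
        for e in ests:
            assert e.p_bonferroni >= e.p_value
            assert e.p_bonferroni <= 1.0
            assert e.p_bonferroni == pytest.approx(min(1.0, e.p_value * len(ests)))

    def test_double_without_single_is_incomplete(self):
        records = [
            _rec(gq.StrainLabel.wild_type(), 7.0),
            _rec(gq.StrainLabel.wild_type(), 7.1),
            _rec(gq.StrainLabel.query_single("q1"), 6.8),
            _rec(gq.StrainLabel.double("q1", "g1"), 6.0),
        ]
        with pytest.raises(IncompleteDesignError):
            gq.fit_interaction_model(records, 30.0)

    def test_unnormalized_records_rejected(self):
        rec = FitnessRecord(gq.StrainLabel.wild_type(), "p1", 30.0, 7.0, normalized=False)
        with pytest.raises(InvalidInputError):
            gq.fit_interaction_model([rec], 30.0)

    def test_no_residual_df_returns_estimates_without_p(self):
        records = [
            _rec(gq.StrainLabel.wild_type(), 7.0),
            _rec(gq.StrainLabel.query_single("q1"), 6.8),
            _rec(gq.StrainLabel.array_single("g1"), 6.9),
            _rec(gq.StrainLabel.double("q1", "g1"), 6.2),
        ]
        fit, ests = gq.fit_interaction_model(records, 30.0)
        assert fit.residual_df == 0
        e = ests[0]
        assert e.epsilon_hat == pytest.approx(6.2 - 6.8 - 6.9 + 7.0)
        assert e.p_value is None and e.se is None

    def test_null_type_i_error_calibrated(self, null_effects):
        rejections = 0
        total = 0
        for seed in range(400):
            curves, _ = gq.simulate_plate_set(
                make_config(null_effects, seed=seed, noise_sd=0.02)
            )
            _fit, ests = gq.estimate_from_curves(curves, 30.0)
            rejections += sum(e.p_value < 0.05 for e in ests)
            total += len(ests)
        assert 0.03 <= rejections / total <= 0.07

    def test_mean_bias_near_zero(self):
        for true_eps in (-0.3, 0.0):
            effects = gq.TrueEffects(
                wt_fitness=7.0, query_effects={"q1": -0.2},
                gene_effects={"g1": -0.1}, interactions={("q1", "g1"): true_eps},
            )
            errors = []
            for seed in range(100):
                curves, _ = gq.simulate_plate_set(
                    make_config(effects, seed=seed, noise_sd=0.02)
                )
                _f, ests = gq.estimate_from_curves(curves, 30.0)
                errors.append(ests[0].epsilon_hat - true_eps)
            assert abs(float(np.mean(errors))) < 0.02


class TestClassify:
    def _estimate(self, q, g, eps, p, temp=30.0):
        return gq.InteractionEstimate(
            query_id=q, gene_id=g, epsilon_hat=eps, se=0.05, t_stat=eps / 0.05,
            p_value=p, p_bonferroni=min(1.0, p * 4), n_double=3, temperature=temp,
        )

    def test_inviable_pair_is_sl_without_growth_data(self):
        spores = [gq.RandomSporeResult("q1", "g1", double_viable=False)]
        edges = gq.classify_interactions([], spores)
        assert len(edges) == 1
        assert edges[0].edge_class == "SL"
        assert edges[0].provenance == "random_spore"

    def test_significant_negative_epsilon_is_ss(self):
        spores = [gq.RandomSporeResult("q1", "g1", True)]
        edges = gq.classify_interactions([self._estimate("q1", "g1", -0.5, 0.001)], spores)
        assert edges[0].edge_class == "SS"
        assert edges[0].strength == pytest.approx(0.5)

    def test_alleviating_interaction_yields_no_edge(self):
        spores = [gq.RandomSporeResult("q1", "g1", True)]
        edges = gq.classify_interactions([self._estimate("q1", "g1", 0.4, 0.001)], spores)
        assert edges == []

    def test_missing_spore_record_is_an_error(self):
        with pytest.raises(MissingViabilityError):
            gq.classify_interactions([self._estimate("q1", "g1", -0.5, 0.001)], [])

    def test_duplicate_spore_record_rejected(self):
        spores = [gq.RandomSporeResult("q1", "g1", True),
                  gq.RandomSporeResult("q1", "g1", False)]
        with pytest.raises(DuplicateRecordError):
            gq.classify_interactions([], spores)

    def test_cross_temperature_merge_keeps_smaller_p(self):
        spores = [gq.RandomSporeResult("q1", "g1", True)]
        ests = [self._estimate("q1", "g1", -0.2, 0.04, temp=26.0),
                self._estimate("q1", "g1", -0.5, 0.001, temp=30.0)]
        edges = gq.classify_interactions(ests, spores)
        assert edges[0].strength == pytest.approx(0.5)

    def test_bonferroni_edge_set_is_subset_of_raw(self):
        spores = [gq.RandomSporeResult("q1", f"g{i}", True) for i in range(4)]
        ests = [self._estimate("q1", f"g{i}", -0.3, p)
                for i, p in enumerate([0.001, 0.02, 0.04, 0.3])]
        raw = {(e.query_id, e.gene_id)
               for e in gq.classify_interactions(ests, spores, use_bonferroni=False)}
        bonf = {(e.query_id, e.gene_id)
                for e in gq.classify_interactions(ests, spores, use_bonferroni=True)}
        assert bonf <= raw
        assert len(bonf) < len(raw)

    def test_multiple_alleles_keep_most_negative_epsilon(self):
        spores = [gq.RandomSporeResult("q1", "g1", True)]
        ests = [self._estimate("q1", "g1", -0.2, 0.01),
                self._estimate("q1", "g1", -0.6, 0.01)]
        edges = gq.classify_interactions(ests, spores)
        assert len(edges) == 1
        assert edges[0].strength == pytest.approx(0.6)
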