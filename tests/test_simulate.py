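import numpy as np
import pandas as pd
import pytest

from clonoshift.antigen import match_signature
from clonoshift.diversity import clonality
from clonoshift.divergence import paired_divergence
from clonoshift.errors import ConfigError
from clonoshift.scoring import build_cluster_signature, enrichment_scores
from clonoshift.survival import median_split
from clonoshift.simulate import (
    ExpressionStudy,
    RepertoireSimConfig,
    TreatmentEffectConfig,
    apply_treatment_effect,
    make_expression_signature,
    make_tcr_signature,
    simulate_expression_study,
    simulate_growth_series,
    simulate_repertoire,
    simulate_survival_cohort,
)


class TestSimulateRepertoire:
    def test_same_seed_identical(self):
        cfg = RepertoireSimConfig(n_clones=300)
        a = simulate_repertoire(cfg, seed=5)
        b = simulate_repertoire(cfg, seed=5)
        pd.testing.assert_frame_equal(a.clones, b.clones)

    def test_different_seed_differs(self):
        cfg = RepertoireSimConfig(n_clones=300)
        a = simulate_repertoire(cfg, seed=5)
        b = simulate_repertoire(cfg, seed=6)
        assert set(a.clones["cdr3_aa"]) != set(b.clones["cdr3_aa"])

    def test_planted_mass_recovered_at_depth(self):
        sig = make_tcr_signature(n=60, seed=0)
        cfg = RepertoireSimConfig(
            n_clones=1000,
            signature=sig,
            signature_clones=40,
            signature_mass=0.25,
            sequencing_depth=100_000,
        )
        rep = simulate_repertoire(cfg, seed=3)
        part = match_signature(rep, sig)
        assert part.signature_frequency == pytest.approx(0.25, abs=0.02)

    def test_dirichlet_high_concentration_evens_repertoire(self):
        cfg = RepertoireSimConfig(
            n_clones=500,
            frequency_law="dirichlet",
            conc=1e6,
            sequencing_depth=None,
        )
        rep = simulate_repertoire(cfg, seed=1)
        assert clonality(rep) < 1e-3

    def test_infeasible_configs_rejected(self):
        with pytest.raises(ConfigError):
            RepertoireSimConfig(n_clones=10, signature_clones=3,
                                signature_mass=0.2)
        sig = make_tcr_signature(n=2, seed=0)
        with pytest.raises(ConfigError):
            RepertoireSimConfig(n_clones=10, signature=sig,
                                signature_clones=5, signature_mass=0.2)

    def test_frequencies_normalized(self):
        cfg = RepertoireSimConfig(n_clones=200, sequencing_depth=None)
        rep = simulate_repertoire(cfg, seed=9)
        assert rep.frequencies.sum() == pytest.approx(1.0, abs=1e-9)


class TestTreatmentEffect:
    def test_null_effect_close_to_pre(self):
        cfg = RepertoireSimConfig(n_clones=500, sequencing_depth=100_000)
        pre = simulate_repertoire(cfg, seed=2)
        null = TreatmentEffectConfig(sequencing_depth=100_000)
        post = apply_treatment_effect(pre, null, seed=3)
        res = paired_divergence(pre, post, n_top=300)
        assert res.jsd_rank < 0.02  # resampling noise only
        assert res.jsd_vj < 0.02

    def test_expansion_raises_clonality(self):
        cfg = RepertoireSimConfig(n_clones=300, sequencing_depth=20_000)
        effect = TreatmentEffectConfig(
            expansion_fraction=0.01,
            expansion_factor=20.0,
            sequencing_depth=20_000,
        )
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            pre = simulate_repertoire(cfg, seed=seed)
            post = apply_treatment_effect(pre, effect, seed=seed + 1000)
            wins += clonality(post) > clonality(pre)
        assert wins >= 0.95 * n_seeds

    def test_tilt_preserves_clone_identity(self):
        cfg = RepertoireSimConfig(n_clones=200, sequencing_depth=None)
        pre = simulate_repertoire(cfg, seed=4)
        effect = TreatmentEffectConfig(tilt_exponent=1.3,
                                       sequencing_depth=None)
        post = apply_treatment_effect(pre, effect, seed=5)
        assert set(post.clones["cdr3_aa"]) == set(pre.clones["cdr3_aa"])
        assert clonality(post) > clonality(pre)


class TestExpressionStudy:
    def test_null_effect_centered(self):
        sig = make_expression_signature(n_genes=20, seed=0)
        diffs = []
        for seed in range(20):
            study = simulate_expression_study(
                sig, n_per_group=10, effect_scale=0.0, noise_sd=0.2,
                seed=seed,
            )
            scores = enrichment_scores(study.expr, sig)
            treated = scores[study.groups == "treated"].mean()
            control = scores[study.groups == "control"].mean()
            diffs.append(treated - control)
        assert abs(np.mean(diffs)) < 0.05

    def test_power_at_stated_conditions(self):
        sig = make_expression_signature(n_genes=25, seed=1)
        positive = 0
        for seed in range(30):
            study = simulate_expression_study(
                sig, n_per_group=20, effect_scale=1.0, noise_sd=0.1,
                seed=seed,
            )
            scores = enrichment_scores(study.expr, sig)
            positive += (
                scores[study.groups == "treated"].mean()
                > scores[study.groups == "control"].mean()
            )
        assert positive == 30

    def test_round_trip_signature_recovery(self):
        sig = make_expression_signature(n_genes=30, seed=2)
        study = simulate_expression_study(sig, seed=3)
        rebuilt = build_cluster_signature(
            study.de_sc, study.de_bulk, sc_log2fc_min=0.5, p_max=0.01,
            bulk_fc_min=1.3,
        )
        recovered = set(rebuilt.genes) & set(sig.genes)
        assert len(recovered) >= 0.9 * sig.n
        # no background genes sneak in
        assert all(g.startswith("SIG") for g in rebuilt.genes)


class TestSurvivalCohort:
    def test_protective_score_orders_survival(self, rng):
        scores = rng.normal(size=400)
        recs = simulate_survival_cohort(
            scores, log_hr=-0.5, baseline_rate=0.02, censor_rate=0.002,
            seed=11,
        )
        labels = median_split(scores)
        high = [r.time for r, g in zip(recs, labels) if g == "high" and r.event]
        low = [r.time for r, g in zip(recs, labels) if g == "low" and r.event]
        assert np.median(high) > np.median(low)

    def test_extreme_censoring(self, rng):
        recs = simulate_survival_cohort(
            rng.normal(size=50), log_hr=0.0, baseline_rate=0.01,
            censor_rate=1e6, seed=1,
        )
        assert not any(r.event for r in recs)

    def test_deterministic_given_seed(self, rng):
        scores = rng.normal(size=30)
        a = simulate_survival_cohort(scores, log_hr=0.3, seed=5)
        b = simulate_survival_cohort(scores, log_hr=0.3, seed=5)
        assert [(r.time, r.event) for r in a] == [(r.time, r.event) for r in b]


def test_growth_series_deterministic():
    a = simulate_growth_series("SD", seed=9, jitter=0.1)
    b = simulate_growth_series("SD", seed=9, jitter=0.1)
    np.testing.assert_allclose(a.volumes, b.volumes)
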