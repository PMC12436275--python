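import numpy as np
import pytest

from paretomol import moo, rl
from paretomol.fixtures import toy_px_predictor
from paretomol.generator import clone_generator


@pytest.fixture()
def toy_objectives():
    return [
        moo.ObjectiveSpec("FURAN", "high_affinity",
                          toy_px_predictor("c1ccco1")),
        moo.ObjectiveSpec("PYRIDINE", "low_affinity",
                          toy_px_predictor("c1ccncc1")),
    ]


class TestEvolutionarySampling:
    def test_pure_agent_limit_matches_plain_sampling(self, trained_generator):
        """crossover threshold 1 (crover never chosen) and mutation off
        must reproduce exact plain agent sampling draws."""
        cfg = rl.EvolutionConfig(crossover_threshold=1.0,
                                 mutation_threshold=0.0, seed=4)
        crover = clone_generator(trained_generator)
        prior = clone_generator(trained_generator)
        # different weights so any accidental crover/prior use would show
        for p in crover.params + prior.params:
            p.value *= 0.5
        evo = rl.evolutionary_sample(trained_generator, crover, prior, 30,
                                     cfg, np.random.default_rng(9))
        evo2 = rl.evolutionary_sample(trained_generator, None, None, 30,
                                      cfg, np.random.default_rng(9))
        assert evo.smiles == evo2.smiles
        assert evo.log_probs == pytest.approx(evo2.log_probs, abs=1e-5)

    def test_mutation_off_means_prior_unused(self, trained_generator):
        cfg = rl.EvolutionConfig(crossover_threshold=1.0,
                                 mutation_threshold=0.0, seed=4)
        batch = rl.evolutionary_sample(trained_generator, None, None, 20,
                                       cfg, np.random.default_rng(0))
        assert len(batch) == 20

    def test_vocab_mismatch_rejected(self, trained_generator, tiny_generator):
        cfg = rl.EvolutionConfig(seed=0)
        import paretomol as pm
        other = pm.SmilesGenerator(
            pm.GeneratorConfig(vocab_size=4, embed_dim=8, hidden_size=8,
                               block_layers=1, num_blocks=1,
                               attention_heads=1, seed=0),
            pm.Vocabulary(["GO", "EOS", "C", "O"]))
        with pytest.raises(ValueError):
            rl.evolutionary_sample(trained_generator, other, None, 5, cfg)

    def test_reproducible_under_fixed_seed(self, trained_generator):
        cfg = rl.EvolutionConfig(seed=0)
        crover = clone_generator(trained_generator)
        prior = clone_generator(trained_generator)
        a = rl.evolutionary_sample(trained_generator, crover, prior, 15, cfg,
                                   np.random.default_rng(5))
        b = rl.evolutionary_sample(trained_generator, crover, prior, 15, cfg,
                                   np.random.default_rng(5))
        assert a.smiles == b.smiles


class TestRouletteSelection:
    def test_default_fraction_selects_20_of_100(self):
        scores = np.random.default_rng(0).random(100)
        idx = rl.roulette_select(scores, 0.2, np.random.default_rng(1))
        assert len(idx) == 20
        assert len(set(idx.tolist())) == 20

    def test_certain_winner_selected(self):
        scores = np.zeros(100)
        scores[42] = 1.0
        idx = rl.roulette_select(scores, 0.01, np.random.default_rng(2))
        assert list(idx) == [42]

    def test_all_zero_scores_uniform(self):
        idx = rl.roulette_select(np.zeros(50), 0.2, np.random.default_rng(3))
        assert len(set(idx.tolist())) == 10

    def test_deterministic_given_seed(self):
        scores = np.random.default_rng(4).random(60)
        a = rl.roulette_select(scores, 0.25, np.random.default_rng(7))
        b = rl.roulette_select(scores, 0.25, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            rl.roulette_select(np.array([-1.0, 2.0]), 0.5)

    def test_selection_biased_toward_high_scores(self):
        scores = np.r_[np.full(50, 0.01), np.full(50, 1.0)]
        rng = np.random.default_rng(8)
        hits = sum((rl.roulette_select(scores, 0.2, rng) >= 50).sum()
                   for _ in range(20))
        assert hits > 250  # >62% of 400 selections from the high block


class TestPolicyGradient:
    def test_zero_rewards_null_update(self, trained_generator):
        batch = trained_generator.sample(10, rng=np.random.default_rng(0))
        before = trained_generator.get_weights()
        loss = rl.policy_gradient_update(trained_generator, batch.sequences,
                                         np.zeros(10))
        assert loss == 0.0
        for a, b in zip(before, trained_generator.get_weights()):
            assert np.array_equal(a, b)

    def test_length_mismatch_raises(self, trained_generator):
        batch = trained_generator.sample(5, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            rl.policy_gradient_update(trained_generator, batch.sequences,
                                      np.ones(4))

    def test_identical_batches_identical_updates(self, vocab, toy_corpus):
        import paretomol as pm
        runs = []
        for _ in range(2):
            cfg = pm.GeneratorConfig(vocab_size=len(vocab), embed_dim=16,
                                     hidden_size=32, block_layers=1,
                                     num_blocks=1, attention_heads=2, seed=3)
            model = pm.SmilesGenerator(cfg, vocab)
            batch = model.sample(8, rng=np.random.default_rng(1))
            rl.policy_gradient_update(model, batch.sequences,
                                      np.linspace(0.1, 1, 8))
            runs.append(model.get_weights())
        for a, b in zip(*runs):
            assert np.array_equal(a, b)

    def test_rewarded_token_frequency_increases(self, trained_generator,
                                                vocab):
        """REINFORCE on an oxygen-containing-sequence reward must raise
        the sampled frequency of oxygen over training."""
        agent = clone_generator(trained_generator)
        o_idx = vocab.index("O")
        rng = np.random.default_rng(6)
        freqs = []
        for _ in range(25):
            batch = agent.sample(64, rng=rng)
            rewards = np.array([float(o_idx in s) for s in batch.sequences])
            freqs.append(rewards.mean())
            rl.policy_gradient_update(agent, batch.sequences, rewards)
        assert np.mean(freqs[-5:]) > np.mean(freqs[:5])


class TestMetrics:
    def test_ratio_definitions(self):
        smiles = ["CCO"] * 9 + ["C(("]
        valid = np.array([True] * 9 + [False])
        desirable = np.zeros(10, dtype=bool)
        m = rl.compute_metrics(smiles, valid, desirable, np.zeros(10))
        assert m.validity == pytest.approx(0.9)
        assert m.desirability == 0.0
        assert m.uniqueness == pytest.approx(0.1)  # one distinct structure

    def test_accumulated_set_suppresses_repeats(self):
        seen = {"CCO"}
        m = rl.compute_metrics(["CCO", "CCN"], np.array([True, True]),
                               np.zeros(2, dtype=bool), np.zeros(2), seen)
        assert m.uniqueness == pytest.approx(0.5)
        assert "CCN" in seen

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            rl.compute_metrics([], np.array([]), np.array([]), np.array([]))

    def test_metrics_bounded(self, trained_generator, toy_objectives):
        batch = trained_generator.sample(40, rng=np.random.default_rng(0))
        rewards, valid, desirable = moo.score_molecules(batch.smiles,
                                                        toy_objectives)
        m = rl.compute_metrics(batch.smiles, valid, desirable,
                               np.abs(rewards).mean(axis=1))
        for value in (m.validity, m.desirability, m.uniqueness):
            assert 0.0 <= value <= 1.0


class TestTrainRL:
    def _run(self, trained_generator, toy_objectives, scheme, tmp_path,
             epochs=2, sync=2):
        agent = clone_generator(trained_generator)
        prior = clone_generator(trained_generator)
        crover = clone_generator(trained_generator)
        cfg = rl.EvolutionConfig(epochs=epochs, batch_size=32,
                                 crover_sync_interval=sync, seed=11)
        return rl.train_rl(agent, toy_objectives, scheme, cfg, prior=prior,
                           crover=crover,
                           metrics_path=tmp_path / "metrics.csv",
                           checkpoint_path=tmp_path / "best.npz")

    @pytest.mark.parametrize("scheme", ["weighted", "pareto"])
    def test_smoke_run_writes_artifacts(self, trained_generator,
                                        toy_objectives, scheme, tmp_path):
        state, metrics = self._run(trained_generator, toy_objectives, scheme,
                                   tmp_path)
        assert len(metrics) == 2
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "best.npz").exists()
        for m in metrics:
            assert 0 <= m.validity <= 1
            assert 0 <= m.desirability <= 1
            assert 0 <= m.uniqueness <= 1
            assert m.mean_reward >= 0

    def test_prior_parameters_untouched(self, trained_generator,
                                        toy_objectives, tmp_path):
        prior = clone_generator(trained_generator)
        before = prior.get_weights()
        agent = clone_generator(trained_generator)
        cfg = rl.EvolutionConfig(epochs=3, batch_size=32,
                                 crover_sync_interval=2, seed=1)
        rl.train_rl(agent, toy_objectives, "pareto", cfg, prior=prior)
        for a, b in zip(before, prior.get_weights()):
            assert np.array_equal(a, b)

    def test_crover_synced_to_best_checkpoint(self, trained_generator,
                                              toy_objectives, tmp_path):
        agent = clone_generator(trained_generator)
        prior = clone_generator(trained_generator)
        crover = clone_generator(trained_generator)
        cfg = rl.EvolutionConfig(epochs=2, batch_size=32,
                                 crover_sync_interval=2, seed=2)
        state, _ = rl.train_rl(agent, toy_objectives, "weighted", cfg,
                               prior=prior, crover=crover)
        for a, b in zip(crover.get_weights(), state.best_weights):
            assert np.array_equal(a, b)

    def test_unknown_scheme_rejected(self, trained_generator, toy_objectives):
        with pytest.raises(ValueError):
            rl.train_rl(trained_generator, toy_objectives, "lexicographic",
                        rl.EvolutionConfig(epochs=1))


class TestCompositeRank:
    def test_affine_components(self):
        out = rl.composite_rank(["CCO"], np.array([1.0]), np.array([1.0]),
                                top_n=1)
        assert out[0][1] == pytest.approx(1.0)
        out = rl.composite_rank(["CCO"], np.array([0.5]), np.array([0.5]),
                                top_n=1)
        # 0.4*0.5 + 0.4*0.5 + 0.2*1 (first occurrence is unique)
        assert out[0][1] == pytest.approx(0.6)

    def test_duplicate_loses_uniqueness_credit(self):
        out = rl.composite_rank(["CCO", "OCC"], np.ones(2), np.ones(2),
                                top_n=2)
        scores = dict(out)
        assert max(scores.values()) == pytest.approx(1.0)
        assert min(scores.values()) == pytest.approx(0.8)

    def test_top_n_of_larger_batch(self, trained_generator):
        batch = trained_generator.sample(100, rng=np.random.default_rng(1))
        rng = np.random.default_rng(2)
        out = rl.composite_rank(batch.smiles, rng.random(100) > 0.5,
                                rng.random(100), top_n=10)
        assert len(out) == 10
        scores = [s for _, s in out]
        assert scores == sorted(scores, reverse=True)
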