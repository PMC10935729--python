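import numpy as np
import pytest
from scipy import stats

from molseal.chem import descriptor_matrix
from molseal.oracles import PseudoROCS
from molseal.surrogate import (PoolEntry, TrainingPool, adaptive_subsample,
                               fit_surrogate, lookahead_mae)


def _entries(mols, labels, epoch=0, X=None):
    X = descriptor_matrix(mols, "fast") if X is None else X
    return [PoolEntry(canonical=m.canonical_smiles, descriptors=x,
                      label=float(y), epoch=epoch)
            for m, x, y in zip(mols, X, labels)]


class TestTrainingPool:
    def test_window_trims_oldest(self, corpus_medium):
        pool = TrainingPool(window=1000)
        mols = corpus_medium[:1200]
        pool.add(_entries(mols, np.arange(1200)))
        # duplicates in the corpus collapse; everything kept is most recent
        assert len(pool) <= 1000
        kept_labels = [e.label for e in pool.entries]
        assert kept_labels == sorted(kept_labels)
        assert pool.entries[-1].label == 1199

    def test_duplicate_keeps_latest_label(self, corpus_small):
        pool = TrainingPool(window=10)
        mols = corpus_small[:3]
        pool.add(_entries(mols, [0.1, 0.2, 0.3]))
        pool.add(_entries([mols[0]], [0.9]))
        assert len(pool) == 3
        assert pool.entries[-1].canonical == mols[0].canonical_smiles
        assert pool.entries[-1].label == 0.9

    def test_empty_plus_five(self, corpus_small):
        pool = TrainingPool()
        pool.add(_entries(corpus_small[:5], np.linspace(0, 1, 5)))
        assert len(pool) == 5

    def test_nonfinite_label_rejected(self, corpus_small):
        pool = TrainingPool()
        with pytest.raises(ValueError):
            pool.add(_entries(corpus_small[:1], [np.nan]))


class TestFitPredict:
    def test_refit_is_deterministic(self, corpus_small):
        X = descriptor_matrix(corpus_small[:100], "fast")
        y = np.linspace(0, 1, 100)
        m1 = fit_surrogate((X, y), seed=3)
        m2 = fit_surrogate((X, y), seed=3)
        p1, s1 = m1.predict_matrix(X[:20])
        p2, s2 = m2.predict_matrix(X[:20])
        assert np.array_equal(p1, p2) and np.array_equal(s1, s2)

    def test_constant_labels_give_constant_certain_predictions(self, corpus_small):
        X = descriptor_matrix(corpus_small[:50], "fast")
        m = fit_surrogate((X, np.full(50, 0.42)), seed=0)
        mean, sd = m.predict_matrix(X[:10])
        assert np.allclose(mean, 0.42)
        assert np.allclose(sd, 0.0)

    def test_linear_descriptor_target_recovered(self, corpus_small):
        X = descriptor_matrix(corpus_small[:200], "fast")
        w = np.zeros(X.shape[1])
        w[0], w[5] = 1.0, 2.0  # MW and TPSA
        y = X @ w
        y = (y - y.min()) / (y.max() - y.min())
        m = fit_surrogate((X, y), seed=0)
        mean, _ = m.predict_matrix(X)
        assert np.abs(mean - y).mean() < 0.05  # < 5% of label range

    def test_too_small_pool_refuses_to_fit(self, corpus_small):
        X = descriptor_matrix(corpus_small[:1], "fast")
        assert fit_surrogate((X, np.array([0.5])), seed=0) is None

    def test_prediction_order_equivariance(self, corpus_small):
        X = descriptor_matrix(corpus_small[:60], "fast")
        y = np.linspace(0, 1, 60)
        m = fit_surrogate((X, y), seed=1)
        mean, sd = m.predict_matrix(X[:10])
        mean_r, sd_r = m.predict_matrix(X[:10][::-1])
        assert np.array_equal(mean[::-1], mean_r)
        assert np.array_equal(sd[::-1], sd_r)


class TestLearnability:
    def test_learns_smooth_descriptor_oracle(self, corpus_medium):
        """Held-out MAE on the noiseless similarity oracle beats a mean-only
        predictor by a wide margin after 500 labelled compounds."""
        oracle = PseudoROCS()
        train, hold = corpus_medium[:500], corpus_medium[500:800]
        Xtr = descriptor_matrix(train, "fast")
        ytr = oracle.score_many(train)
        Xho = descriptor_matrix(hold, "fast")
        yho = oracle.score_many(hold)
        model = fit_surrogate((Xtr, ytr), seed=0)
        mean, _ = model.predict_matrix(Xho)
        mae = np.abs(mean - yho).mean()
        baseline = np.abs(ytr.mean() - yho).mean()
        assert mae < 0.05
        assert mae < baseline / 3

    def test_no_hallucinated_signal_on_pure_noise(self, corpus_medium):
        """Labels drawn independently of structure: the forest must not beat
        the mean-only predictor (20 seeds, one-sided t-test)."""
        X = descriptor_matrix(corpus_medium[:300], "fast")
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=300)
            model = fit_surrogate((X[:200], y[:200]), seed=seed, n_trees=100)
            mean, _ = model.predict_matrix(X[200:])
            mae_rf = np.abs(mean - y[200:]).mean()
            mae_base = np.abs(y[:200].mean() - y[200:]).mean()
            diffs.append(mae_rf - mae_base)
        # one-sided test of "forest significantly better" must NOT reject
        t, p_two = stats.ttest_1samp(diffs, 0.0)
        p_better = p_two / 2 if t < 0 else 1.0
        assert p_better > 0.01


class TestAdaptiveSubsample:
    def _pool(self, corpus_medium, n=300):
        oracle = PseudoROCS()
        mols = corpus_medium[:n]
        pool = TrainingPool(window=10_000, selection_mode="adaptive")
        pool.add(_entries(mols, oracle.score_many(mols)))
        return pool

    def test_identity_when_pool_fits(self, corpus_small):
        pool = TrainingPool(selection_mode="adaptive")
        pool.add(_entries(corpus_small[:20], np.linspace(0, 1, 20)))
        sel = adaptive_subsample(pool, 30, cycles=2, seed=0)
        assert [e.canonical for e in sel] == [e.canonical for e in pool.entries]

    def test_exact_size_and_determinism(self, corpus_medium):
        pool = self._pool(corpus_medium)
        s1 = adaptive_subsample(pool, 60, cycles=3, seed=5, n_trees=30)
        s2 = adaptive_subsample(pool, 60, cycles=3, seed=5, n_trees=30)
        assert len(s1) == 60
        assert [e.canonical for e in s1] == [e.canonical for e in s2]

    def test_selects_higher_uncertainty_than_random(self, corpus_medium):
        """Across seeds, the adaptively chosen subset should carry at least
        as much model uncertainty as a size-matched random subset."""
        pool = self._pool(corpus_medium)
        X, y = pool.matrix()
        wins = 0
        for seed in range(10):
            chosen = adaptive_subsample(pool, 50, cycles=1, seed=seed, n_trees=30)
            ref = fit_surrogate((X, y), seed=seed, n_trees=30)
            _, sd_all = ref.predict_matrix(X)
            idx = {e.canonical: i for i, e in enumerate(pool.entries)}
            sd_sel = np.mean([sd_all[idx[e.canonical]] for e in chosen])
            rng = np.random.default_rng(1000 + seed)
            sd_rand = np.mean(sd_all[rng.choice(len(X), 50, replace=False)])
            wins += sd_sel >= sd_rand
        assert wins >= 7


class TestPersistence:
    def test_pool_csv_snapshot(self, corpus_small, tmp_path):
        import pandas as pd
        pool = TrainingPool()
        pool.add(_entries(corpus_small[:5], np.linspace(0, 1, 5), epoch=2))
        pool.to_csv(tmp_path / "pool.csv")
        back = pd.read_csv(tmp_path / "pool.csv")
        assert list(back.columns) == ["smiles", "label", "epoch"]
        assert len(back) == 5 and set(back["epoch"]) == {2}

    def test_model_blob_roundtrip(self, corpus_small, tmp_path):
        from molseal.surrogate import SurrogateModel
        X = descriptor_matrix(corpus_small[:60], "fast")
        y = np.linspace(0, 1, 60)
        model = fit_surrogate((X, y), seed=9)
        model.save(tmp_path / "surrogate")
        back = SurrogateModel.load(tmp_path / "surrogate")
        m1, s1 = model.predict_matrix(X[:8])
        m2, s2 = back.predict_matrix(X[:8])
        assert np.array_equal(m1, m2) and np.array_equal(s1, s2)


class TestLookaheadMAE:
    def test_memorized_constant_labels_give_zero(self, corpus_small):
        X = descriptor_matrix(corpus_small[:50], "fast")
        model = fit_surrogate((X, np.full(50, 0.3)), seed=0)
        assert lookahead_mae(model, X[:10], np.full(10, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_on_balanced_labels(self, corpus_small):
        X = descriptor_matrix(corpus_small[:40], "fast")
        model = fit_surrogate((X, np.full(40, 0.5)), seed=0)
        labels = np.array([0.0, 1.0] * 5)
        assert lookahead_mae(model, X[:10], labels) == pytest.approx(0.5)

    def test_empty_batch_rejected(self, corpus_small):
        X = descriptor_matrix(corpus_small[:10], "fast")
        model = fit_surrogate((X, np.linspace(0, 1, 10)), seed=0)
        with pytest.raises(ValueError):
            lookahead_mae(model, X[:0], [])
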