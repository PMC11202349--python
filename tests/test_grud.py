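import numpy as np
import pytest

from tdgan import GrudConfig, MaskedSeries
from tdgan.grud import (GrudParams, _backward, _forward, combine_estimate,
                        complete_vector, decay_factor, hidden_update, impute,
                        mae_loss, regress_estimate, run_grud, train_grud)
from tdgan.model import normalize_dataset
from tdgan.baselines import _feature_means
from tdgan.ugan import ImputationResult

from conftest import random_masked_series


class TestDecayFactor:
    def test_nonpositive_score_gives_one(self):
        v = decay_factor(np.array(1.0), W=np.array([-2.0]), b=np.array([0.0]))
        assert np.allclose(v, 1.0)

    def test_closed_form(self):
        v = decay_factor(np.array(1.0), W=np.array([1.0]), b=np.array([0.0]))
        assert v[0] == pytest.approx(np.exp(-1.0))

    def test_nonincreasing_in_uncertainty(self, rng):
        W = np.abs(rng.normal(size=4))
        b = rng.normal(size=4)
        us = np.linspace(0, 5, 20)
        vs = np.array([decay_factor(np.array(u), W, b) for u in us])
        assert (np.diff(vs, axis=0) <= 1e-15).all()

    def test_range_property(self, rng):
        for _ in range(50):
            v = decay_factor(np.abs(rng.normal()), rng.normal(size=3),
                             rng.normal(size=3))
            assert ((v > 0.0) & (v <= 1.0)).all()


class TestRegressEstimate:
    def test_zero_hidden_returns_bias(self, rng):
        Wr, br = rng.normal(size=(3, 5)), rng.normal(size=3)
        assert np.allclose(regress_estimate(np.zeros(5), Wr, br), br)

    def test_zero_weights_ignore_history(self, rng):
        br = rng.normal(size=3)
        out = regress_estimate(rng.normal(size=5), np.zeros((3, 5)), br)
        assert np.allclose(out, br)

    def test_affine_in_hidden_state(self, rng):
        Wr, br = rng.normal(size=(3, 5)), rng.normal(size=3)
        h = rng.normal(size=5)
        base = regress_estimate(np.zeros(5), Wr, br)
        assert np.allclose(regress_estimate(2 * h, Wr, br) - base,
                           2 * (regress_estimate(h, Wr, br) - base))


class TestCombineComplete:
    def test_full_trust_in_fill(self, rng):
        xb, xr = rng.normal(size=4), rng.normal(size=4)
        assert np.allclose(combine_estimate(np.ones(4), xb, xr), xb)

    def test_full_trust_in_history(self, rng):
        xb, xr = rng.normal(size=4), rng.normal(size=4)
        assert np.allclose(combine_estimate(np.zeros(4), xb, xr), xr)

    def test_quarter_blend(self):
        c = combine_estimate(np.array([0.25]), np.array([2.0]),
                             np.array([-2.0]))
        assert c[0] == pytest.approx(-1.0)

    def test_combination_stays_between_endpoints(self, rng):
        v = rng.random(6)
        xb, xr = rng.normal(size=6), rng.normal(size=6)
        c = combine_estimate(v, xb, xr)
        lo, hi = np.minimum(xb, xr), np.maximum(xb, xr)
        assert ((c >= lo - 1e-12) & (c <= hi + 1e-12)).all()

    def test_complete_vector_cases(self):
        x = np.array([3.0, 0.0])
        c = np.array([9.0, 5.0])
        assert np.allclose(complete_vector(np.ones(2), x, c), x)
        assert np.allclose(complete_vector(np.zeros(2), x, c), c)
        assert np.allclose(complete_vector(np.array([1.0, 0.0]), x, c),
                           [3.0, 5.0])


class TestHiddenUpdate:
    def _params(self, d=3, H=4, seed=0):
        return GrudParams(np.random.default_rng(seed), d, H)

    def test_zero_decay_forgets_history(self, rng):
        params = self._params()
        cfg = GrudConfig(hidden_size=4)
        xc, m = rng.normal(size=3), np.array([1.0, 0, 1])
        h1 = hidden_update(rng.normal(size=4), np.zeros(4), xc, m, params, cfg)
        h2 = hidden_update(rng.normal(size=4), np.zeros(4), xc, m, params, cfg)
        assert np.allclose(h1, h2)

    def test_literal_mode_all_zero_weights(self, rng):
        params = self._params()
        for name in params.names:
            getattr(params, name).fill(0.0)
        params.bh[:] = 0.7
        cfg = GrudConfig(hidden_size=4, literal_eq12=True)
        h = hidden_update(rng.normal(size=4), np.ones(4),
                          rng.normal(size=3), np.ones(3), params, cfg)
        assert np.allclose(h, np.tanh(0.7))

    @pytest.mark.parametrize("literal", [True, False])
    def test_preserves_unit_interval(self, rng, literal):
        # the recurrence maps hidden states in [-1, 1] back into [-1, 1]
        # (literal mode squashes any input; the gated mode interpolates
        # between the decayed state and a squashed candidate), so
        # trajectories started at h_0 = 0 stay bounded
        params = self._params()
        cfg = GrudConfig(hidden_size=4, literal_eq12=literal)
        for _ in range(20):
            h_prev = rng.uniform(-1, 1, size=4) if not literal \
                else rng.normal(scale=5, size=4)
            h = hidden_update(h_prev, rng.random(4),
                              rng.normal(scale=5, size=3),
                              (rng.random(3) < 0.5).astype(float),
                              params, cfg)
            assert (np.abs(h) <= 1.0).all()


class TestMaeLoss:
    def test_zero_when_exact_on_observed(self, rng):
        x = rng.normal(size=(4, 3))
        m = (rng.random(x.shape) < 0.5).astype(float)
        c = x.copy()
        c[m == 0] = 99.0
        assert mae_loss(x, m, c) == 0.0

    def test_single_cell(self):
        assert mae_loss(np.array([1.0]), np.array([1.0]),
                        np.array([0.0])) == 1.0

    def test_invariant_to_masked_cells(self, rng):
        x = rng.normal(size=(4, 3))
        m = (rng.random(x.shape) < 0.5).astype(float)
        c = rng.normal(size=x.shape)
        c2 = c.copy()
        c2[m == 0] += 100.0
        assert mae_loss(x, m, c) == pytest.approx(mae_loss(x, m, c2))


@pytest.mark.parametrize("literal", [False, True])
def test_bptt_gradients_match_finite_differences(literal):
    rng = np.random.default_rng(0)
    B, n, d, H = 2, 6, 3, 4
    X = rng.normal(size=(B, n, d))
    M = (rng.random((B, n, d)) < 0.7).astype(float)
    XF = rng.normal(size=(B, n, d)) * 0.5
    U = np.abs(rng.normal(size=(B, n)))
    cfg = GrudConfig(hidden_size=H, literal_eq12=literal)
    params = GrudParams(np.random.default_rng(1), d, H)
    loss, caches = _forward(params, cfg, X, M, XF, U)
    _backward(params, cfg, X, M, XF, caches)
    eps = 1e-6
    for name in params.names:
        p = getattr(params, name)
        g = params.grads[name]
        num = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = _forward(params, cfg, X, M, XF, U)
            p[idx] = orig - eps
            lm, _ = _forward(params, cfg, X, M, XF, U)
            p[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        assert np.allclose(g, num, rtol=1e-4, atol=1e-7), name


def _mean_stage1(norm_records):
    """Stage-1 stand-in: the raw estimate is the feature mean everywhere."""
    out = []
    for r in norm_records:
        means = _feature_means(r)
        ddm = np.broadcast_to(means[:, None], r.values.shape).copy()
        merged = r.mask * r.values + (1 - r.mask) * ddm
        out.append(ImputationResult(ddm=ddm, merged=merged,
                                    uncertainty=np.zeros(r.n_steps)))
    return out


class TestTrainGrud:
    def test_improves_on_mean_fill_for_autocorrelated_data(self):
        """With a mean-fill stage 1 and zero uncertainty, training the
        corrector lowers the held-out RMSE on AR(1) data in most seeds."""
        from tdgan import (SyntheticConfig, corrupt_dataset, evaluate_heldout,
                          generate_truth)
        cfg = SyntheticConfig(d=3, n=60, records=10, seed=1024)
        truth = generate_truth(cfg)
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            corr, held = corrupt_dataset(truth, 0.3, 900 + seed)
            norm, state = normalize_dataset(corr)
            s1 = _mean_stage1(norm)
            gcfg = GrudConfig(epochs=120, seed=seed)

            def score(fill):
                mats = []
                for rec, r, s in zip(corr, norm, s1):
                    dense = state.inverse(fill(r, s))
                    obs = rec.mask == 1.0
                    dense[obs] = rec.values[obs]
                    mats.append(dense)
                return evaluate_heldout(held, mats).rmse

            base = score(lambda r, s: s.merged)
            params, _ = train_grud(norm, s1, gcfg)
            corrected = score(lambda r, s: impute(r, s, params, gcfg))
            wins += corrected < base
        assert wins >= 0.7 * n_seeds

    def test_zero_uncertainty_still_trains(self, rng):
        recs = [random_masked_series(rng, d=2, n=10) for _ in range(3)]
        norm, _ = normalize_dataset(recs)
        s1 = _mean_stage1(norm)
        gcfg = GrudConfig(epochs=5, hidden_size=4, seed=0)
        params, hist = train_grud(norm, s1, gcfg)
        assert len(hist) == 5 and all(np.isfinite(hist))
        # with u = 0 the input decay is the constant exp(-max(0, b))
        trace = run_grud(norm[0], s1[0], params, gcfg)
        assert np.allclose(trace.v_input, trace.v_input[0])

    def test_identical_seeds_identical_parameters(self, rng):
        recs = [random_masked_series(rng, d=2, n=10) for _ in range(3)]
        norm, _ = normalize_dataset(recs)
        s1 = _mean_stage1(norm)
        gcfg = GrudConfig(epochs=10, hidden_size=4, seed=9)
        p1, h1 = train_grud(norm, s1, gcfg)
        p2, h2 = train_grud(norm, s1, gcfg)
        assert h1 == h2
        for name in p1.names:
            assert np.array_equal(getattr(p1, name), getattr(p2, name))

    def test_short_records_skipped_with_warning(self, rng):
        short = MaskedSeries([[1.0]], [[1.0]], [0.0])
        good = random_masked_series(rng, d=1, n=8)
        norm, _ = normalize_dataset([short, good])
        s1 = _mean_stage1(norm)
        with pytest.warns(UserWarning, match="skipped"):
            train_grud(norm, s1, GrudConfig(epochs=2, hidden_size=2, seed=0))

    def test_all_records_too_short_rejected(self):
        short = MaskedSeries([[1.0]], [[1.0]], [0.0])
        s1 = _mean_stage1([short])
        with pytest.raises(ValueError):
            train_grud([short], s1, GrudConfig(epochs=1, seed=0))


class TestTraceAndImpute:
    def _fitted(self, rng, p_miss=0.4):
        recs = [random_masked_series(rng, d=3, n=15, p_miss=p_miss)
                for _ in range(4)]
        norm, state = normalize_dataset(recs)
        s1 = _mean_stage1(norm)
        gcfg = GrudConfig(epochs=10, hidden_size=6, seed=2)
        params, _ = train_grud(norm, s1, gcfg)
        return recs, norm, state, s1, params, gcfg

    def test_decay_factors_in_unit_interval(self, rng):
        _, norm, _, s1, params, gcfg = self._fitted(rng)
        for r, s in zip(norm, s1):
            tr = run_grud(r, s, params, gcfg)
            assert ((tr.v_input > 0) & (tr.v_input <= 1)).all()
            assert ((tr.v_hidden > 0) & (tr.v_hidden <= 1)).all()

    def test_combined_between_fill_and_regression(self, rng):
        _, norm, _, s1, params, gcfg = self._fitted(rng)
        r, s = norm[0], s1[0]
        tr = run_grud(r, s, params, gcfg)
        lo = np.minimum(s.ddm.T, tr.x_reg)
        hi = np.maximum(s.ddm.T, tr.x_reg)
        assert ((tr.combined >= lo - 1e-12) & (tr.combined <= hi + 1e-12)).all()

    def test_observed_cells_preserved(self, rng):
        recs, norm, state, s1, params, gcfg = self._fitted(rng)
        for rec, r, s in zip(recs, norm, s1):
            out = impute(r, s, params, gcfg, norm_state=state)
            obs = rec.mask == 1.0
            # de-normalization round-trips the observed cells
            assert np.allclose(out[obs], rec.values[obs], atol=1e-9)

    def test_fully_observed_record_passes_through(self, rng):
        recs = [random_masked_series(rng, d=2, n=10, p_miss=0.0)
                for _ in range(2)]
        norm, state = normalize_dataset(recs)
        s1 = _mean_stage1(norm)
        gcfg = GrudConfig(epochs=3, hidden_size=4, seed=1)
        params, _ = train_grud(norm, s1, gcfg)
        out = impute(norm[0], s1[0], params, gcfg, norm_state=state)
        assert np.allclose(out, recs[0].values, atol=1e-9)

    def test_missing_cells_equal_trace_estimates(self, rng):
        _, norm, _, s1, params, gcfg = self._fitted(rng)
        r, s = norm[0], s1[0]
        tr = run_grud(r, s, params, gcfg)
        out = impute(r, s, params, gcfg)
        miss = r.mask == 0.0
        assert np.array_equal(out[miss], tr.combined.T[miss])
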