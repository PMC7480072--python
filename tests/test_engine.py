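import math

import numpy as np
import pytest

from popcsf import (
    CSFParams,
    DegenerateError,
    FalseAlarmUpdateError,
    LikelihoodTable,
    Outcome,
    ParameterDomain,
    Posterior,
    PsychometricSpec,
    StopRule,
    ValidationError,
    expected_posterior_entropy,
    init_posterior,
    posterior_mean,
    run_adaptive_session,
    select_stimulus,
    update_posterior,
)
from conftest import random_small_domain
from oracles import brute_bayes_update, brute_expected_entropy, brute_select


class _StubLik:
    """A likelihood table with hand-chosen hit probabilities."""

    def __init__(self, row):
        self.table = np.asarray(row, float)[None, :]

    def row(self, contrast, f_cpd):
        return self.table[0]

    def stimulus(self, idx):
        return (0.5, 1.0)


def _toy_domain(n_g=2):
    return ParameterDomain(
        gmax_grid=np.logspace(1, 2, n_g),
        fmax_grid=np.array([3.0]),
        beta_grid=np.array([3.0]),
        lapse_grid=np.array([0.05]),
    )


class TestInitPosterior:
    def test_uniform_default(self, live_params):
        post = init_posterior(live_params)
        assert post.mass.shape == (15, 10, 9, 3)
        assert np.allclose(post.mass, 1 / 4050)
        assert post.flat.sum() == pytest.approx(1.0, abs=1e-12)

    def test_injected_delta_prior_unchanged(self):
        dom = _toy_domain()
        prior = np.zeros(dom.shape)
        prior[1, 0, 0, 0] = 1.0
        post = init_posterior(dom, prior)
        assert np.array_equal(post.mass, prior)

    def test_unnormalized_prior_is_scaled(self):
        dom = _toy_domain()
        prior = np.full(dom.shape, 7.0)
        post = init_posterior(dom, prior)
        assert np.allclose(post.mass, 0.5)

    def test_bad_priors_rejected(self, live_params):
        with pytest.raises(ValidationError):
            init_posterior(live_params, np.ones((2, 2)))
        dom = _toy_domain()
        with pytest.raises(ValidationError):
            init_posterior(dom, -np.ones(dom.shape))
        with pytest.raises(ValidationError):
            init_posterior(dom, np.zeros(dom.shape))


class TestUpdatePosterior:
    def test_two_cell_hand_bayes(self):
        # one Hit where p_hit = (0.8, 0.2) -> posterior (0.8, 0.2)
        dom = _toy_domain()
        lik = _StubLik([0.8, 0.2])
        post = update_posterior(init_posterior(dom), (0.5, 1.0), Outcome.HIT, lik)
        assert np.allclose(post.flat, [0.8, 0.2], atol=1e-15)
        post = update_posterior(init_posterior(dom), (0.5, 1.0), Outcome.MISS, lik)
        assert np.allclose(post.flat, [0.2, 0.8], atol=1e-15)

    def test_hit_then_miss_commutes(self):
        dom = _toy_domain()
        lik = _StubLik([0.7, 0.3])
        u = init_posterior(dom)
        a = update_posterior(update_posterior(u, (0.5, 1), Outcome.HIT, lik),
                             (0.5, 1), Outcome.MISS, lik)
        b = update_posterior(update_posterior(u, (0.5, 1), Outcome.MISS, lik),
                             (0.5, 1), Outcome.HIT, lik)
        assert np.allclose(a.mass, b.mass, atol=1e-15)

    def test_delta_prior_is_fixed_point(self):
        dom = _toy_domain()
        prior = np.zeros(dom.shape)
        prior[0, 0, 0, 0] = 1.0
        post = init_posterior(dom, prior)
        out = update_posterior(post, (0.5, 1), Outcome.HIT, _StubLik([0.6, 0.4]))
        assert np.array_equal(out.mass, prior)

    def test_false_alarm_rejected(self, live_lik, live_params):
        post = init_posterior(live_params)
        c, f = live_lik.stimulus(0)
        with pytest.raises(FalseAlarmUpdateError):
            update_posterior(post, (c, f), Outcome.FALSE_ALARM, live_lik)

    def test_degenerate_update_raises(self):
        dom = _toy_domain()
        prior = np.zeros(dom.shape)
        prior[0, 0, 0, 0] = 1.0
        post = init_posterior(dom, prior)
        with pytest.raises(DegenerateError):
            update_posterior(post, (0.5, 1), Outcome.HIT, _StubLik([0.0, 0.9]))

    def test_input_posterior_unchanged(self, live_lik, live_params):
        post = init_posterior(live_params)
        before = post.mass.copy()
        update_posterior(post, live_lik.stimulus(10), Outcome.HIT, live_lik)
        assert np.array_equal(post.mass, before)

    def test_fuzz_against_brute_force(self, rng, psy):
        # randomized small domains, real likelihood tables
        for _ in range(200):
            dom = random_small_domain(rng)
            contrasts = np.sort(rng.uniform(0.001, 1.0, size=2))
            freqs = np.sort(rng.uniform(1.0, 12.0, size=2))
            lik = LikelihoodTable(contrasts, freqs, dom, psy)
            mass = rng.random(dom.size) + 1e-3
            post = init_posterior(dom, (mass / mass.sum()).reshape(dom.shape))
            s = int(rng.integers(lik.n_stimuli))
            hit = bool(rng.random() < 0.5)
            got = update_posterior(
                post, lik.stimulus(s),
                Outcome.HIT if hit else Outcome.MISS, lik,
            )
            want = brute_bayes_update(post.flat.tolist(), lik.table[s].tolist(), hit)
            assert np.allclose(got.flat, want, atol=1e-12)
            assert got.flat.sum() == pytest.approx(1.0, abs=1e-9)


class TestEntropyAndSelection:
    def test_delta_posterior_zero_entropy_everywhere(self, live_lik, live_params):
        prior = np.zeros(live_params.shape)
        prior[3, 4, 2, 1] = 1.0
        post = init_posterior(live_params, prior)
        for s in (0, 37, 149):
            e = expected_posterior_entropy(post, live_lik.stimulus(s), live_lik)
            assert e == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_stimulus_gives_log2_k(self):
        dom = _toy_domain(4)
        post = init_posterior(dom)
        e = expected_posterior_entropy(post, (0.5, 1.0), _StubLik([0.3] * 4))
        assert e == pytest.approx(math.log2(4), abs=1e-12)

    def test_two_cell_entropy_matches_hand_mixture(self):
        dom = _toy_domain()
        row = [0.8, 0.2]
        post = init_posterior(dom)
        got = expected_posterior_entropy(post, (0.5, 1.0), _StubLik(row))
        want = brute_expected_entropy([0.5, 0.5], row)
        assert got == pytest.approx(want, abs=1e-12)

    def test_selection_matches_exhaustive_scan_small(self, rng, psy):
        for _ in range(20):
            dom = random_small_domain(rng)
            contrasts = np.sort(rng.uniform(0.001, 1.0, size=3))
            freqs = np.sort(rng.uniform(1.0, 12.0, size=3))
            lik = LikelihoodTable(contrasts, freqs, dom, psy)
            mass = rng.random(dom.size) + 1e-3
            post = init_posterior(dom, (mass / mass.sum()).reshape(dom.shape))
            c, f = select_stimulus(post, lik, np.random.default_rng(0))
            _, ents = brute_select(post.flat.tolist(), lik.table.tolist())
            chosen = lik.index_of(c, f)
            assert ents[chosen] <= min(ents) + 1e-10

    def test_delta_posterior_tie_break_is_seeded(self, live_lik, live_params):
        prior = np.zeros(live_params.shape)
        prior[3, 4, 2, 1] = 1.0
        post = init_posterior(live_params, prior)
        picks = {select_stimulus(post, live_lik, np.random.default_rng(s)) for s in range(5)}
        assert len(picks) > 1  # ties are broken randomly ...
        a = select_stimulus(post, live_lik, np.random.default_rng(7))
        b = select_stimulus(post, live_lik, np.random.default_rng(7))
        assert a == b  # ... but reproducibly given the seed

    def test_concentrated_posterior_selects_near_threshold(self, live_lik, live_params):
        # all mass on one hypothesis -> chosen contrast within one grid step
        # of that hypothesis's threshold at the chosen frequency
        from popcsf import threshold_contrast

        gi, fi, bi, li = 7, 5, 3, 0
        prior = np.zeros(live_params.shape)
        prior[gi, fi, bi, li] = 1.0
        # a delta is already converged; use a slightly smeared peak instead
        prior[gi - 1, fi, bi, li] = 0.5
        prior[gi + 1, fi, bi, li] = 0.5
        prior[gi, fi - 1, bi, li] = 0.5
        prior[gi, fi + 1, bi, li] = 0.5
        post = init_posterior(live_params, prior)
        c, f = select_stimulus(post, live_lik, np.random.default_rng(0))
        params = CSFParams(
            live_params.gmax_grid[gi], live_params.fmax_grid[fi],
            live_params.beta_grid[bi], live_params.lapse_grid[li],
        )
        alpha = threshold_contrast(f, params)
        log_step = np.log10(live_lik.contrasts[1] / live_lik.contrasts[0])
        assert abs(np.log10(c / alpha)) <= 1.5 * log_step


class TestPosteriorMean:
    def test_delta_recovers_grid_point(self, live_params):
        gi, fi, bi, li = 9, 4, 4, 1
        prior = np.zeros(live_params.shape)
        prior[gi, fi, bi, li] = 1.0
        est = posterior_mean(init_posterior(live_params, prior))
        assert est.gmax == pytest.approx(live_params.gmax_grid[gi], rel=1e-12)
        assert est.fmax == pytest.approx(live_params.fmax_grid[fi], rel=1e-12)
        assert est.beta == pytest.approx(live_params.beta_grid[bi], rel=1e-12)
        assert est.lapse == pytest.approx(live_params.lapse_grid[li], rel=1e-12)

    def test_uniform_means_are_grid_midpoints(self, live_params):
        est = posterior_mean(init_posterior(live_params))
        # geometric midpoint of the symmetric log grid 3..300 is sqrt(900)=30
        assert est.gmax == pytest.approx(30.0, rel=1e-9)
        assert est.fmax == pytest.approx(math.sqrt(10.0), rel=1e-9)
        assert est.beta == pytest.approx(5.0, rel=1e-12)
        assert est.lapse == pytest.approx(np.mean([0.05, 0.1, 0.2]), rel=1e-12)


class TestAdaptiveSession:
    def test_bookkeeping_and_determinism(self, live_stim_cpd, live_params, psy):
        true = CSFParams(100.0, 3.0, 3.0, 0.0)
        res = run_adaptive_session(
            true, live_stim_cpd, live_params, psy,
            StopRule(max_hits=None, max_trials=60), seed=3,
        )
        assert len(res.trials) == 60
        assert res.posterior.flat.sum() == pytest.approx(1.0, abs=1e-9)
        res2 = run_adaptive_session(
            true, live_stim_cpd, live_params, psy,
            StopRule(max_hits=None, max_trials=60), seed=3,
        )
        assert [t.outcome for t in res.trials] == [t.outcome for t in res2.trials]
        assert np.array_equal(res.posterior.mass, res2.posterior.mass)

    def test_stop_at_max_hits(self, live_stim_cpd, live_params, psy):
        res = run_adaptive_session(
            CSFParams(100.0, 3.0, 3.0, 0.05), live_stim_cpd, live_params, psy,
            StopRule(max_hits=30, max_trials=200), seed=5,
        )
        assert res.n_hits == 30
        assert res.n_misses == len(res.trials) - 30

    def test_entropy_nonincreasing_in_expectation(self, live_stim_cpd, live_params, psy):
        # seed-averaged entropy trajectories; per-trial noise is allowed
        true = CSFParams(30.0, 3.0, 3.0, 0.05)
        checkpoints = [5, 20, 60]
        traj = np.zeros(len(checkpoints))
        for seed in range(8):
            res = run_adaptive_session(
                true, live_stim_cpd, live_params, psy,
                StopRule(max_hits=None, max_trials=60), seed=seed,
                checkpoints=checkpoints,
            )
            traj += [res.checkpoints[c].entropy_bits() for c in checkpoints]
        traj /= 8
        assert traj[0] < np.log2(live_params.size)
        assert np.all(np.diff(traj) < 0)
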