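"""Sampler, diagnostics, summaries, and the MLE cross-check."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from occubear import (
    DetectionHistory,
    MCMCConfig,
    PosteriorChains,
    Priors,
    fit_mle,
    gelman_rubin,
    run_mcmc,
    run_mcmc_batch,
    summarize_posterior,
)
from occubear.simulate import SimulationScenario, simulate_dataset

SMALL = MCMCConfig(n_chains=2, n_adapt=200, n_iterations=1500, seed=3)


def _sim(n_sites=60, seed=0, **kw):
    ds = simulate_dataset(SimulationScenario(n_sites=n_sites, seed=seed, **kw))
    return ds.detection_history


def _chains_from_array(arr, names=None) -> PosteriorChains:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    C, T, P = arr.shape
    cfg = MCMCConfig(n_chains=C, n_adapt=0, n_iterations=T, burn_in=0.0, seed=0)
    return PosteriorChains(
        draws=arr,
        param_names=names or [f"param_{j}" for j in range(P)],
        config=cfg,
        acceptance=np.zeros((C, 1)),
        z_mean=np.zeros(1),
        site_ids=np.array([0]),
    )


class TestSampler:
    def test_seeded_determinism(self):
        h = _sim()
        a = run_mcmc(h, None, SMALL)
        b = run_mcmc(h, None, SMALL)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.z_mean, b.z_mean)

    def test_different_seeds_differ(self):
        h = _sim()
        a = run_mcmc(h, None, SMALL)
        b = run_mcmc(h, None, MCMCConfig(n_chains=2, n_adapt=200, n_iterations=1500, seed=4))
        assert not np.array_equal(a.draws, b.draws)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="n_chains"):
            MCMCConfig(n_chains=1)

    def test_acceptance_rates_in_adapted_band(self):
        h = _sim(n_sites=100, seed=2)
        ch = run_mcmc(h, None, MCMCConfig(n_chains=2, n_adapt=600, n_iterations=2500, seed=1))
        assert 0.1 < ch.acceptance.mean() < 0.6

    def test_batch_matches_single_run_shapes_and_determinism(self):
        h1, h2 = _sim(seed=1), _sim(seed=2)
        fits = run_mcmc_batch([h1, h2], [None, None], SMALL)
        assert len(fits) == 2
        assert fits[0].draws.shape == fits[1].draws.shape
        again = run_mcmc_batch([h1, h2], [None, None], SMALL)
        np.testing.assert_array_equal(fits[1].draws, again[1].draws)

    def test_finite_sample_occupancy_at_least_naive(self):
        # z_i = 1 is forced at detected sites, so sum(z)/N >= naive occupancy
        h = _sim(n_sites=152, seed=5)
        ch = run_mcmc(h, None, SMALL)
        naive = np.mean(h.y > 0)
        occ = ch.draws[:, :, ch.param_names.index("occ_fss")]
        assert (occ >= naive - 1e-12).all()


class TestGelmanRubin:
    def test_well_mixed_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        rhat = gelman_rubin(_chains_from_array(rng.normal(size=(2, 4000))), burn=False)
        assert abs(rhat.iloc[0] - 1.0) < 0.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(2, 2000))
        arr[0] -= 10
        arr[1] += 10
        rhat = gelman_rubin(_chains_from_array(arr), burn=False)
        assert rhat.iloc[0] > 1.1

    def test_matches_direct_between_within_formula(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(3, 400)) + np.array([[0.0], [0.2], [-0.1]])
        rhat = gelman_rubin(_chains_from_array(arr), burn=False).iloc[0]
        # independent split-chain computation
        half = 200
        seqs = [arr[c, s * half:(s + 1) * half] for c in range(3) for s in range(2)]
        W = np.mean([s.var(ddof=1) for s in seqs])
        Bn = np.var([s.mean() for s in seqs], ddof=1)
        expected = np.sqrt(((half - 1) / half * W + Bn) / W)
        assert rhat == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        arr = np.cumsum(rng.normal(size=(2, 1000)), axis=1) * 0.01 + rng.normal(
            size=(2, 1000)
        )
        ours = gelman_rubin(_chains_from_array(arr), burn=False).iloc[0]
        theirs = float(az.rhat(az.convert_to_dataset(arr), method="split")["x"])
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_degenerate_chain_gives_nan_with_warning(self):
        arr = np.ones((2, 100))
        with pytest.warns(UserWarning, match="zero within-chain variance"):
            rhat = gelman_rubin(_chains_from_array(arr), burn=False)
        assert np.isnan(rhat.iloc[0])


class TestSummaries:
    def test_constant_chain_summary(self):
        with pytest.warns(UserWarning):
            s = summarize_posterior(_chains_from_array(np.full((2, 100), 3.5)))
        row = s.table.iloc[0]
        assert row["mean"] == 3.5 and row["sd"] == 0.0
        assert row["q2.5"] == 3.5 and row["q97.5"] == 3.5

    def test_standard_normal_draws_recover_moments(self):
        rng = np.random.default_rng(4)
        s = summarize_posterior(_chains_from_array(rng.normal(size=(2, 50_000))))
        row = s.table.iloc[0]
        assert row["mean"] == pytest.approx(0.0, abs=0.02)
        assert row["sd"] == pytest.approx(1.0, abs=0.02)
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.05)

    def test_invariant_to_chain_order(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(3, 500))
        a = summarize_posterior(_chains_from_array(arr)).table
        b = summarize_posterior(_chains_from_array(arr[::-1])).table
        pd.testing.assert_frame_equal(
            a.drop(columns="rhat"), b.drop(columns="rhat")
        )

    def test_chain_dataframe_round_trip(self):
        h = _sim()
        ch = run_mcmc(h, None, SMALL)
        df = ch.to_dataframe()
        assert set(df.columns) == {"chain", "iteration", *ch.param_names}
        assert len(df) == ch.draws.shape[0] * ch.draws.shape[1]


class TestMLE:
    def test_intercept_only_recovers_psi(self):
        ds = simulate_dataset(
            SimulationScenario(
                n_sites=5000, beta=np.r_[logit(0.3), np.zeros(7)], p_true=0.5, seed=21
            )
        )
        res = fit_mle(ds.detection_history, None)
        assert res.converged and not res.boundary_p
        psi_hat = 1 / (1 + np.exp(-res.params.beta[0]))
        se = np.sqrt(0.3 * 0.7 / 5000) * 1.5  # inflate for detection uncertainty
        assert abs(psi_hat - 0.3) < 3 * se

    def test_all_detected_every_occasion_hits_boundary(self):
        mat = pd.DataFrame(np.ones((25, 3)), columns=["a", "b", "c"])
        h = DetectionHistory(site_ids=np.arange(25), occasion_matrix=mat)
        res = fit_mle(h, None)
        assert res.boundary_p and res.params.p > 0.99

    def test_mle_dominates_nearby_points(self):
        from occubear import ModelParams, total_loglik

        h = _sim(n_sites=300, seed=8)
        res = fit_mle(h, None)
        rng = np.random.default_rng(0)
        for _ in range(20):
            beta = res.params.beta + rng.normal(0, 0.3, size=1)
            p = np.clip(res.params.p + rng.normal(0, 0.05), 0.01, 0.99)
            assert total_loglik(ModelParams(beta=beta, p=p), h, None) <= res.loglik + 1e-8


class TestPriorsValidation:
    def test_bad_prior_rejected(self):
        with pytest.raises(ValueError):
            Priors(beta_sd=0.0)
        with pytest.raises(ValueError):
            Priors(p_a=0.0)

    def test_flat_prior_allowed(self):
        assert Priors(beta_sd=None).beta_sd is None
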