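"""Gibbs sampler: conjugate oracles, degenerate priors, chain bookkeeping."""

import numpy as np
import pytest

from hpart.annotate import Partition, make_partition
from hpart.bayesrrc import MixturePrior, gibbs_fit, pip_and_shares, trace_diagnostics
from hpart import phenosim as ps


def one_group_partition(m):
    return Partition(
        names=["all"], groups=[np.arange(m)], mode="noLDMS", design="MC"
    )


class TestDegeneratePriors:
    def test_spike_only_prior_fits_pure_noise_model(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.3, size=(200, 40)).astype(float)
        y = rng.normal(0.0, 1.5, size=200)
        prior = MixturePrior(pi_init=(1.0, 0.0, 0.0, 0.0), fix_pi=True)
        summ = gibbs_fit(y, X, one_group_partition(40), prior=prior,
                         n_iter=600, burn_in=200, seed=2)
        assert np.all(summ.chain.beta == 0.0)
        assert np.all(summ.pip == 0.0)
        assert summ.sigma_e2 == pytest.approx(y.var(), rel=0.1)

    def test_single_group_share_is_100_every_draw(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.4, size=(150, 60)).astype(float)
        beta = rng.normal(0, 0.3, size=60)
        y = X @ beta + rng.normal(size=150)
        summ = gibbs_fit(y, X, one_group_partition(60), n_iter=400, burn_in=150, seed=4)
        shares = summ.chain.kept_shares()
        assert np.allclose(shares[:, 0], 100.0)


class TestConjugateOracle:
    def test_single_variant_matches_closed_form_posterior(self):
        """With one variant, a fixed non-spike indicator and pinned
        hyper-parameters, the effect draws must match the Normal conjugate
        posterior (mean and E[beta^2] within 2% over 20,000 draws)."""
        rng = np.random.default_rng(5)
        n = 300
        x = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        xc = x[:, 0] - x[:, 0].mean()
        y = xc * 0.8 + rng.normal(0, 1.0, n)
        prior = MixturePrior(
            scales=(2.0,), pi_init=(0.0, 1.0), nu0=1e9, s0_frac=0.5, fix_pi=True
        )
        summ = gibbs_fit(y, x, one_group_partition(1), prior=prior,
                         n_iter=21_000, burn_in=1_000, seed=6)
        vary = y.var()
        sigma_e2 = 0.5 * vary  # pinned by the huge prior df
        omega = 2.0 * 0.5 * vary  # scale * s0_frac * var(y) / n_groups
        xs = xc / x[:, 0].std()
        d = n + sigma_e2 / omega  # x'x = n for a standardized column
        post_mean = (xs @ y) / d
        post_var = sigma_e2 / d
        draws_sq = summ.chain.gvar[1_000:, 0]  # = beta^2 (unit-variance column)
        mean_abs = np.sqrt(draws_sq).mean() * np.sign(post_mean)
        assert mean_abs == pytest.approx(post_mean, rel=0.02)
        assert draws_sq.mean() == pytest.approx(post_mean**2 + post_var, rel=0.02)

    def test_prior_structure_recovered_from_simulated_data(self):
        """Smoke parameter-recovery: a group carrying real effects gets a
        clearly larger posterior share than an empty group."""
        rng = np.random.default_rng(7)
        n, m = 400, 120
        X = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        beta = np.zeros(m)
        beta[:40] = rng.normal(0, 0.25, 40)  # group 1 causal, group 2 null
        g = Xs @ beta
        y = g + rng.normal(0, g.std(), n)
        part = Partition(
            names=["causal", "null"],
            groups=[np.arange(40), np.arange(40, m)],
            mode="noLDMS", design="MC",
        )
        summ = gibbs_fit(y, X, part, n_iter=800, burn_in=300, seed=8)
        assert summ.shares["causal"] > 70.0
        assert summ.shares["null"] < 30.0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(9)
    n, m = 200, 80
    X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    beta = rng.normal(0, 0.2, m)
    y = (X - X.mean(0)) @ beta + rng.normal(size=n)
    part = Partition(
        names=["a", "b"], groups=[np.arange(40), np.arange(40, 80)],
        mode="noLDMS", design="MC",
    )
    summ = gibbs_fit(y, X, part, n_iter=500, burn_in=200, seed=10)
    return X, y, summ


class TestChainBookkeeping:

    def test_residual_consistency(self, fitted):
        """y - mu - X beta recomputed from scratch matches the incrementally
        maintained residual."""
        X, y, summ = fitted
        ch = summ.chain
        Xs = (X - X.mean(0)) / X.std(0)
        recomputed = y - ch.mu_final - Xs @ ch.beta
        assert np.allclose(recomputed, ch.residual, atol=1e-8)

    def test_seeded_chains_reproduce_bitwise(self, fitted):
        X, y, summ = fitted
        part = Partition(
            names=["a", "b"], groups=[np.arange(40), np.arange(40, 80)],
            mode="noLDMS", design="MC",
        )
        again = gibbs_fit(y, X, part, n_iter=500, burn_in=200, seed=10)
        assert np.array_equal(again.chain.sigma_s2, summ.chain.sigma_s2)
        assert np.array_equal(again.chain.beta, summ.chain.beta)

    def test_share_recomputation_matches_online_accumulator(self, fitted):
        _, _, summ = fitted
        _, table = pip_and_shares(summ.chain)
        assert np.allclose(
            table["share_mean"].to_numpy(), summ.chain.online_share_mean, atol=1e-10
        )

    def test_pip_bounds(self, fitted):
        _, _, summ = fitted
        assert np.all((summ.pip >= 0) & (summ.pip <= 1))

    def test_bad_iteration_budget_raises(self, fitted):
        X, y, _ = fitted
        with pytest.raises(ValueError):
            gibbs_fit(y, X, one_group_partition(80), n_iter=100, burn_in=100)


class TestTraceDiagnostics:
    def test_white_noise_chain_not_flagged(self, ):
        from hpart.bayesrrc import ChainState

        rng = np.random.default_rng(11)
        n_iter = 2000
        chain = ChainState(
            group_names=["g"], n_iter=n_iter, burn_in=500,
            sigma_s2=rng.normal(1.0, 0.1, (n_iter, 1)),
            sigma_e2=rng.normal(1.0, 0.1, n_iter),
            mu=rng.normal(0.0, 0.05, n_iter),
            gvar=np.abs(rng.normal(1.0, 0.1, (n_iter, 1))),
            nonspike_kept=np.zeros(1, dtype=np.int64),
            online_share_mean=np.array([100.0]),
            beta=np.zeros(1), comp=np.zeros(1, dtype=np.int64),
            residual=np.zeros(5), mu_final=0.0,
        )
        table = trace_diagnostics(chain)
        assert not table["flagged"].any()

    def test_drifting_chain_is_flagged(self):
        from hpart.bayesrrc import ChainState

        n_iter = 2000
        drift = np.linspace(0.0, 3.0, n_iter)
        chain = ChainState(
            group_names=["g"], n_iter=n_iter, burn_in=0,
            sigma_s2=drift[:, None].copy(),
            sigma_e2=np.ones(n_iter), mu=np.zeros(n_iter),
            gvar=np.ones((n_iter, 1)),
            nonspike_kept=np.zeros(1, dtype=np.int64),
            online_share_mean=np.array([100.0]),
            beta=np.zeros(1), comp=np.zeros(1, dtype=np.int64),
            residual=np.zeros(5), mu_final=0.0,
        )
        table = trace_diagnostics(chain, splits=[(0, 1000), (1000, 2000)])
        assert table.loc[table["parameter"] == "sigma_s2[g]", "flagged"].item()

    def test_overlapping_ranges_raise(self):
        from hpart.bayesrrc import ChainState

        chain = ChainState(
            group_names=["g"], n_iter=100, burn_in=0,
            sigma_s2=np.ones((100, 1)), sigma_e2=np.ones(100), mu=np.zeros(100),
            gvar=np.ones((100, 1)), nonspike_kept=np.zeros(1, dtype=np.int64),
            online_share_mean=np.array([100.0]),
            beta=np.zeros(1), comp=np.zeros(1, dtype=np.int64),
            residual=np.zeros(5), mu_final=0.0,
        )
        with pytest.raises(ValueError):
            trace_diagnostics(chain, splits=[(0, 60), (50, 100)])

    def test_short_vs_long_chain_shares_agree_at_reduced_scale(
        self, small_panel, small_annotation
    ):
        """A short chain's posterior share distribution overlaps a 4x longer
        chain's on the same replicate."""
        part = make_partition(small_annotation, mode="noLDMS", design="TC", focal="OCR")
        spec = ps.ocr50_scenario(m_causal=60, h2=0.5)
        y, _ = ps.assemble_phenotypes(small_panel, small_annotation, spec, seed=21)
        short = gibbs_fit(y, small_panel.dosages, part, n_iter=600, burn_in=200, seed=22)
        long = gibbs_fit(y, small_panel.dosages, part, n_iter=2400, burn_in=800, seed=23)
        s_short = short.chain.kept_shares()[:, 0]
        s_long = long.chain.kept_shares()[:, 0]
        pooled = np.sqrt(s_short.std() ** 2 + s_long.std() ** 2)
        assert abs(s_short.mean() - s_long.mean()) < max(3 * pooled, 10.0)
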