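"""Full Gibbs sampler: determinism, invariants, summaries, diagnostics, and an
exact-posterior oracle.

The oracle integrates the half-sib threshold model exactly: for each sire
family the marginal likelihood integrates the sire effect with Gauss-Hermite
quadrature, and the posterior over (h2, intercept) is evaluated on a dense
2-D grid.  The Gibbs posterior mean must agree with the exact posterior mean.
"""

import logging

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats
from scipy.special import log_ndtr, logsumexp

from whorlherit.pedigree import Pedigree, PedigreeRecord
from whorlherit.phenotypes import TraitDataset
from whorlherit.threshold_gibbs import (
    DiagnosticsReport,
    MCMCConfig,
    ModelError,
    convergence_diagnostics,
    heritability,
    posterior_mode,
    run_chains,
    run_gibbs,
    summarize_posterior,
)

from conftest import halfsib_phenotypes


# --------------------------------------------------------------------------
# data helpers


def halfsib_binary(n_sires: int, offspring: int, true_h2: float, seed: int,
                   beta_true: float = 0.2):
    """Binary half-sib data drawn from the model itself (sires founders,
    dams unknown, offspring phenotyped, one sex level)."""
    rng = np.random.default_rng(seed)
    var_u = true_h2 / (1.0 - true_h2)  # var_e = 1
    recs, rows, y = [], [], []
    for j in range(n_sires):
        s = f"S{j}"
        recs.append(PedigreeRecord(s, None, None, "M"))
        u_s = rng.normal(0.0, np.sqrt(var_u))
        for m in range(offspring):
            o = f"O{j}_{m}"
            recs.append(PedigreeRecord(o, s, None, "M"))
            # unknown dam: u_o | u_s ~ N(0.5 u_s, 0.75 var_u)
            L = beta_true + 0.5 * u_s + rng.normal(0.0, np.sqrt(0.75 * var_u + 1.0))
            cat = 1 if L <= 0 else 2
            rows.append((o, "M", cat))
            y.append(cat)
    ped = Pedigree(recs)
    data = TraitDataset("whorl_number",
                        pd.DataFrame(rows, columns=["id", "sex", "category"]))
    return ped, data, np.array(y).reshape(n_sires, offspring)


def exact_posterior_mean_h2(y: np.ndarray, prior_nu: float, prior_scale: float,
                            n_h2: int = 150, n_beta: int = 101,
                            n_nodes: int = 60) -> float:
    """Exact posterior mean of h2 for the binary half-sib model above.

    Marginal likelihood per family: integrate the sire effect u_s ~
    N(0, var_u) by Gauss-Hermite; offspring liabilities given u_s are
    independent N(beta + 0.5 u_s, 0.75 var_u + 1) with threshold 0.
    Prior: flat on beta, scaled inverse chi-square (prior_nu, prior_scale)
    on var_u, transformed to the h2 grid with the Jacobian.
    """
    h2_grid = np.linspace(0.005, 0.95, n_h2)
    beta_grid = np.linspace(-1.5, 1.5, n_beta)
    nodes, weights = hermegauss(n_nodes)  # weight exp(-x^2/2)
    logw = np.log(weights / np.sqrt(2 * np.pi))
    log_post = np.empty((n_h2, n_beta))
    n1 = (y == 1).sum(axis=1)  # per family
    n2 = (y == 2).sum(axis=1)
    for i, h2 in enumerate(h2_grid):
        var_u = h2 / (1.0 - h2)
        sd = np.sqrt(0.75 * var_u + 1.0)
        u_s = np.sqrt(var_u) * nodes  # (K,)
        for j, beta in enumerate(beta_grid):
            z = -(beta + 0.5 * u_s) / sd
            lp1 = log_ndtr(z)          # P(category 1) at each node
            lp2 = log_ndtr(-z)
            # (families, nodes): log f(y_f | u_s = node)
            ll = n1[:, None] * lp1[None, :] + n2[:, None] * lp2[None, :]
            log_post[i, j] = logsumexp(ll + logw[None, :], axis=1).sum()
        # scaled inv-chi2 prior on var_u == invgamma(nu/2, nu S/2); Jacobian
        # dvar_u/dh2 = (1 - h2)^-2
        log_post[i] += stats.invgamma.logpdf(var_u, a=prior_nu / 2,
                                             scale=prior_nu * prior_scale / 2)
        log_post[i] += -2.0 * np.log1p(-h2)
    post = np.exp(log_post - log_post.max())
    marg_h2 = post.sum(axis=1)
    return float((h2_grid * marg_h2).sum() / marg_h2.sum())


# --------------------------------------------------------------------------
# heritability


def test_heritability_values_and_errors():
    assert heritability(1.0, 1.0) == pytest.approx(0.5)
    assert heritability(0.0, 1.0) == 0.0
    assert np.allclose(heritability([1.0, 3.0], [3.0, 1.0]), [0.25, 0.75])
    with pytest.raises(ModelError):
        heritability(1.0, 0.0)
    with pytest.raises(ModelError):
        heritability(-0.1, 1.0)


def test_mcmc_config_validation():
    with pytest.raises(ModelError):
        MCMCConfig(n_iterations=100, burn_in=100)
    with pytest.raises(ModelError):
        MCMCConfig(thinning=0)
    with pytest.raises(ModelError):
        MCMCConfig(parameterization="bogus")
    cfg = MCMCConfig(n_iterations=105, burn_in=5, thinning=10)
    assert cfg.n_retained == 10


# --------------------------------------------------------------------------
# run_gibbs: determinism and invariants


def small_cfg(**kw):
    base = dict(n_iterations=600, burn_in=100, seed=11)
    base.update(kw)
    return MCMCConfig(**base)


def test_same_seed_gives_bit_identical_chains():
    ped, data, _ = halfsib_binary(8, 6, true_h2=0.3, seed=2)
    a = run_gibbs(data, ped, small_cfg())
    b = run_gibbs(data, ped, small_cfg())
    assert np.array_equal(a.var_u, b.var_u)
    assert np.array_equal(a.var_e, b.var_e)
    assert np.array_equal(a.thresholds, b.thresholds)
    assert np.array_equal(a.h2, b.h2)


def test_different_seeds_give_different_chains():
    ped, data, _ = halfsib_binary(8, 6, true_h2=0.3, seed=2)
    a = run_gibbs(data, ped, small_cfg(seed=1))
    b = run_gibbs(data, ped, small_cfg(seed=2))
    assert not np.array_equal(a.h2, b.h2)


def test_chain_invariants_binary():
    ped, data, _ = halfsib_binary(8, 6, true_h2=0.3, seed=5)
    chain = run_gibbs(data, ped, small_cfg())
    assert len(chain) == chain.config.n_retained
    assert np.all(chain.var_u > 0)
    assert np.all(chain.var_e == 1.0)           # fixed for binary traits
    assert np.all(chain.thresholds == 0.0)      # single fixed threshold
    assert np.all((chain.h2 >= 0) & (chain.h2 < 1))
    assert np.array_equal(chain.h2, chain.var_u / (chain.var_u + chain.var_e))


def test_chain_invariants_three_categories():
    ped, data = halfsib_phenotypes(n_sires=8, offspring=8, seed=9, n_cat=3)
    chain = run_gibbs(data, ped, small_cfg())
    assert np.all(chain.thresholds[:, 0] == 0.0)  # both thresholds fixed
    assert np.all(chain.thresholds[:, 1] == 1.0)
    assert np.all(chain.var_e > 0)                # sampled
    assert chain.var_e.std() > 0
    df = chain.to_frame()
    assert list(df.columns) == ["var_u", "var_e", "t1", "t2", "h2"]


def test_four_categories_free_threshold_ordered():
    ped, data = halfsib_phenotypes(n_sires=8, offspring=10, seed=4, n_cat=4)
    chain = run_gibbs(data, ped, small_cfg())
    t = chain.thresholds
    assert np.all(t[:, 0] == 0.0) and np.all(t[:, 1] == 1.0)
    assert np.all(t[:, 2] > t[:, 1])  # sampled threshold stays ordered


def test_thinning_subsamples_consistently():
    ped, data, _ = halfsib_binary(6, 5, true_h2=0.3, seed=3)
    full = run_gibbs(data, ped, small_cfg(n_iterations=500, burn_in=100, thinning=1))
    thin = run_gibbs(data, ped, small_cfg(n_iterations=500, burn_in=100, thinning=4))
    assert np.array_equal(thin.h2, full.h2[::4])


# --------------------------------------------------------------------------
# exact posterior oracle


def test_gibbs_matches_exact_quadrature_posterior():
    ped, data, y = halfsib_binary(10, 8, true_h2=0.4, seed=13)
    cfg = MCMCConfig(n_iterations=40_000, burn_in=4_000, seed=21,
                     prior_nu=4.0, prior_scale=0.25)
    chain = run_gibbs(data, ped, cfg)
    exact = exact_posterior_mean_h2(y, prior_nu=4.0, prior_scale=0.25)
    assert chain.h2.mean() == pytest.approx(exact, abs=0.02)


# --------------------------------------------------------------------------
# posterior summaries


def test_summarize_beta_fixture_against_analytic():
    rng = np.random.default_rng(0)
    a, b = 20.0, 10.0
    samples = rng.beta(a, b, 200_000)
    s = summarize_posterior(samples)
    dist = stats.beta(a, b)
    assert s.mean == pytest.approx(dist.mean(), abs=3 * dist.std() / np.sqrt(2e5))
    assert s.sd == pytest.approx(dist.std(), rel=0.02)
    assert s.mode == pytest.approx((a - 1) / (a + b - 2), abs=0.01)
    assert s.ci_low == pytest.approx(dist.ppf(0.025), abs=0.005)
    assert s.ci_high == pytest.approx(dist.ppf(0.975), abs=0.005)
    assert set(s.as_dict()) == {"mode", "mean", "sd", "ci_low", "ci_high"}


def test_summarize_hpd_interval_narrower_for_skewed():
    rng = np.random.default_rng(1)
    samples = rng.beta(2, 8, 100_000)  # right-skewed
    et = summarize_posterior(samples, ci="equal_tailed")
    hpd = summarize_posterior(samples, ci="hpd")
    assert (hpd.ci_high - hpd.ci_low) < (et.ci_high - et.ci_low)


def test_summarize_constant_chain_degenerate():
    s = summarize_posterior(np.full(2000, 0.4))
    assert s.mean == s.mode == s.ci_low == s.ci_high == 0.4
    assert s.sd == 0.0


def test_summarize_requires_enough_samples():
    with pytest.raises(ModelError, match="1000"):
        summarize_posterior(np.linspace(0, 1, 999))
    with pytest.raises(ModelError, match="unknown ci"):
        summarize_posterior(np.linspace(0, 1, 2000), ci="weird")


def test_posterior_mode_warns_on_multimodality(caplog):
    rng = np.random.default_rng(2)
    samples = np.concatenate([rng.normal(0.2, 0.02, 5000),
                              rng.normal(0.8, 0.02, 5000)])
    with caplog.at_level(logging.WARNING):
        posterior_mode(samples)
    assert any("multimodal" in r.message for r in caplog.records)


def test_posterior_mode_unimodal_no_warning(caplog):
    rng = np.random.default_rng(3)
    samples = np.clip(rng.normal(0.5, 0.05, 10_000), 0, 1)
    with caplog.at_level(logging.WARNING):
        mode = posterior_mode(samples)
    assert not caplog.records
    assert mode == pytest.approx(0.5, abs=0.02)


# --------------------------------------------------------------------------
# convergence diagnostics


def test_diagnostics_flag_identical_chains():
    ped, data, _ = halfsib_binary(6, 5, true_h2=0.3, seed=1)
    c = run_gibbs(data, ped, small_cfg(n_iterations=400, burn_in=100))
    rep = convergence_diagnostics([c, c])
    assert rep.degenerate and not rep.converged
    assert np.isnan(rep.psrf)


def test_diagnostics_require_matching_configs():
    ped, data, _ = halfsib_binary(6, 5, true_h2=0.3, seed=1)
    a = run_gibbs(data, ped, small_cfg(n_iterations=400, burn_in=100, seed=1))
    b = run_gibbs(data, ped, small_cfg(n_iterations=400, burn_in=100, seed=2,
                                       prior_scale=0.5))
    with pytest.raises(ModelError, match="mismatch"):
        convergence_diagnostics([a, b])
    with pytest.raises(ModelError, match="at least 2"):
        convergence_diagnostics([a])


def test_diagnostics_two_seed_chains():
    ped, data, _ = halfsib_binary(10, 8, true_h2=0.4, seed=13)
    cfg = MCMCConfig(n_iterations=6000, burn_in=1000, seed=5, n_chains=2)
    chains = run_chains(data, ped, cfg)
    assert [c.seed for c in chains] == [5, 6]
    rep = convergence_diagnostics(chains)
    assert isinstance(rep, DiagnosticsReport)
    assert not rep.degenerate
    assert np.isfinite(rep.psrf) and rep.ess > 0
    assert rep.psrf < 1.2  # short well-identified chains mix adequately
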