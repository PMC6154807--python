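"""The BYM sampler: deviance, ICAR prior, Gibbs conditionals, sweeps."""

import numpy as np
import pytest
import scipy.stats as st

import bymmap as bm
from bymmap.areal_data import ValidationError


# ---------------------------------------------------------------- deviance

def test_poisson_deviance_closed_forms():
    assert bm.poisson_deviance([1], [1.0], [1.0]) == pytest.approx(2.0)
    assert bm.poisson_deviance([0], [2.0], [1.0]) == pytest.approx(4.0)


def test_poisson_deviance_matches_pmf_oracle():
    rng = np.random.default_rng(2)
    Y = rng.integers(0, 30, size=12)
    E = rng.uniform(0.5, 20, size=12)
    theta = rng.uniform(0.2, 3.0, size=12)
    want = -2.0 * sum(
        st.poisson.logpmf(y, th * e) for y, e, th in zip(Y, E, theta)
    )
    assert bm.poisson_deviance(Y, E, theta) == pytest.approx(want)


def test_poisson_deviance_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        bm.poisson_deviance([1], [0.0], [1.0])
    with pytest.raises(ValidationError):
        bm.poisson_deviance([1], [1.0], [-1.0])


# ---------------------------------------------------------------- ICAR prior

def test_icar_logpdf_zero_vector(path_graph):
    # quadratic term vanishes; value is ((n-c)/2) log tau
    assert bm.icar_logpdf(np.zeros(3), 1.0, path_graph) == pytest.approx(0.0)
    assert bm.icar_logpdf(np.zeros(3), 2.5, path_graph) == pytest.approx(np.log(2.5))


def test_icar_logpdf_path_hand_value(path_graph):
    # edges (A,B),(B,C): ((-1)-0)^2 + (0-1)^2 = 2 -> -1 at tau=1
    assert bm.icar_logpdf(np.array([-1.0, 0.0, 1.0]), 1.0, path_graph) == pytest.approx(-1.0)


def test_icar_invariance_under_component_shifts():
    g = bm.AdjacencyGraph(tuple("ABCDE"), ((0, 1), (1, 2), (3, 4)))  # two components
    rng = np.random.default_rng(0)
    u = rng.standard_normal(5)
    base = bm.icar_logpdf(u, 3.0, g)
    shifted = u.copy()
    shifted[:3] += 7.7
    shifted[3:] -= 2.2
    assert bm.icar_logpdf(shifted, 3.0, g) == pytest.approx(base, abs=1e-9)


def test_u_full_conditional_examples(path_graph):
    u = np.array([-1.0, 0.0, 1.0])
    mean, prec = bm.u_full_conditional_prior(1, u, 2.0, path_graph)
    assert mean == pytest.approx(0.0)
    assert prec == pytest.approx(4.0)
    # all neighbors equal k -> mean k
    mean, _ = bm.u_full_conditional_prior(0, np.array([5.0, 3.0, 9.0]), 1.0, path_graph)
    assert mean == pytest.approx(3.0)


def test_u_full_conditional_island_is_an_error():
    g = bm.AdjacencyGraph(("A", "B", "C"), ((0, 1),))
    with pytest.raises(ValidationError, match="island"):
        bm.u_full_conditional_prior(2, np.zeros(3), 1.0, g)


def test_full_conditional_consistent_with_joint_density():
    """exp(icar_logpdf) restricted to one coordinate is proportional to the
    derived normal full conditional (density-ratio check on a 4-node graph)."""
    g = bm.AdjacencyGraph(
        ("A", "B", "C", "D"), ((0, 1), (0, 2), (0, 3), (1, 2), (2, 3))
    )
    tau = 1.7
    base = np.array([0.0, 0.3, -0.2, 0.5])
    mean, prec = bm.u_full_conditional_prior(0, base, tau, g)
    ref = None
    for x in np.linspace(-2, 2, 9):
        u = base.copy()
        u[0] = x
        joint = bm.icar_logpdf(u, tau, g)
        cond = st.norm.logpdf(x, loc=mean, scale=1 / np.sqrt(prec))
        if ref is None:
            ref = joint - cond
        else:
            assert joint - cond == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------- Gibbs draws

def test_gibbs_tau_u_monte_carlo_mean(path_graph):
    priors = bm.Priors(a_u=0.5, b_u=0.0005)
    rng = np.random.default_rng(9)
    # u = 0: target Gamma(a_u + (n-c)/2, b_u) = Gamma(1.5, 0.0005)
    draws = np.array(
        [bm.gibbs_tau_u(np.zeros(3), path_graph, priors, rng) for _ in range(100_000)]
    )
    want_mean = 1.5 / 0.0005
    assert draws.mean() == pytest.approx(want_mean, rel=0.02)


def test_gibbs_tau_u_distribution(path_graph):
    """u=(-1,0,1), a=0.5, b=0.0005 -> Gamma(1.5, 1.0005) (shape-rate)."""
    priors = bm.Priors(a_u=0.5, b_u=0.0005)
    rng = np.random.default_rng(12)
    draws = np.array(
        [bm.gibbs_tau_u(np.array([-1.0, 0.0, 1.0]), path_graph, priors, rng)
         for _ in range(10_000)]
    )
    res = st.kstest(draws, "gamma", args=(1.5, 0.0, 1.0 / 1.0005))
    assert res.pvalue > 0.01


def test_gibbs_tau_v_distribution_and_scaling():
    priors = bm.Priors(a_v=0.5, b_v=0.0005)
    rng = np.random.default_rng(21)
    v = np.array([0.5, -0.3, 0.2, 0.1, -0.6])
    shape = 0.5 + 2.5
    rate = 0.0005 + 0.5 * np.sum(v**2)
    draws = np.array([bm.gibbs_tau_v(v, priors, rng) for _ in range(10_000)])
    assert st.kstest(draws, "gamma", args=(shape, 0.0, 1.0 / rate)).pvalue > 0.01
    # scaling v by 2 multiplies the quadratic rate increment by 4
    draws2 = np.array([bm.gibbs_tau_v(2 * v, priors, rng) for _ in range(10_000)])
    rate2 = 0.0005 + 0.5 * 4 * np.sum(v**2)
    assert draws2.mean() == pytest.approx(shape / rate2, rel=0.05)


def test_gibbs_tau_v_zero_vector_shape():
    # v = 0, n = 10: Gamma(5.5, b_v); mean = 5.5 / 0.0005
    priors = bm.Priors()
    rng = np.random.default_rng(33)
    draws = np.array([bm.gibbs_tau_v(np.zeros(10), priors, rng) for _ in range(50_000)])
    assert draws.mean() == pytest.approx(5.5 / 0.0005, rel=0.03)


# ---------------------------------------------------------------- sweeps

def _toy_problem():
    graph = bm.grid_graph(2, 2, "queen")
    areas = bm.AreaTable(graph.area_ids, np.array([12, 9, 11, 7]),
                         np.array([10.0, 10.0, 10.0, 10.0]))
    return areas, graph


def test_zero_step_sweep_keeps_state_but_refreshes_precisions():
    areas, graph = _toy_problem()
    cfg = bm.MCMCConfig(seed=1, step_alpha=0.0, step_u=0.0, step_v=0.0)
    state = bm.ModelState(0.1, np.array([0.05, -0.05, 0.02, -0.02]),
                          np.zeros(4), 1.0, 1.0)
    new = bm.mh_sweep(state, areas, graph, bm.Priors(), cfg, np.random.default_rng(4))
    assert new.alpha == pytest.approx(state.alpha)
    np.testing.assert_allclose(new.u, state.u, atol=1e-12)
    np.testing.assert_allclose(new.v, state.v, atol=1e-12)
    assert new.tau_u != state.tau_u and new.tau_v != state.tau_v


def test_sweep_recentres_u(path_graph):
    areas = bm.AreaTable(path_graph.area_ids, np.array([5, 7, 6]),
                         np.array([5.0, 5.0, 5.0]))
    cfg = bm.MCMCConfig(seed=2)
    rng = np.random.default_rng(8)
    state = bm.ModelState(0.0, np.array([0.4, -0.1, 0.3]), np.zeros(3), 1.0, 1.0)
    theta_before_shift = state.theta
    for _ in range(5):
        state = bm.mh_sweep(state, areas, path_graph, bm.Priors(), cfg, rng)
        assert abs(state.u.mean()) < 1e-10
    # recentring itself leaves theta invariant: (u + c, alpha - c) same theta
    shifted = bm.ModelState(state.alpha - 0.3, state.u + 0.3, state.v,
                            state.tau_u, state.tau_v)
    np.testing.assert_allclose(shifted.theta, state.theta, rtol=1e-12)
    del theta_before_shift


def test_run_mcmc_is_deterministic_given_seed():
    areas, graph = _toy_problem()
    cfg = bm.MCMCConfig(seed=77, n_iter=400, burn_in=100, thin=3)
    c1 = bm.run_mcmc(areas, graph, cfg)
    c2 = bm.run_mcmc(areas, graph, cfg)
    np.testing.assert_array_equal(c1.theta, c2.theta)
    np.testing.assert_array_equal(c1.alpha, c2.alpha)
    np.testing.assert_array_equal(c1.deviance, c2.deviance)
    assert c1.n_draws == (400 - 100) // 3


def test_acceptance_rates_strictly_interior():
    areas, graph = _toy_problem()
    cfg = bm.MCMCConfig(seed=5, n_iter=2000, burn_in=500, thin=1)
    chain = bm.run_mcmc(areas, graph, cfg)
    for rate in chain.acceptance.values():
        assert 0.0 < rate < 1.0


def test_chain_export(tmp_path):
    areas, graph = _toy_problem()
    cfg = bm.MCMCConfig(seed=5, n_iter=500, burn_in=100, thin=2)
    chain = bm.run_mcmc(areas, graph, cfg)
    chain.write(tmp_path / "chain.csv", theta_path=tmp_path / "theta.csv")
    import pandas as pd

    back = pd.read_csv(tmp_path / "chain.csv")
    assert list(back.columns) == ["alpha", "tau_u", "tau_v", "deviance"]
    assert len(back) == chain.n_draws
    th = pd.read_csv(tmp_path / "theta.csv")
    assert th.shape == chain.theta.shape


def test_config_from_file(tmp_path):
    p = tmp_path / "run.cfg"
    p.write_text("n_iter = 1000\nburn_in = 200\nthin = 2\nstep_u = 0.3\nadapt = false\n")
    cfg = bm.MCMCConfig.from_file(p, seed=4)
    assert cfg.n_iter == 1000 and cfg.thin == 2 and cfg.adapt is False
    assert cfg.step_u == pytest.approx(0.3)
    bad = tmp_path / "bad.cfg"
    bad.write_text("nope = 3\n")
    with pytest.raises(ValidationError):
        bm.MCMCConfig.from_file(bad, seed=4)


def test_islands_keep_u_pinned_at_zero():
    # 2x2 grid plus one isolated area: island u stays 0, chain still runs
    ids = ("A00", "A01", "A02", "A03", "ISL")
    g = bm.AdjacencyGraph(ids, ((0, 1), (0, 2), (0, 3), (1, 3), (2, 3), (1, 2)))
    areas = bm.AreaTable(ids, np.array([12, 9, 11, 7, 10]), np.full(5, 10.0))
    cfg = bm.MCMCConfig(seed=3, n_iter=300, burn_in=100, thin=1)
    sampler = bm.BYMSampler(areas, g, bm.Priors(), cfg)
    state = sampler.initial_state()
    rng = np.random.default_rng(0)
    for _ in range(50):
        sampler.sweep(state, rng)
        assert state.u[4] == 0.0


# ---------------------------------------------------------------- DIC

def _constant_chain(theta_vals, areas):
    theta = np.array(theta_vals, dtype=float)
    dev = np.array([bm.poisson_deviance(areas.Y, areas.E, t) for t in theta])
    return bm.ChainOutput(
        area_ids=tuple(areas.area_ids),
        alpha=np.zeros(len(theta)),
        tau_u=np.ones(len(theta)),
        tau_v=np.ones(len(theta)),
        theta=theta,
        deviance=dev,
        acceptance={"u": 0.4, "v": 0.4, "alpha": 0.4},
        n_iter=len(theta), burn_in=0, thin=1,
    )


def test_dic_degenerate_chain_has_zero_pd():
    areas = bm.AreaTable(("A",), np.array([4]), np.array([5.0]))
    chain = _constant_chain([[0.8], [0.8], [0.8]], areas)
    out = bm.dic(chain, areas)
    assert out.p_d == pytest.approx(0.0, abs=1e-9)
    assert out.dic == pytest.approx(out.d_bar)


def test_dic_two_draw_hand_computation():
    areas = bm.AreaTable(("A",), np.array([3]), np.array([2.0]))
    chain = _constant_chain([[1.0], [2.0]], areas)
    d1 = bm.poisson_deviance([3], [2.0], [1.0])
    d2 = bm.poisson_deviance([3], [2.0], [2.0])
    d_bar = (d1 + d2) / 2
    d_hat = bm.poisson_deviance([3], [2.0], [1.5])  # posterior-mean theta
    out = bm.dic(chain, areas)
    assert out.d_bar == pytest.approx(d_bar)
    assert out.p_d == pytest.approx(d_bar - d_hat)
    assert out.dic == pytest.approx(2 * d_bar - d_hat)
    assert out.p_d > 0  # Jensen gap


def test_dic_requires_two_draws():
    areas = bm.AreaTable(("A",), np.array([3]), np.array([2.0]))
    chain = _constant_chain([[1.0]], areas)
    with pytest.raises(ValidationError):
        bm.dic(chain, areas)


# ---------------------------------------------------------------- shrinkage

def test_posterior_rr_beats_smr_when_expected_counts_are_small():
    """With E ~ 5 the raw SMR is noisy; hierarchical pooling must lower
    the mean squared error against the generating relative risks."""
    spec = bm.SimulationSpec(seed=14, rows=8, cols=8, regime="constant",
                             e_constant=5.0, alpha_true=0.0,
                             tau_u_true=4.0, tau_v_true=25.0)
    sim = bm.simulate_dataset(spec)
    cfg = bm.MCMCConfig(seed=15, n_iter=6000, burn_in=2000, thin=2)
    chain = bm.run_mcmc(sim.areas, sim.graph, cfg)
    rr = chain.theta.mean(axis=0)
    smr = sim.areas.Y / sim.areas.E
    mse_rr = np.mean((rr - sim.theta_true) ** 2)
    mse_smr = np.mean((smr - sim.theta_true) ** 2)
    assert mse_rr < mse_smr
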