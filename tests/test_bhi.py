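"""Bayesian quantifier: conjugate updates, MH kernel, joint density, recovery."""

import numpy as np
import pytest
from scipy import stats

from srmquant.bhi import (
    BHIModel,
    MCMCConfig,
    PriorSpec,
    default_priors,
    gamma_precision_update,
    gaussian_linear_update,
    init_peak_positions,
    mh_uniform_step,
    run_bhi,
)
from srmquant.design import DesignSpec, build_design
from srmquant.simulate import simulate_traces

from conftest import make_toy_truth


class TestGaussianLinearUpdate:
    def test_no_observations_returns_prior(self):
        m, p = gaussian_linear_update(1.5, 4.0, np.array([]), np.array([]), 1.0)
        assert (m, p) == (1.5, 4.0)

    def test_flat_prior_single_observation(self):
        m, p = gaussian_linear_update(0.0, 1e-12, np.array([1.0]), np.array([2.7]), 3.0)
        assert m == pytest.approx(2.7, rel=1e-9)
        assert p == pytest.approx(3.0, rel=1e-9)

    def test_matches_quadrature_oracle(self):
        """Posterior mean/precision agree with normalised numerical
        quadrature of prior x likelihood to 1e-6 relative."""
        rng = np.random.default_rng(7)
        prior_mean, prior_prec = 0.8, 2.5
        a = rng.normal(size=5)
        z = rng.normal(size=5)
        obs_prec = 3.2
        m, p = gaussian_linear_update(prior_mean, prior_prec, a, z, obs_prec)

        theta = np.linspace(-10, 10, 400_001)
        logpost = -0.5 * prior_prec * (theta - prior_mean) ** 2
        for ak, zk in zip(a, z):
            logpost = logpost - 0.5 * obs_prec * (zk - ak * theta) ** 2
        w = np.exp(logpost - logpost.max())
        w /= np.trapezoid(w, theta)
        mean_q = np.trapezoid(w * theta, theta)
        var_q = np.trapezoid(w * (theta - mean_q) ** 2, theta)
        assert m == pytest.approx(mean_q, rel=1e-6)
        assert p == pytest.approx(1.0 / var_q, rel=1e-6)

    def test_improper_posterior_rejected(self):
        with pytest.raises(ValueError, match="improper"):
            gaussian_linear_update(0.0, 0.0, np.array([]), np.array([]), 1.0)


class TestGammaPrecisionUpdate:
    def test_empty_residuals_sample_prior(self):
        alpha, beta = 2.0, 3.0
        draw = gamma_precision_update(alpha, beta, np.array([]), np.random.default_rng(0))
        oracle = float(np.random.default_rng(0).gamma(alpha, beta))
        assert draw == pytest.approx(oracle)

    def test_concentrates_at_true_precision(self):
        """With 10^4 residuals of variance sigma^2 the draw sits near
        1/sigma^2 (the conditional SD shrinks like 1/sqrt(N))."""
        sigma = 0.5
        resid = np.random.default_rng(3).normal(0, sigma, size=10_000)
        draws = [
            gamma_precision_update(1.0, 1.0, resid, np.random.default_rng(s))
            for s in range(5)
        ]
        assert np.mean(draws) == pytest.approx(1.0 / sigma**2, rel=0.1)

    def test_reproducible(self):
        resid = np.ones(10)
        a = gamma_precision_update(1.0, 1.0, resid, np.random.default_rng(42))
        b = gamma_precision_update(1.0, 1.0, resid, np.random.default_rng(42))
        assert a == b


class TestMHStep:
    def test_zero_step_never_moves(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            new, ok = mh_uniform_step(0.5, lambda v: 0.0, 0.0, (0.0, 1.0), rng)
            assert new == 0.5 and not ok

    def test_out_of_bounds_rejected(self):
        rng = np.random.default_rng(1)
        # huge step: essentially every proposal leaves the tiny interval
        moved = [
            mh_uniform_step(0.5, lambda v: 0.0, 1e6, (0.4999, 0.5001), rng)[1]
            for _ in range(200)
        ]
        assert not any(moved)

    def test_flat_posterior_acceptance_matches_gaussian_mass(self):
        """On a flat posterior the long-run acceptance equals the Gaussian
        probability that the proposal lands inside the prior bounds."""
        rng = np.random.default_rng(5)
        x, step, bounds = 0.3, 0.25, (0.0, 1.0)
        cur = x
        hits = 0
        n = 4000
        for _ in range(n):
            cur, ok = mh_uniform_step(cur, lambda v: 0.0, step, bounds, rng)
            hits += ok
        # the chain wanders, so compare against the stationary average mass
        grid = np.linspace(*bounds, 200)
        mass = np.mean(
            stats.norm.cdf((bounds[1] - grid) / step)
            - stats.norm.cdf((bounds[0] - grid) / step)
        )
        assert hits / n == pytest.approx(mass, abs=0.05)


class TestPeakInit:
    def test_shared_peak_survives_product(self):
        grid = np.linspace(0, 40, 401)

        def bump(c):
            return np.exp(-0.5 * ((grid - c) / 1.0) ** 2)

        a = bump(10) + bump(20)
        b = bump(20) + bump(30)
        pos, flagged = init_peak_positions(grid, [a, b])
        assert pos == pytest.approx(20.0, abs=0.1)
        assert not flagged

    def test_single_trace_argmax(self):
        grid = np.linspace(0, 10, 101)
        tr = np.exp(-0.5 * ((grid - 7.3) / 0.5) ** 2)
        pos, _ = init_peak_positions(grid, [tr])
        assert pos == pytest.approx(7.3, abs=0.05)

    def test_all_zero_falls_back_to_midpoint(self):
        grid = np.linspace(0, 10, 101)
        with pytest.warns(UserWarning, match="midpoint"):
            pos, flagged = init_peak_positions(grid, [np.zeros_like(grid)])
        assert flagged and pos == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# full model


def _toy_model(truth, design, grid, mode="quantify", known_y=None, tight=True):
    from srmquant.simulate import simulate_traces

    traces = simulate_traces(design, truth, grid, seed=0)
    priors = default_priors(truth.pep_map, grid)
    if tight:
        priors.tau_bounds = np.column_stack(
            [truth.tau - 0.3, truth.tau + 0.3]
        )
        priors.lam_bounds = np.column_stack(
            [truth.lam * 0.5, truth.lam * 2.0]
        )
    return BHIModel(traces, truth.pep_map, priors=priors, mode=mode, known_y=known_y)


def test_log_joint_matches_independent_recomputation(
    toy_truth, single_reading_design, fine_grid
):
    """The implemented log-posterior equals the sum of the factorised
    log-densities, recomputed term by term with scipy distributions."""
    model = _toy_model(toy_truth, single_reading_design, fine_grid, tight=False)
    rng = np.random.default_rng(11)
    state = model._init_state(rng)
    # perturb away from the initialiser so no term is accidentally zero
    state["kappa"] += 0.1
    state["xi"][0] = state["xi"][0] + 0.05
    state["phi"][0] = state["phi"][0] * 1.02
    state["gamma_n"], state["gamma_star_n"] = 50.0, 80.0
    state["C"][(0, 0)] = model.peak(fine_grid, state["tau"][0, 0], state["lam"][0, 0])

    pr = model.priors
    pm = toy_truth.pep_map
    expected = 0.0
    expected += stats.norm.logpdf(
        state["y"][0], pr.m_y[0], 1 / np.sqrt(pr.gamma_y[0])
    )
    h = float(((state["g"] * pm.d) @ state["y"])[0])
    expected += stats.norm.logpdf(
        state["kappa"][0, 0], h, 1 / np.sqrt(pr.gamma_kappa)
    )
    expected += stats.uniform.logpdf(
        state["tau"][0, 0], pr.tau_bounds[0, 0], np.ptp(pr.tau_bounds[0])
    )
    expected += stats.uniform.logpdf(
        state["lam"][0, 0], pr.lam_bounds[0, 0], np.ptp(pr.lam_bounds[0])
    )
    expected += stats.norm.logpdf(
        state["xi"][0], pr.m_xi[0], 1 / np.sqrt(pr.gamma_xi[0])
    ).sum()
    expected += stats.norm.logpdf(
        state["phi"][0], 1.0, 1 / np.sqrt(pr.gamma_phi_star)
    ).sum()
    for gname in ("gamma_n", "gamma_star_n"):
        expected += stats.gamma.logpdf(state[gname], pr.alpha_n, scale=pr.beta_n)
    rd = model.readings[0]
    C = state["C"][(0, 0)]
    mean_nat = state["kappa"][0, 0] * state["xi"][0][:, None] * C
    mean_lab = pm.kappa_star[0] * state["xi"][0][:, None] * state["phi"][0][:, None] * C
    expected += stats.norm.logpdf(
        rd.native[0], mean_nat, 1 / np.sqrt(state["gamma_n"])
    ).sum()
    expected += stats.norm.logpdf(
        rd.labeled[0], mean_lab, 1 / np.sqrt(state["gamma_star_n"])
    ).sum()

    assert model.log_joint(state) == pytest.approx(expected, rel=1e-9)


def test_eap_recovers_concentration(toy_truth, single_reading_design, fine_grid):
    """Noiseless three-transition toy with tight peak priors and a vague
    concentration prior: EAP(y) lands within 5% of the truth."""
    model = _toy_model(toy_truth, single_reading_design, fine_grid)
    res = model.fit(MCMCConfig(iterations=500, seed=1, mode="quantify"))
    est = res.protein_estimates
    assert est["estimate"].iloc[0] == pytest.approx(3.0, rel=0.05)
    assert est["ci_low"].iloc[0] <= est["estimate"].iloc[0] <= est["ci_high"].iloc[0]


def test_calibration_recovers_yield(single_reading_design, fine_grid):
    """QC traces generated with g = 0.5 and known y: EAP(g) within 10%."""
    truth = make_toy_truth(y=3.0, g=0.5, gamma_n=1e6, gamma_star_n=1e6)
    model = _toy_model(
        truth, single_reading_design, fine_grid, mode="calibrate", known_y=np.array([3.0])
    )
    res = model.fit(MCMCConfig(iterations=500, seed=2, mode="calibrate"))
    assert res.yield_estimates["g"].iloc[0] == pytest.approx(0.5, rel=0.10)


def test_posterior_sharpens_with_lower_noise(single_reading_design, fine_grid):
    """Raising the data precision contracts the posterior around the truth."""
    sds, errs = [], []
    for gamma in (1e2, 1e6):
        truth = make_toy_truth(gamma_n=gamma, gamma_star_n=gamma)
        model = _toy_model(truth, single_reading_design, fine_grid)
        res = model.fit(MCMCConfig(iterations=400, seed=4, mode="quantify"))
        est = res.protein_estimates
        sds.append(est["posterior_sd"].iloc[0])
        errs.append(abs(est["estimate"].iloc[0] - 3.0))
    assert sds[1] < sds[0]
    assert errs[1] < 0.05 * 3.0


def test_fixed_seed_bit_identical(toy_truth, single_reading_design, fine_grid):
    model = _toy_model(toy_truth, single_reading_design, fine_grid)
    cfg = MCMCConfig(iterations=120, seed=9, mode="quantify", keep_draws=True)
    a = model.fit(cfg)
    b = model.fit(cfg)
    assert np.array_equal(a.draws["y"], b.draws["y"])
    assert a.eap["gamma_n"] == b.eap["gamma_n"]


def test_warmup_must_precede_end():
    with pytest.raises(ValueError, match="warm-up"):
        MCMCConfig(iterations=100, warmup=100)


def test_calibrate_then_quantify_consistency(fine_grid):
    """Yields calibrated on QC readings feed quantification of readings
    generated with those very yields: the truth lies within 3 posterior
    SDs in at least 95% of seeded replicates."""
    spec = DesignSpec(
        n_dilutions=1,
        include_pool=False,
        aliquots_per_sample=1,
        digestions_per_aliquot=1,
        injections_per_digestion=1,
        n_day_couples=1,
    )
    design = build_design(spec)
    qc_design = design[design["is_qc"]].head(1).reset_index(drop=True)
    sample_design = design[~design["is_qc"]].reset_index(drop=True)
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        truth = make_toy_truth(y=4.0, g=0.6, gamma_n=1e4, gamma_star_n=1e4)
        qc_traces = simulate_traces(qc_design, truth, fine_grid, seed=100 + rep)
        priors = default_priors(truth.pep_map, fine_grid)
        priors.tau_bounds = np.column_stack([truth.tau - 0.3, truth.tau + 0.3])
        priors.lam_bounds = np.column_stack([truth.lam * 0.5, truth.lam * 2.0])
        known_y = truth.sample_y("qc", qc_design["dilution"].iloc[0])
        cal = BHIModel(
            qc_traces, truth.pep_map, priors=priors, mode="calibrate", known_y=known_y
        ).fit(MCMCConfig(iterations=300, seed=rep, mode="calibrate"))
        g_hat = truth.pep_map.g.copy()
        g_hat[truth.pep_map.d > 0] = np.clip(cal.eap["g"], 1e-3, 1.0)

        traces = simulate_traces(sample_design, truth, fine_grid, seed=200 + rep)
        quant = BHIModel(
            traces,
            truth.pep_map.with_yields(g_hat),
            priors=priors,
            mode="quantify",
        ).fit(MCMCConfig(iterations=300, seed=1000 + rep, mode="quantify"))
        est = quant.protein_estimates
        err = abs(est["estimate"].iloc[0] - 4.0)
        # combined uncertainty: quantification SD plus propagated yield SD
        g_sd = float(cal.sd["g"][0])
        prop = est["estimate"].iloc[0] * g_sd / float(g_hat[0, 0])
        tol = 3.0 * np.sqrt(est["posterior_sd"].iloc[0] ** 2 + prop**2)
        hits += err <= tol
    assert hits >= 0.95 * n_rep


def test_peptide_missing_both_channels_rejected(
    toy_truth, single_reading_design, fine_grid
):
    traces = simulate_traces(single_reading_design, toy_truth, fine_grid, seed=0)
    broken = traces.frame[traces.frame["channel"] == "native"]
    from srmquant.simulate import TraceSet

    with pytest.raises(ValueError, match="both channels"):
        BHIModel(TraceSet(broken, validate=False), toy_truth.pep_map)
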