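"""Bayesian hierarchical inversion (BHI) of the SRM acquisition chain.

The acquisition chain is modelled hierarchically: a protein concentration
``y_p`` induces peptide concentrations ``kappa_i ~ N(H_i(y), 1/gamma_kappa)``
with ``H_i(y) = sum_p g_ip d_ip y_p``; each native transition chromatogram
is ``I_l(t_n) = kappa_i xi_il C(tau_i, lam_i)(t_n)`` plus Gaussian noise of
precision ``gamma_n``, and the labeled (AQUA) chromatogram replaces
``kappa_i`` by the known spike ``kappa*_i`` and corrects the gain by
``phi*_il`` with noise precision ``gamma*_n``.  Priors: Normal on ``xi``
(per-peptide mean ``m_xi_i``), Normal centred at 1 on ``phi*``, Gamma on
the noise precisions (scale parameterisation: mean ``alpha_n * beta_n``),
Uniform on the peak position ``tau_i`` and width ``lam_i``, Normal on the
protein concentrations ``y_p`` and on the digestion yields ``g_ip``.

Posterior computation is a Gibbs sweep in the order
``kappa, tau, lam, xi, phi*, gamma, gamma*`` followed by the target block
(``y`` in quantification mode, ``g`` in yield-calibration mode).  Normal
conditionals are sampled exactly from their conjugate mean/precision;
``tau`` and ``lam`` take one Metropolis-Hastings random-walk step each.
Point estimates are EAP (posterior expectation), i.e. the empirical mean
of the post-warm-up draws.

Several readings may be fitted jointly (e.g. combining QC measurements):
``kappa``, ``tau`` and ``lam`` then get per-reading copies while ``xi``,
``phi*``, the noise precisions and the target block are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .peaks import trace_product_argmax
from .peptides import PeptideProteinMap
from .simulate import GaussianPeak, TraceSet

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "BHIModel",
    "BHIResults",
    "default_priors",
    "gaussian_linear_update",
    "gamma_precision_update",
    "mh_uniform_step",
    "init_peak_positions",
    "run_bhi",
]


# ---------------------------------------------------------------------------
# sampling primitives


def gaussian_linear_update(
    prior_mean: float,
    prior_prec: float,
    coeffs: np.ndarray,
    obs: np.ndarray,
    obs_prec: float | np.ndarray,
) -> tuple[float, float]:
    """Conjugate update of a scalar under a Gaussian linear observation model.

    Observations ``z_k = a_k * theta + e_k`` with ``e_k ~ N(0, 1/gamma_k)``
    and prior ``theta ~ N(m, 1/prior_prec)`` give

        post_prec = prior_prec + sum_k a_k^2 gamma_k
        post_mean = (prior_prec * m + sum_k a_k gamma_k z_k) / post_prec
    """
    coeffs = np.asarray(coeffs, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    gamma = np.broadcast_to(np.asarray(obs_prec, dtype=float), coeffs.shape)
    if prior_prec < 0:
        raise ValueError("prior inverse variance must be >= 0")
    post_prec = prior_prec + float(np.sum(gamma * coeffs * coeffs))
    if post_prec <= 0:
        raise ValueError("improper posterior: total inverse variance is zero")
    post_mean = (prior_prec * prior_mean + float(np.sum(gamma * coeffs * obs))) / post_prec
    return post_mean, post_prec


def gamma_precision_update(
    alpha: float, beta: float, residuals: np.ndarray, rng: np.random.Generator
) -> float:
    """Draw a noise precision from its Gamma full conditional.

    The prior has shape ``alpha`` and SCALE ``beta`` (density kernel
    ``gamma^(alpha-1) exp(-gamma/beta)``, prior mean ``alpha*beta``), i.e.
    prior rate ``1/beta``; ``N`` Gaussian residuals add ``N/2`` to the
    shape and ``||r||^2 / 2`` to the rate.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    if not np.all(np.isfinite(residuals)):
        raise ValueError("residuals must be finite")
    return _gamma_draw_from_ssr(
        alpha, beta, residuals.size, float(residuals @ residuals), rng
    )


def _gamma_draw_from_ssr(
    alpha: float, beta: float, n: int, ssr: float, rng: np.random.Generator
) -> float:
    shape = alpha + n / 2.0
    rate = 1.0 / beta + max(ssr, 0.0) / 2.0
    return float(rng.gamma(shape, 1.0 / rate))


def mh_uniform_step(
    current: float,
    log_post,
    step: float,
    bounds: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """One Metropolis-Hastings random-walk step under a Uniform prior.

    A symmetric Gaussian proposal outside the prior bounds has density
    zero and is rejected outright; otherwise the usual accept/reject on
    the log-posterior ratio applies.
    """
    lo, hi = bounds
    if not lo <= current <= hi:
        raise ValueError("current value outside the prior bounds")
    prop = current + step * rng.standard_normal()
    if step == 0 or not lo <= prop <= hi:
        return current, False
    if np.log(rng.random()) < log_post(prop) - log_post(current):
        return prop, True
    return current, False


def init_peak_positions(
    grid: np.ndarray,
    traces: list[np.ndarray],
    bounds: tuple[float, float] | None = None,
) -> tuple[float, bool]:
    """Initial retention time: argmax of the pointwise trace product."""
    return trace_product_argmax(grid, traces, bounds)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PriorSpec:
    """Hyperparameters of every prior in the acquisition-chain model.

    Arrays are indexed like the peptide map (S peptides, P proteins).
    ``beta_n`` is the SCALE of the Gamma prior on the noise precisions.
    """

    m_xi: np.ndarray  # (S,) transition-gain prior means
    gamma_xi: np.ndarray  # (S,) gain prior precisions
    gamma_phi_star: float  # AQUA correction prior precision (mean fixed at 1)
    alpha_n: float  # Gamma shape, shared by gamma_n and gamma*_n
    beta_n: float  # Gamma scale
    tau_bounds: np.ndarray  # (S, 2) uniform bounds on peak position
    lam_bounds: np.ndarray  # (S, 2) uniform bounds on peak width
    gamma_kappa: float  # peptide-level precision (fixed hyperparameter)
    m_y: np.ndarray  # (P,) protein prior means
    gamma_y: np.ndarray  # (P,) protein prior precisions
    m_g: float = 0.7  # yield prior mean (calibration mode)
    gamma_g: float = 10.0  # yield prior precision

    def __post_init__(self) -> None:
        self.m_xi = np.asarray(self.m_xi, dtype=float)
        self.gamma_xi = np.asarray(self.gamma_xi, dtype=float)
        self.tau_bounds = np.asarray(self.tau_bounds, dtype=float)
        self.lam_bounds = np.asarray(self.lam_bounds, dtype=float)
        self.m_y = np.asarray(self.m_y, dtype=float)
        self.gamma_y = np.asarray(self.gamma_y, dtype=float)
        if np.any(self.gamma_xi <= 0) or np.any(self.gamma_y <= 0):
            raise ValueError("prior inverse variances must be > 0")
        if min(self.gamma_phi_star, self.gamma_kappa, self.gamma_g) <= 0:
            raise ValueError("prior inverse variances must be > 0")
        if self.alpha_n <= 0 or self.beta_n <= 0:
            raise ValueError("Gamma hyperparameters must be > 0")
        if np.any(self.tau_bounds[:, 0] >= self.tau_bounds[:, 1]):
            raise ValueError("tau bounds must satisfy m < M")
        if np.any(self.lam_bounds[:, 0] >= self.lam_bounds[:, 1]) or np.any(
            self.lam_bounds[:, 0] <= 0
        ):
            raise ValueError("lam bounds must satisfy 0 < m < M")


def default_priors(
    pep_map: PeptideProteinMap,
    grid: np.ndarray,
    nominal_width: float = 0.1,
) -> PriorSpec:
    """Weakly informative priors anchored only on the time grid.

    Transition gains get a vague Normal around 1 (they are identified by
    the labeled channel, whose peptide level is known); ``phi*`` is held
    near 1; peak positions may lie anywhere on the grid and widths
    between twice the grid spacing and a quarter of the grid span.
    """
    S, P = pep_map.n_peptides, pep_map.n_proteins
    grid = np.asarray(grid, dtype=float)
    dt = float(np.min(np.diff(grid)))
    span = float(grid[-1] - grid[0])
    return PriorSpec(
        m_xi=np.ones(S),
        gamma_xi=np.full(S, 1e-2),
        gamma_phi_star=100.0,
        alpha_n=1.0,
        beta_n=1.0,
        tau_bounds=np.column_stack([np.full(S, grid[0]), np.full(S, grid[-1])]),
        lam_bounds=np.column_stack(
            [np.full(S, max(2 * dt, nominal_width / 4)), np.full(S, span / 4)]
        ),
        gamma_kappa=1e4,
        m_y=np.ones(P),
        gamma_y=np.full(P, 1e-6),
    )


@dataclass
class MCMCConfig:
    """Chain length, warm-up, MH step sizes, seed and estimation mode."""

    iterations: int = 2000
    warmup: int | None = None  # default: half of iterations
    step_tau: float | None = None  # default: (tau_M - tau_m) / 20
    step_lam: float | None = None  # default: (lam_M - lam_m) / 20
    seed: int = 0
    mode: str = "quantify"  # or "calibrate"
    keep_draws: bool = False

    def __post_init__(self) -> None:
        if self.warmup is None:
            self.warmup = self.iterations // 2
        if not 0 < self.warmup < self.iterations:
            raise ValueError(
                f"warm-up index must satisfy 0 < warmup < iterations, "
                f"got {self.warmup} / {self.iterations}"
            )
        if self.mode not in ("quantify", "calibrate"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# model


class _ReadingData:
    """Per-reading trace arrays on a common grid."""

    def __init__(self, reading_id: str, grid: np.ndarray, by_pep: dict, pep_map):
        self.reading_id = reading_id
        self.grid = np.asarray(grid, dtype=float)
        self.native: dict[int, np.ndarray] = {}  # (L_i, N) matrices
        self.labeled: dict[int, np.ndarray] = {}
        self.transitions: dict[int, list[str]] = {}
        self.ssq_native: dict[int, float] = {}
        self.ssq_labeled: dict[int, float] = {}
        for pep, tr_map in by_pep.items():
            i = pep_map.peptides.index(pep)
            trs = sorted(tr_map)
            nat = [tr_map[t].get("native") for t in trs]
            lab = [tr_map[t].get("labeled") for t in trs]
            if any(v is None for v in nat) or any(v is None for v in lab):
                raise ValueError(
                    f"reading {reading_id!r}, peptide {pep!r}: "
                    "every transition needs both channels"
                )
            self.native[i] = np.vstack(nat)
            self.labeled[i] = np.vstack(lab)
            self.transitions[i] = trs
            self.ssq_native[i] = float(np.sum(self.native[i] ** 2))
            self.ssq_labeled[i] = float(np.sum(self.labeled[i] ** 2))


class BHIModel:
    """Hierarchical Bayesian model of one or several SRM readings.

    In ``quantify`` mode the digestion yields (in ``pep_map.g``) are known
    and the protein concentrations ``y`` are the target; in ``calibrate``
    mode the concentrations ``known_y`` are known (QC sample) and the
    yields ``g_ip`` are the target.  ``fit`` runs the Gibbs/MH sampler and
    returns a :class:`BHIResults`.
    """

    def __init__(
        self,
        traces: TraceSet,
        pep_map: PeptideProteinMap,
        priors: PriorSpec | None = None,
        mode: str = "quantify",
        known_y: np.ndarray | None = None,
        reading_ids: list[str] | None = None,
        peak_shape=None,
    ):
        self.pep_map = pep_map
        self.mode = mode
        self.peak = peak_shape or GaussianPeak()
        if mode == "calibrate":
            if known_y is None:
                raise ValueError("calibration mode requires the known QC concentrations")
            self.known_y = np.asarray(known_y, dtype=float)
        else:
            self.known_y = None
        rids = reading_ids or traces.reading_ids
        self.readings: list[_ReadingData] = []
        for rid in rids:
            grid, by_pep = traces.reading_arrays(rid)
            self.readings.append(_ReadingData(rid, grid, by_pep, pep_map))
        if not self.readings:
            raise ValueError("no readings to fit")
        self.pep_idx = sorted(self.readings[0].native)
        for i in self.pep_idx:
            if self.readings[0].native[i].shape[0] < 1:
                raise ValueError(
                    f"peptide {pep_map.peptides[i]!r} has no transitions"
                )
        self.priors = priors or default_priors(pep_map, self.readings[0].grid)

    # -- state ------------------------------------------------------------

    def _init_state(self, rng: np.random.Generator) -> dict:
        pr = self.priors
        R = len(self.readings)
        S = self.pep_map.n_peptides
        state: dict = {
            "tau": np.zeros((R, S)),
            "lam": np.zeros((R, S)),
            "kappa": np.zeros((R, S)),
            "xi": {},
            "phi": {},
            "gamma_n": pr.alpha_n * pr.beta_n,
            "gamma_star_n": pr.alpha_n * pr.beta_n,
        }
        if self.mode == "quantify":
            state["y"] = pr.m_y.copy()
            state["g"] = self.pep_map.g.copy()
        else:
            state["y"] = self.known_y.copy()
            state["g"] = np.where(self.pep_map.d > 0, pr.m_g, 1.0)
        for i in self.pep_idx:
            L = self.readings[0].native[i].shape[0]
            state["xi"][i] = np.full(L, pr.m_xi[i])
            state["phi"][i] = np.ones(L)
        # data-driven starting point: trace-product argmax for tau, product
        # second moment for lam (a product of K unimodal traces narrows the
        # width by sqrt(K)), labeled areas for xi (kappa* is known) and
        # native areas for kappa
        h0 = (state["g"] * self.pep_map.d) @ state["y"]
        xi0_sum = {i: np.zeros_like(state["xi"][i]) for i in self.pep_idx}
        for r, rd in enumerate(self.readings):
            for i in self.pep_idx:
                all_tr = list(rd.native[i]) + list(rd.labeled[i])
                pos, flat = init_peak_positions(
                    rd.grid, all_tr, tuple(pr.tau_bounds[i])
                )
                state["tau"][r, i] = pos
                lam0 = float(np.mean(pr.lam_bounds[i]))
                if not flat:
                    prod = np.ones_like(rd.grid)
                    for trace in all_tr:
                        prod *= np.clip(trace, 0.0, None)
                    mass = prod.sum()
                    if mass > 0:
                        m = float((prod * rd.grid).sum() / mass)
                        var = float((prod * (rd.grid - m) ** 2).sum() / mass)
                        lam0 = np.sqrt(max(var, 1e-12) * len(all_tr))
                state["lam"][r, i] = float(
                    np.clip(lam0, pr.lam_bounds[i, 0], pr.lam_bounds[i, 1])
                )
                areas = np.trapezoid(np.clip(rd.labeled[i], 0.0, None), rd.grid, axis=1)
                xi0_sum[i] += np.maximum(areas, 1e-12) / max(
                    self.pep_map.kappa_star[i], 1e-12
                )
        R = len(self.readings)
        for i in self.pep_idx:
            state["xi"][i] = xi0_sum[i] / R
        for r, rd in enumerate(self.readings):
            for i in self.pep_idx:
                nat_areas = np.trapezoid(
                    np.clip(rd.native[i], 0.0, None), rd.grid, axis=1
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    k0 = float(np.mean(nat_areas / np.maximum(state["xi"][i], 1e-12)))
                state["kappa"][r, i] = k0 if np.isfinite(k0) else h0[i]

        # start the target block consistent with the data-derived kappa:
        # the kappa <-> target link (precision gamma_kappa) is tight, so a
        # prior-mean start would mix pathologically slowly
        kappa_bar = state["kappa"].mean(axis=0)
        if self.mode == "quantify":
            A = (state["g"] * self.pep_map.d)[self.pep_idx, :]
            sol, *_ = np.linalg.lstsq(A, kappa_bar[self.pep_idx], rcond=None)
            state["y"] = sol
        else:
            d = self.pep_map.d
            for i in self.pep_idx:
                active = np.nonzero(d[i] > 0)[0]
                if active.size == 1:
                    p_ix = active[0]
                    denom = d[i, p_ix] * state["y"][p_ix]
                    if denom > 0:
                        state["g"][i, p_ix] = kappa_bar[i] / denom

        # start the noise precisions at their conditional mean given the
        # initial state rather than at the vague prior mean
        for gname, chan in (("gamma_n", "native"), ("gamma_star_n", "labeled")):
            ssr, count = 0.0, 0
            for r, rd in enumerate(self.readings):
                for i in self.pep_idx:
                    C = self.peak(rd.grid, state["tau"][r, i], state["lam"][r, i])
                    amp = state["kappa"][r, i] if chan == "native" else (
                        self.pep_map.kappa_star[i]
                    )
                    phi = 1.0 if chan == "native" else state["phi"][i][:, None]
                    data = rd.native[i] if chan == "native" else rd.labeled[i]
                    resid = data - amp * state["xi"][i][:, None] * phi * C
                    ssr += float(np.sum(resid * resid))
                    count += resid.size
            state[gname] = (pr.alpha_n + count / 2.0) / (1.0 / pr.beta_n + ssr / 2.0)
        state["C"] = {
            (r, i): self.peak(rd.grid, state["tau"][r, i], state["lam"][r, i])
            for r, rd in enumerate(self.readings)
            for i in self.pep_idx
        }
        state["proj"] = {key: self._proj(*key, C) for key, C in state["C"].items()}
        return state

    # -- log joint (for MH steps and bookkeeping tests) --------------------

    def log_joint(self, state: dict) -> float:
        """Full log-posterior density of the factorised model.

        Sum of the prior log-densities of y (or g), kappa | y, tau, lam,
        xi, phi*, gamma, gamma* and the two trace likelihoods, including
        normalisation constants.
        """
        pr = self.priors
        lp = 0.0
        # target priors
        if self.mode == "quantify":
            lp += float(
                np.sum(_norm_logpdf(state["y"], pr.m_y, pr.gamma_y))
            )
        else:
            active = self.pep_map.d > 0
            lp += float(
                np.sum(_norm_logpdf(state["g"][active], pr.m_g, pr.gamma_g))
            )
        h = (state["g"] * self.pep_map.d) @ state["y"]
        for r, rd in enumerate(self.readings):
            for i in self.pep_idx:
                lp += float(_norm_logpdf(state["kappa"][r, i], h[i], pr.gamma_kappa))
                for bounds, val in (
                    (pr.tau_bounds[i], state["tau"][r, i]),
                    (pr.lam_bounds[i], state["lam"][r, i]),
                ):
                    if not bounds[0] <= val <= bounds[1]:
                        return -np.inf
                    lp -= np.log(bounds[1] - bounds[0])
        for i in self.pep_idx:
            lp += float(
                np.sum(_norm_logpdf(state["xi"][i], pr.m_xi[i], pr.gamma_xi[i]))
            )
            lp += float(
                np.sum(_norm_logpdf(state["phi"][i], 1.0, pr.gamma_phi_star))
            )
        for gname in ("gamma_n", "gamma_star_n"):
            lp += _gamma_logpdf(state[gname], pr.alpha_n, pr.beta_n)
        lp += self._log_likelihood(state)
        return lp

    def _log_likelihood(self, state: dict) -> float:
        ll = 0.0
        gn, gs = state["gamma_n"], state["gamma_star_n"]
        ks = self.pep_map.kappa_star
        n_nat = n_lab = 0
        ssr_nat = ssr_lab = 0.0
        for r, rd in enumerate(self.readings):
            for i in self.pep_idx:
                C = state["C"][(r, i)]
                mean_nat = state["kappa"][r, i] * state["xi"][i][:, None] * C
                mean_lab = (
                    ks[i] * state["xi"][i][:, None] * state["phi"][i][:, None] * C
                )
                rn = rd.native[i] - mean_nat
                rl = rd.labeled[i] - mean_lab
                ssr_nat += float(np.sum(rn * rn))
                ssr_lab += float(np.sum(rl * rl))
                n_nat += rn.size
                n_lab += rl.size
        ll += 0.5 * n_nat * (np.log(gn) - np.log(2 * np.pi)) - 0.5 * gn * ssr_nat
        ll += 0.5 * n_lab * (np.log(gs) - np.log(2 * np.pi)) - 0.5 * gs * ssr_lab
        return ll

    # -- Gibbs sweep -------------------------------------------------------

    # The sweep works on sufficient statistics of each peptide's traces:
    # nc = native @ C, lc = labeled @ C and cc = C @ C, plus the constant
    # sums of squares precomputed per reading.  Every conditional below
    # depends on the data only through these projections, so the full
    # (L, N) residual matrices never need to be formed inside the chain.

    def _proj(self, r: int, i: int, C: np.ndarray):
        rd = self.readings[r]
        return rd.native[i] @ C, rd.labeled[i] @ C, float(C @ C)

    def _ssr_pair(self, state, r, i, nc, lc, cc) -> tuple[float, float]:
        """Native and labeled residual sums of squares for peptide i."""
        rd = self.readings[r]
        xi = state["xi"][i]
        phi = state["phi"][i]
        k = state["kappa"][r, i]
        ks = self.pep_map.kappa_star[i]
        xiphi = xi * phi
        ssr_nat = rd.ssq_native[i] - 2 * k * float(xi @ nc) + k * k * float(xi @ xi) * cc
        ssr_lab = (
            rd.ssq_labeled[i]
            - 2 * ks * float(xiphi @ lc)
            + ks * ks * float(xiphi @ xiphi) * cc
        )
        return ssr_nat, ssr_lab

    def _peptide_loglik(self, state, r, i, C, proj=None) -> float:
        """Trace log-likelihood terms touching peptide i in reading r
        (up to the Gaussian normalisation constants, which cancel in
        every MH ratio)."""
        nc, lc, cc = proj if proj is not None else self._proj(r, i, C)
        ssr_nat, ssr_lab = self._ssr_pair(state, r, i, nc, lc, cc)
        return -0.5 * state["gamma_n"] * ssr_nat - 0.5 * state["gamma_star_n"] * ssr_lab

    def _sweep(self, state: dict, rng: np.random.Generator, accept: dict) -> None:
        pr = self.priors
        ks = self.pep_map.kappa_star
        gd = state["g"] * self.pep_map.d
        h = gd @ state["y"]
        proj = state["proj"]

        # kappa | y, traces  (native channel only: kappa* is known)
        for r in range(len(self.readings)):
            for i in self.pep_idx:
                nc, _, cc = proj[(r, i)]
                xi = state["xi"][i]
                p = pr.gamma_kappa + state["gamma_n"] * float(xi @ xi) * cc
                m = (pr.gamma_kappa * h[i] + state["gamma_n"] * float(xi @ nc)) / p
                state["kappa"][r, i] = m + rng.standard_normal() / np.sqrt(p)

        # tau, lam | rest  (MH random walk under Uniform priors)
        for par, bounds_all in (("tau", pr.tau_bounds), ("lam", pr.lam_bounds)):
            step_default = {"tau": self._step_tau, "lam": self._step_lam}[par]
            for r, rd in enumerate(self.readings):
                for i in self.pep_idx:
                    bounds = tuple(bounds_all[i])

                    def log_post(v, r=r, i=i, par=par):
                        tau = state["tau"][r, i] if par != "tau" else v
                        lam = state["lam"][r, i] if par != "lam" else v
                        C = self.peak(self.readings[r].grid, tau, lam)
                        return self._peptide_loglik(state, r, i, C)

                    step = step_default[i] if np.ndim(step_default) else step_default
                    new, ok = mh_uniform_step(
                        state[par][r, i], log_post, float(step), bounds, rng
                    )
                    accept[par].append(ok)
                    if ok:
                        state[par][r, i] = new
                        C = self.peak(rd.grid, state["tau"][r, i], state["lam"][r, i])
                        state["C"][(r, i)] = C
                        proj[(r, i)] = self._proj(r, i, C)

        # xi | rest  (both channels inform the gains; the transitions of a
        # peptide are conditionally independent, so they draw as a vector)
        for i in self.pep_idx:
            phi = state["phi"][i]
            a_nat = a_lab = 0.0
            b_nat = np.zeros_like(state["xi"][i])
            b_lab = np.zeros_like(state["xi"][i])
            for r in range(len(self.readings)):
                nc, lc, cc = proj[(r, i)]
                k = state["kappa"][r, i]
                a_nat = a_nat + k * k * cc
                a_lab = a_lab + cc
                b_nat = b_nat + k * nc
                b_lab = b_lab + lc
            prec = (
                pr.gamma_xi[i]
                + state["gamma_n"] * a_nat
                + state["gamma_star_n"] * (ks[i] * phi) ** 2 * a_lab
            )
            num = (
                pr.gamma_xi[i] * pr.m_xi[i]
                + state["gamma_n"] * b_nat
                + state["gamma_star_n"] * ks[i] * phi * b_lab
            )
            state["xi"][i] = num / prec + rng.standard_normal(prec.size) / np.sqrt(prec)

        # phi* | rest  (labeled channel only)
        for i in self.pep_idx:
            xi = state["xi"][i]
            cc_sum = sum(proj[(r, i)][2] for r in range(len(self.readings)))
            lc_sum = sum(proj[(r, i)][1] for r in range(len(self.readings)))
            prec = pr.gamma_phi_star + state["gamma_star_n"] * (ks[i] * xi) ** 2 * cc_sum
            num = pr.gamma_phi_star * 1.0 + state["gamma_star_n"] * ks[i] * xi * lc_sum
            state["phi"][i] = num / prec + rng.standard_normal(prec.size) / np.sqrt(prec)

        # gamma, gamma* | rest
        ssr_nat = ssr_lab = 0.0
        n_nat = n_lab = 0
        for r, rd in enumerate(self.readings):
            for i in self.pep_idx:
                nc, lc, cc = proj[(r, i)]
                sn, sl = self._ssr_pair(state, r, i, nc, lc, cc)
                ssr_nat += sn
                ssr_lab += sl
                n_nat += rd.native[i].size
                n_lab += rd.labeled[i].size
        state["gamma_n"] = _gamma_draw_from_ssr(pr.alpha_n, pr.beta_n, n_nat, ssr_nat, rng)
        state["gamma_star_n"] = _gamma_draw_from_ssr(
            pr.alpha_n, pr.beta_n, n_lab, ssr_lab, rng
        )

        # target block: y | kappa  or  g | kappa
        if self.mode == "quantify":
            gd = state["g"] * self.pep_map.d
            for p_ix in range(self.pep_map.n_proteins):
                coeffs, obs = [], []
                for i in self.pep_idx:
                    if self.pep_map.d[i, p_ix] == 0:
                        continue
                    others = float(
                        gd[i] @ state["y"] - gd[i, p_ix] * state["y"][p_ix]
                    )
                    for r in range(len(self.readings)):
                        coeffs.append(gd[i, p_ix])
                        obs.append(state["kappa"][r, i] - others)
                if not coeffs:
                    continue
                m, p = gaussian_linear_update(
                    pr.m_y[p_ix],
                    pr.gamma_y[p_ix],
                    np.asarray(coeffs),
                    np.asarray(obs),
                    pr.gamma_kappa,
                )
                state["y"][p_ix] = m + rng.standard_normal() / np.sqrt(p)
        else:
            d = self.pep_map.d
            for i in self.pep_idx:
                for p_ix in np.nonzero(d[i] > 0)[0]:
                    others = float(
                        (state["g"][i] * d[i]) @ state["y"]
                        - state["g"][i, p_ix] * d[i, p_ix] * state["y"][p_ix]
                    )
                    a = d[i, p_ix] * state["y"][p_ix]
                    obs = np.asarray(
                        [
                            state["kappa"][r, i] - others
                            for r in range(len(self.readings))
                        ]
                    )
                    m, p = gaussian_linear_update(
                        pr.m_g,
                        pr.gamma_g,
                        np.full(obs.shape, a),
                        obs,
                        pr.gamma_kappa,
                    )
                    state["g"][i, p_ix] = m + rng.standard_normal() / np.sqrt(p)

    # -- driver ------------------------------------------------------------

    def fit(self, config: MCMCConfig | None = None) -> "BHIResults":
        config = config or MCMCConfig(mode=self.mode)
        if config.mode != self.mode:
            config = replace(config, mode=self.mode)
        pr = self.priors
        self._step_tau = (
            config.step_tau
            if config.step_tau is not None
            else (pr.tau_bounds[:, 1] - pr.tau_bounds[:, 0]) / 20.0
        )
        self._step_lam = (
            config.step_lam
            if config.step_lam is not None
            else (pr.lam_bounds[:, 1] - pr.lam_bounds[:, 0]) / 20.0
        )
        rng = np.random.default_rng([int(config.seed) % (2**31), 1618])
        state = self._init_state(rng)
        accept: dict = {"tau": [], "lam": []}
        kept: dict[str, list] = {name: [] for name in self._tracked(state)}
        for it in range(config.iterations):
            self._sweep(state, rng, accept)
            if it >= config.warmup:
                for name, value in self._tracked(state).items():
                    kept[name].append(value)
        draws = {name: np.asarray(v) for name, v in kept.items()}
        return BHIResults(
            model=self,
            config=config,
            draws=draws if config.keep_draws else None,
            eap={k: v.mean(axis=0) for k, v in draws.items()},
            sd={k: v.std(axis=0, ddof=1) if v.shape[0] > 1 else np.zeros_like(v[0], dtype=float) for k, v in draws.items()},
            ci={
                k: np.quantile(v, [0.025, 0.975], axis=0) for k, v in draws.items()
            },
            acceptance={
                k: float(np.mean(v)) if v else float("nan") for k, v in accept.items()
            },
        )

    def _tracked(self, state: dict) -> dict:
        out = {
            "gamma_n": float(state["gamma_n"]),
            "gamma_star_n": float(state["gamma_star_n"]),
            "kappa": state["kappa"].copy(),
            "tau": state["tau"].copy(),
            "lam": state["lam"].copy(),
        }
        if self.mode == "quantify":
            out["y"] = state["y"].copy()
        else:
            out["g"] = state["g"][self.pep_map.d > 0].copy()
        return out


def _norm_logpdf(x, mean, prec):
    x = np.asarray(x, dtype=float)
    return 0.5 * (np.log(prec) - np.log(2 * np.pi)) - 0.5 * prec * (x - mean) ** 2


def _gamma_logpdf(x, alpha, beta):
    from scipy.special import gammaln

    if x <= 0:
        return -np.inf
    return (alpha - 1) * np.log(x) - x / beta - alpha * np.log(beta) - gammaln(alpha)


@dataclass
class BHIResults:
    """Posterior summaries (EAP, SD, credible intervals) of a BHI fit."""

    model: BHIModel
    config: MCMCConfig
    eap: dict
    sd: dict
    ci: dict
    acceptance: dict
    draws: dict | None = None

    @property
    def protein_estimates(self) -> pd.DataFrame:
        """EAP, posterior SD and 95% CI of each protein concentration."""
        if "y" not in self.eap:
            raise ValueError("protein estimates exist only in quantification mode")
        prots = self.model.pep_map.proteins
        return pd.DataFrame(
            {
                "protein": list(prots),
                "estimate": self.eap["y"],
                "posterior_sd": self.sd["y"],
                "ci_low": self.ci["y"][0],
                "ci_high": self.ci["y"][1],
            }
        )

    @property
    def yield_estimates(self) -> pd.DataFrame:
        """EAP, posterior SD and 95% CI of each active digestion yield."""
        if "g" not in self.eap:
            raise ValueError("yield estimates exist only in calibration mode")
        pm = self.model.pep_map
        pairs = [
            (pep, prot)
            for i, pep in enumerate(pm.peptides)
            for p, prot in enumerate(pm.proteins)
            if pm.d[i, p] > 0
        ]
        return pd.DataFrame(
            {
                "peptide": [a for a, _ in pairs],
                "protein": [b for _, b in pairs],
                "g": self.eap["g"],
                "posterior_sd": self.sd["g"],
                "ci_low": self.ci["g"][0],
                "ci_high": self.ci["g"][1],
            }
        )

    def plot_trace(self, parameter: str = "y", ax=None):
        """Post-warm-up chain of one tracked parameter (requires
        ``keep_draws=True`` in the MCMC configuration)."""
        import matplotlib.pyplot as plt

        if self.draws is None:
            raise ValueError("chain draws were not retained (keep_draws=False)")
        if ax is None:
            _, ax = plt.subplots()
        draws = np.asarray(self.draws[parameter], dtype=float).reshape(
            len(self.draws[parameter]), -1
        )
        for k in range(draws.shape[1]):
            ax.plot(draws[:, k], lw=0.7, label=f"{parameter}[{k}]")
        ax.set_xlabel("post-warm-up iteration")
        ax.set_ylabel(parameter)
        if draws.shape[1] <= 8:
            ax.legend(fontsize="small")
        return ax

    def summary(self) -> pd.DataFrame:
        """One row per tracked scalar: EAP, SD and central 95% interval."""
        rows = []
        for name, value in self.eap.items():
            flat = np.atleast_1d(np.asarray(value, dtype=float)).ravel()
            sd = np.atleast_1d(np.asarray(self.sd[name], dtype=float)).ravel()
            lo = np.atleast_1d(np.asarray(self.ci[name][0], dtype=float)).ravel()
            hi = np.atleast_1d(np.asarray(self.ci[name][1], dtype=float)).ravel()
            for k in range(flat.size):
                rows.append(
                    {
                        "parameter": name if flat.size == 1 else f"{name}[{k}]",
                        "eap": flat[k],
                        "posterior_sd": sd[k],
                        "ci_2.5%": lo[k],
                        "ci_97.5%": hi[k],
                    }
                )
        return pd.DataFrame(rows)


def run_bhi(
    traces: TraceSet,
    pep_map: PeptideProteinMap,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    known_y: np.ndarray | None = None,
    reading_ids: list[str] | None = None,
) -> BHIResults:
    """Convenience wrapper: build a :class:`BHIModel` and fit it."""
    config = config or MCMCConfig()
    model = BHIModel(
        traces,
        pep_map,
        priors=priors,
        mode=config.mode,
        known_y=known_y,
        reading_ids=reading_ids,
    )
    return model.fit(config)
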