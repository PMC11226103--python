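"""Posterior inference for the lagged-offset Poisson panel model.

Two independent engines:

* :func:`sample_posterior` — Metropolis-within-Gibbs MCMC.  Location
  parameters (alpha, beta, each gamma_i, the delta block) get adaptive
  random-walk Metropolis updates; the two random-effect precisions get exact
  conjugate Gamma draws.  Two extra Metropolis moves translate the chain
  along the near-unidentified directions (alpha vs mean(gamma), and beta vs
  the municipality/year means of the covariate), which is where plain
  single-site samplers stall on this model.  All proposal scales adapt by
  Robbins-Monro during warmup only, so the post-warmup kernel is a fixed,
  valid MCMC kernel.

* :func:`laplace_fit` — Newton optimization of the penalized log-posterior
  at fixed precisions, with the precisions chosen by maximizing the Laplace
  approximation of the marginal posterior.  Used as a cross-check on the
  sampler, in the spirit of deterministic latent-Gaussian approximations.

Both engines share the identification convention of :mod:`cropclim.model`:
delta is constrained to sum to zero, gamma is shrunk by its proper prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import ModelData, PriorConfig, rw1_penalty

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "LaplaceFit",
    "gibbs_update_precision",
    "sample_posterior",
    "laplace_fit",
    "summarize",
]


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_warmup: int = 2000
    n_samples: int = 2000
    seed: int = 0
    target_acceptance: float = 0.44  # scalar updates
    block_target_acceptance: float = 0.234  # delta block
    init_jitter_sd: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_samples) <= 0:
            raise ValueError("chain/warmup/sample counts must be positive")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must be in (0, 1)")


@dataclass
class PosteriorDraws:
    """Per-chain posterior draws; arrays shaped (chains, draws[, dim])."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    tau_gamma: np.ndarray
    tau_delta: np.ndarray
    muni_codes: list = field(default_factory=list)
    years: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per draw: chain, draw, then one column per parameter."""
        chains, draws = self.alpha.shape
        cols = {
            "chain": np.repeat(np.arange(chains), draws),
            "draw": np.tile(np.arange(draws), chains),
            "alpha": self.alpha.ravel(),
            "beta": self.beta.ravel(),
        }
        for i in range(self.gamma.shape[2]):
            cols[f"gamma[{i}]"] = self.gamma[:, :, i].ravel()
        for t in range(self.delta.shape[2]):
            cols[f"delta[{t}]"] = self.delta[:, :, t].ravel()
        cols["tau_gamma"] = self.tau_gamma.ravel()
        cols["tau_delta"] = self.tau_delta.ravel()
        return pd.DataFrame(cols)


def gibbs_update_precision(
    effects: np.ndarray,
    kind: str,
    prior: PriorConfig,
    rng: np.random.Generator,
) -> float:
    """Exact conjugate draw for a random-effect precision.

    iid:  tau | gamma ~ Gamma(a + n/2,     b + sum(gamma^2)/2)
    rw1:  tau | delta ~ Gamma(a + (T-1)/2, b + sum(diff(delta)^2)/2)
    """
    effects = np.asarray(effects, dtype=float)
    if kind == "iid":
        if effects.size < 1:
            raise ValueError("iid update needs at least one effect")
        k = effects.size
        q = float(effects @ effects)
    elif kind == "rw1":
        if effects.size < 2:
            raise ValueError("rw1 update needs at least two effects")
        k = effects.size - 1
        q = rw1_penalty(effects)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    shape = prior.hyper_shape + 0.5 * k
    rate = prior.hyper_rate + 0.5 * q
    return float(rng.gamma(shape, 1.0 / rate))


# ---------------------------------------------------------------------------
# MCMC engine
# ---------------------------------------------------------------------------


class _AdaptiveScale:
    """Robbins-Monro adaptation of a log proposal scale during warmup."""

    def __init__(self, init: float, target: float):
        self.log_s = np.log(init)
        self.target = target
        self.k = 0

    @property
    def s(self) -> float:
        return float(np.exp(self.log_s))

    def update(self, acc_prob: float) -> None:
        self.k += 1
        self.log_s += (acc_prob - self.target) / self.k**0.6


class _VectorAdaptiveScale:
    """Per-component Robbins-Monro adaptation (used for the gamma sites)."""

    def __init__(self, n: int, init: float, target: float):
        self.log_s = np.full(n, np.log(init))
        self.target = target
        self.k = 0

    @property
    def s(self) -> np.ndarray:
        return np.exp(self.log_s)

    def update(self, acc_prob: np.ndarray) -> None:
        self.k += 1
        self.log_s += (acc_prob - self.target) / self.k**0.6


def _acc_prob(log_ratio):
    with np.errstate(over="ignore", invalid="ignore"):
        p = np.exp(np.minimum(log_ratio, 0.0))
    return np.where(np.isfinite(log_ratio), p, 0.0)


class _ChainState:
    def __init__(self, data: ModelData, prior: PriorConfig, cfg: McmcConfig,
                 rng: np.random.Generator, prefit: dict | None = None):
        self.data = data
        self.prior = prior
        self.rng = rng
        d = data
        self.Ysum_m = np.bincount(d.muni_index, weights=d.y, minlength=d.N)
        self.Ysum_t = np.bincount(d.year_index, weights=d.y, minlength=d.T)
        self.Y_tot = float(d.y.sum())
        self.Sxy = float(d.y @ d.x)
        # direction for the beta ridge move: preferably the posterior
        # profile from the pre-fit Hessian; otherwise an unweighted two-way
        # decomposition of the covariate
        if prefit is not None and prefit.get("prof_gamma") is not None:
            self.v_alpha = float(prefit["prof_alpha"])
            self.v_gamma = np.asarray(prefit["prof_gamma"], dtype=float)
            self.v_delta = np.asarray(prefit["prof_delta"], dtype=float)
        else:
            g = d.x.mean()
            cnt_m = np.bincount(d.muni_index, minlength=d.N).astype(float)
            cnt_t = np.bincount(d.year_index, minlength=d.T).astype(float)
            m_dev = (
                np.bincount(d.muni_index, weights=d.x, minlength=d.N) / cnt_m - g
            )
            s_t = np.bincount(d.year_index, weights=d.x, minlength=d.T) / cnt_t
            c_t = s_t - s_t.mean()
            u = d.x - m_dev[d.muni_index] - c_t[d.year_index]
            self.v_alpha = -float(u.mean())
            self.v_gamma = -m_dev
            self.v_delta = -c_t
        self.r = (
            d.x
            + self.v_alpha
            + self.v_gamma[d.muni_index]
            + self.v_delta[d.year_index]
        )
        self.Syr = float(d.y @ self.r)

        # initialization: overdispersed jitter around a cheap posterior-mode
        # pre-fit (at fixed precisions); falls back to a crude rate estimate
        jsd = 2.0 * cfg.init_jitter_sd  # in units of approximate posterior sd
        crude_alpha = float(
            np.log((d.y.sum() + 0.5) / (d.offset_eps.sum() + 0.5))
        )
        for _ in range(20):
            if prefit is not None:
                self.alpha = float(
                    prefit["alpha"] + rng.normal(0.0, jsd * prefit["sd_alpha"])
                )
                self.beta = float(
                    prefit["beta"] + rng.normal(0.0, jsd * prefit["sd_beta"])
                )
                self.gamma = prefit["gamma"] + rng.normal(
                    0.0, jsd * prefit["sd_gamma"], size=d.N
                )
                delta = prefit["delta"] + rng.normal(
                    0.0, jsd * np.maximum(prefit["sd_delta"], 1e-12), size=d.T
                )
            else:
                self.alpha = float(crude_alpha + rng.normal(0.0, cfg.init_jitter_sd))
                self.beta = float(rng.normal(0.0, 0.01 * cfg.init_jitter_sd))
                self.gamma = rng.normal(0.0, 0.1 * cfg.init_jitter_sd, size=d.N)
                delta = rng.normal(0.0, 0.1 * cfg.init_jitter_sd, size=d.T)
            self.delta = delta - delta.mean()
            self.tau_gamma = 10.0
            self.tau_delta = 10.0
            if np.isfinite(self._loglik()):
                break
        else:
            raise RuntimeError("could not find a finite initial state")

        tgt, btgt = cfg.target_acceptance, cfg.block_target_acceptance
        sx = float(d.x.std()) + 1e-12
        if prefit is not None:
            self.s_alpha = _AdaptiveScale(2.4 * prefit["sd_alpha"], tgt)
            self.s_beta = _AdaptiveScale(2.4 * prefit["sd_beta"], tgt)
            self.s_gamma = _VectorAdaptiveScale(d.N, 0.1, tgt)
            self.s_gamma.log_s = np.log(2.4 * np.maximum(prefit["sd_gamma"], 1e-12))
            self.s_delta = _AdaptiveScale(2.4 / max(np.sqrt(d.T), 1.0), btgt)
            self.s_dir_b = _AdaptiveScale(2.4 * prefit["sd_beta"], tgt)
        else:
            self.s_alpha = _AdaptiveScale(0.1, tgt)
            self.s_beta = _AdaptiveScale(0.1 / (1.0 + sx), tgt)
            self.s_gamma = _VectorAdaptiveScale(d.N, 0.1, tgt)
            self.s_delta = _AdaptiveScale(0.1, btgt)
            self.s_dir_b = _AdaptiveScale(0.05 / (1.0 + sx), tgt)
        self.delta_precond = np.ones(d.T)
        # frozen independence-proposal parameters for the beta direction
        if prefit is not None:
            self.beta_prop_mu = float(prefit["beta"])
            self.beta_prop_sd = float(2.0 * prefit["sd_beta"])
        else:
            self.beta_prop_mu = None
            self.beta_prop_sd = None
        self._iter = 0
        self.refresh_lam()
        self._refresh_delta_precond()

    def _refresh_delta_precond(self) -> None:
        """Per-year curvature of the delta conditional, normalized to mean 1.

        Only called during warmup so the post-warmup proposal is a fixed
        symmetric kernel.
        """
        d = self.data
        if d.T < 2:
            return
        diag_r = np.full(d.T, 2.0)
        diag_r[0] = diag_r[-1] = 1.0
        info = np.bincount(d.year_index, weights=self.lam, minlength=d.T)
        info += self.tau_delta * diag_r + 1e-12
        self.delta_precond = info / info.mean()

    # -- likelihood bookkeeping -------------------------------------------
    def _eta(self) -> np.ndarray:
        d = self.data
        return (
            self.alpha
            + self.gamma[d.muni_index]
            + self.delta[d.year_index]
            + self.beta * d.x
        )

    def _loglik(self) -> float:
        d = self.data
        eta = self._eta()
        with np.errstate(over="ignore"):
            lam = d.offset_eps * np.exp(eta)
        if not np.all(np.isfinite(lam)):
            return -np.inf
        return float(d.y @ eta - lam.sum())

    def refresh_lam(self) -> None:
        with np.errstate(over="ignore"):
            self.lam = self.data.offset_eps * np.exp(self._eta())

    # -- updates -----------------------------------------------------------
    def update_alpha(self, adapt: bool) -> None:
        e = self.rng.normal(0.0, self.s_alpha.s)
        p0 = self.prior.fixed_effect_precision
        with np.errstate(over="ignore"):
            dll = e * self.Y_tot - np.expm1(e) * self.lam.sum()
        dlp = -0.5 * p0 * ((self.alpha + e) ** 2 - self.alpha**2)
        ratio = dll + dlp
        if np.log(self.rng.uniform()) < ratio:
            self.alpha += e
            self.lam *= np.exp(e)
        if adapt:
            self.s_alpha.update(float(_acc_prob(ratio)))

    def update_beta(self, adapt: bool) -> None:
        d = self.data
        e = self.rng.normal(0.0, self.s_beta.s)
        p0 = self.prior.fixed_effect_precision
        with np.errstate(over="ignore"):
            f = np.exp(e * d.x)
            dll = e * self.Sxy - float(self.lam @ (f - 1.0))
        dlp = -0.5 * p0 * ((self.beta + e) ** 2 - self.beta**2)
        ratio = dll + dlp if np.isfinite(dll) else -np.inf
        if np.log(self.rng.uniform()) < ratio:
            self.beta += e
            self.lam *= f
        if adapt:
            self.s_beta.update(float(_acc_prob(ratio)))

    def update_gamma(self, adapt: bool) -> None:
        # gamma_i are conditionally independent, so all sites move at once
        d = self.data
        e = self.rng.normal(0.0, self.s_gamma.s)
        Lsum = np.bincount(d.muni_index, weights=self.lam, minlength=d.N)
        with np.errstate(over="ignore"):
            dll = e * self.Ysum_m - np.expm1(e) * Lsum
        dlp = -0.5 * self.tau_gamma * ((self.gamma + e) ** 2 - self.gamma**2)
        ratio = dll + dlp
        acc = np.log(self.rng.uniform(size=d.N)) < ratio
        if acc.any():
            step = np.where(acc, e, 0.0)
            self.gamma += step
            self.lam *= np.exp(step[d.muni_index])
        if adapt:
            self.s_gamma.update(_acc_prob(ratio))

    def update_delta(self, adapt: bool) -> None:
        d = self.data
        if d.T < 2:
            return
        # proposal preconditioned by per-year curvature (frozen after warmup)
        e = self.rng.normal(0.0, self.s_delta.s, size=d.T) / np.sqrt(
            self.delta_precond
        )
        e -= e.mean()  # stay on the sum-to-zero subspace
        Lsum = np.bincount(d.year_index, weights=self.lam, minlength=d.T)
        with np.errstate(over="ignore"):
            dll = float(e @ self.Ysum_t - np.expm1(e) @ Lsum)
        new = self.delta + e
        dlp = -0.5 * self.tau_delta * (rw1_penalty(new) - rw1_penalty(self.delta))
        ratio = dll + dlp if np.isfinite(dll) else -np.inf
        if np.log(self.rng.uniform()) < ratio:
            self.delta = new
            self.lam *= np.exp(e[d.year_index])
        if adapt:
            self.s_delta.update(float(_acc_prob(ratio)))

    def update_dir_alpha_gamma(self) -> None:
        # exact Gibbs draw of the likelihood-invariant translation coordinate
        # alpha -> alpha + e, gamma_i -> gamma_i - e: conditionally Gaussian
        p0 = self.prior.fixed_effect_precision
        N = self.data.N
        prec = p0 + N * self.tau_gamma
        mean = (self.tau_gamma * self.gamma.sum() - p0 * self.alpha) / prec
        e = self.rng.normal(mean, 1.0 / np.sqrt(prec))
        self.alpha += e
        self.gamma -= e

    def update_dir_beta(self, adapt: bool, independence: bool = False) -> None:
        # move beta while absorbing the municipality/year means of x into
        # gamma, delta, alpha: the linear predictor changes only through the
        # two-way residual r, so the likelihood barely resists the move.
        # The independence variant proposes beta directly from the frozen
        # pre-fit Gaussian, giving near-iid exploration of this direction.
        d = self.data
        if independence:
            if self.beta_prop_mu is None:
                return
            b_star = self.rng.normal(self.beta_prop_mu, self.beta_prop_sd)
            e = b_star - self.beta
        else:
            e = self.rng.normal(0.0, self.s_dir_b.s)
        p0 = self.prior.fixed_effect_precision
        with np.errstate(over="ignore"):
            f = np.exp(e * self.r)
            dll = e * self.Syr - float(self.lam @ (f - 1.0))
        new_gamma = self.gamma + e * self.v_gamma
        new_delta = self.delta + e * self.v_delta
        new_alpha = self.alpha + e * self.v_alpha
        new_beta = self.beta + e
        dlp = -0.5 * p0 * (new_alpha**2 - self.alpha**2)
        dlp += -0.5 * p0 * (new_beta**2 - self.beta**2)
        dlp += -0.5 * self.tau_gamma * float(
            new_gamma @ new_gamma - self.gamma @ self.gamma
        )
        dlp += -0.5 * self.tau_delta * (
            rw1_penalty(new_delta) - rw1_penalty(self.delta)
        )
        ratio = dll + dlp if np.isfinite(dll) else -np.inf
        if independence:  # Hastings correction for the asymmetric proposal
            ratio += (
                (new_beta - self.beta_prop_mu) ** 2
                - (self.beta - self.beta_prop_mu) ** 2
            ) / (2.0 * self.beta_prop_sd**2)
        if np.log(self.rng.uniform()) < ratio:
            self.alpha, self.beta = new_alpha, new_beta
            self.gamma, self.delta = new_gamma, new_delta
            self.lam *= f
        if adapt and not independence:
            self.s_dir_b.update(float(_acc_prob(ratio)))

    def update_precisions(self) -> None:
        self.tau_gamma = gibbs_update_precision(
            self.gamma, "iid", self.prior, self.rng
        )
        if self.data.T >= 2:
            self.tau_delta = gibbs_update_precision(
                self.delta, "rw1", self.prior, self.rng
            )
        else:  # no increments: the full conditional is the prior
            self.tau_delta = float(
                self.rng.gamma(self.prior.hyper_shape, 1.0 / self.prior.hyper_rate)
            )

    def step(self, adapt: bool) -> None:
        # one stored draw = two full update sweeps; the extra sweep buys
        # lower autocorrelation at modest cost since every move is O(n)
        self._iter += 1
        self.refresh_lam()
        if adapt and self._iter % 50 == 0:
            self._refresh_delta_precond()
        for _ in range(2):
            self.update_alpha(adapt)
            self.update_beta(adapt)
            self.update_gamma(adapt)
            for _ in range(5):
                self.update_delta(adapt)
            self.update_dir_alpha_gamma()
            for _ in range(3):
                self.update_dir_beta(adapt)
            self.update_dir_beta(adapt, independence=True)
            self.update_precisions()


def sample_posterior(
    data: ModelData,
    prior: PriorConfig | None = None,
    config: McmcConfig | None = None,
) -> PosteriorDraws:
    """Run independent adaptive Metropolis-within-Gibbs chains.

    Fully deterministic given (data, prior, config): each chain draws from a
    child stream of ``SeedSequence([config.seed, chain])``.
    """
    if data.n_obs == 0:
        raise ValueError("cannot sample: no observations")
    prior = prior or PriorConfig()
    config = config or McmcConfig()

    # one cheap fixed-precision mode fit seeds every chain's init and scales
    try:
        lf = laplace_fit(data, prior, precisions=(10.0, 10.0))
        prefit = {
            "alpha": lf.alpha, "beta": lf.beta,
            "gamma": lf.gamma, "delta": lf.delta,
            "sd_alpha": max(lf.sd_alpha, 1e-12),
            "sd_beta": max(lf.sd_beta, 1e-12),
            "sd_gamma": np.maximum(lf.sd_gamma, 1e-12),
            "sd_delta": lf.sd_delta,
            "prof_alpha": lf.beta_profile_alpha,
            "prof_gamma": lf.beta_profile_gamma,
            "prof_delta": lf.beta_profile_delta,
        }
    except RuntimeError:
        prefit = None

    C, S = config.n_chains, config.n_samples
    alpha = np.empty((C, S))
    beta = np.empty((C, S))
    gamma = np.empty((C, S, data.N))
    delta = np.empty((C, S, data.T))
    tau_g = np.empty((C, S))
    tau_d = np.empty((C, S))

    for c in range(C):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, c]))
        state = _ChainState(data, prior, config, rng, prefit=prefit)
        for _ in range(config.n_warmup):
            state.step(adapt=True)
        for s in range(S):
            state.step(adapt=False)
            alpha[c, s] = state.alpha
            beta[c, s] = state.beta
            gamma[c, s] = state.gamma
            delta[c, s] = state.delta
            tau_g[c, s] = state.tau_gamma
            tau_d[c, s] = state.tau_delta

    return PosteriorDraws(
        alpha=alpha, beta=beta, gamma=gamma, delta=delta,
        tau_gamma=tau_g, tau_delta=tau_d,
        muni_codes=list(data.muni_codes), years=list(data.years),
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary table: mean, sd, central 95% interval, diagnostics.

    Quantiles are pooled across chains; split-R-hat and rank-based bulk ESS
    come from arviz.  With a single chain R-hat is reported as NaN
    (unavailable), never as 1.0.
    """
    import arviz as az

    arrays = {
        "alpha": draws.alpha,
        "beta": draws.beta,
        "gamma": draws.gamma,
        "delta": draws.delta,
        "tau_gamma": draws.tau_gamma,
        "tau_delta": draws.tau_delta,
    }
    multi = draws.n_chains >= 2
    ds = az.convert_to_dataset(arrays)
    rhat = az.rhat(ds) if multi else None
    ess = az.ess(ds, method="bulk")

    rows = []

    def emit(name, flat, rh, es):
        pooled = flat.reshape(-1)
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
                "q2.5": float(np.quantile(pooled, 0.025)),
                "q97.5": float(np.quantile(pooled, 0.975)),
                "rhat": rh,
                "ess": es,
            }
        )

    for name in ("alpha", "beta", "tau_gamma", "tau_delta"):
        emit(
            name,
            arrays[name],
            float(rhat[name].values) if multi else float("nan"),
            float(ess[name].values),
        )
    for vec, labels in (("gamma", draws.muni_codes), ("delta", draws.years)):
        dim = arrays[vec].shape[2]
        for i in range(dim):
            label = labels[i] if i < len(labels) else i
            emit(
                f"{vec}[{label}]",
                arrays[vec][:, :, i],
                float(rhat[vec].values[i]) if multi else float("nan"),
                float(ess[vec].values[i]),
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Laplace / MAP cross-check
# ---------------------------------------------------------------------------


@dataclass
class LaplaceFit:
    alpha: float
    beta: float
    gamma: np.ndarray
    delta: np.ndarray
    sd_alpha: float
    sd_beta: float
    sd_gamma: np.ndarray
    sd_delta: np.ndarray
    tau_gamma: float
    tau_delta: float
    log_evidence: float
    grad_norm: float
    n_iterations: int
    # posterior ridge through beta: conditional-mean shift of the other
    # location parameters per unit change of beta (from the Hessian inverse)
    beta_profile_alpha: float = 0.0
    beta_profile_gamma: np.ndarray | None = None
    beta_profile_delta: np.ndarray | None = None


def _sum_zero_basis(T: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^T, shape (T, T-1)."""
    from scipy.linalg import null_space

    return null_space(np.ones((1, T)))


def _newton_mode(X, y, eps, P, alpha0, tol=1e-8, max_iter=100):
    """Maximize sum(y*eta - eps*exp(eta)) - theta'P theta/2 by damped Newton.

    The convergence tolerance on the gradient norm is the larger of ``tol``
    and the float64 resolution of the objective (~1e-14 of the total count),
    since on very large panels the score cannot be driven below rounding
    noise.
    """
    p = X.shape[1]
    theta = np.zeros(p)
    theta[0] = alpha0
    scale = max(1.0, float(np.abs(y).sum()))
    tol_eff = max(tol, 1e-14 * scale)

    def objective(th):
        eta = X @ th
        with np.errstate(over="ignore"):
            lam = eps * np.exp(eta)
        if not np.all(np.isfinite(lam)):
            return -np.inf, None
        return float(y @ eta - lam.sum() - 0.5 * th @ P @ th), lam

    f, lam = objective(theta)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        grad = X.T @ (y - lam) - P @ theta
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < tol_eff:
            H = (X.T * lam) @ X + P
            return theta, H, f, grad_norm, it
        H = (X.T * lam) @ X + P
        step = np.linalg.solve(H, grad)
        noise = 1e-9 * max(1.0, abs(f))  # objective resolution floor
        t = 1.0
        for _ in range(60):  # backtracking line search
            f_new, lam_new = objective(theta + t * step)
            if f_new > f - noise:
                break
            t *= 0.5
        else:
            break
        theta = theta + t * step
        f, lam = f_new, lam_new
    # final convergence check
    grad = X.T @ (y - lam) - P @ theta
    grad_norm = float(np.linalg.norm(grad))
    if grad_norm < tol_eff:
        H = (X.T * lam) @ X + P
        return theta, H, f, grad_norm, max_iter
    raise RuntimeError(
        f"Newton did not converge: gradient norm {grad_norm:.3e} after "
        f"{max_iter} iterations"
    )


def laplace_fit(
    data: ModelData,
    prior: PriorConfig | None = None,
    precisions: tuple[float, float] | None = None,
) -> LaplaceFit:
    """Gaussian (Laplace) approximation around the posterior mode.

    The latent block (alpha, beta, gamma, delta) is maximized by Newton
    iterations at fixed precisions; unless ``precisions`` is supplied, the
    precision pair is chosen by maximizing the Laplace approximation to its
    marginal posterior (Nelder-Mead on the log scale).  Posterior sds come
    from the inverse negative Hessian at the mode; delta is parameterized in
    an orthonormal sum-to-zero basis throughout.
    """
    prior = prior or PriorConfig()
    d = data
    N, T = d.N, d.T
    n = d.n_obs
    has_delta = T >= 2
    p = 2 + N + (T - 1 if has_delta else 0)

    X = np.zeros((n, p))
    if n:
        X[:, 0] = 1.0
        X[:, 1] = d.x
        X[np.arange(n), 2 + d.muni_index] = 1.0
    Z = _sum_zero_basis(T) if has_delta else None
    if has_delta and n:
        X[:, 2 + N:] = Z[d.year_index]
    if has_delta:
        D = np.diff(np.eye(T), axis=0)
        Q_u = Z.T @ (D.T @ D) @ Z  # RW1 structure in the sum-zero basis
    y = d.y.astype(float)
    eps = d.offset_eps.astype(float)
    alpha0 = float(np.log((y.sum() + 0.5) / (eps.sum() + 0.5))) if n else 0.0
    a, b = prior.hyper_shape, prior.hyper_rate
    p0 = prior.fixed_effect_precision

    def penalty_matrix(tau_g, tau_d):
        P = np.zeros((p, p))
        P[0, 0] = P[1, 1] = p0
        P[range(2, 2 + N), range(2, 2 + N)] = tau_g
        if has_delta:
            P[2 + N:, 2 + N:] = tau_d * Q_u
        return P

    def evidence(log_taus):
        tau_g, tau_d = np.exp(log_taus)
        P = penalty_matrix(tau_g, tau_d)
        theta, H, f, gnorm, it = _newton_mode(X, y, eps, P, alpha0)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, None
        lev = (
            f
            + 0.5 * N * np.log(tau_g)
            + (0.5 * (T - 1) * np.log(tau_d) if has_delta else 0.0)
            + 0.5 * p * np.log(2.0 * np.pi)
            - 0.5 * logdet
        )
        for tau in (tau_g, tau_d):
            lev += a * np.log(b) - gammaln(a) + (a - 1) * np.log(tau) - b * tau
        return float(lev), (theta, H, gnorm, it)

    if precisions is not None:
        log_taus = np.log(np.asarray(precisions, dtype=float))
    else:
        from scipy.optimize import minimize

        res = minimize(
            lambda lt: -evidence(lt)[0],
            x0=np.log([10.0, 10.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        log_taus = res.x

    lev, (theta, H, gnorm, it) = evidence(log_taus)
    cov = np.linalg.inv(H)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    gamma = theta[2:2 + N]
    if has_delta:
        u = theta[2 + N:]
        delta = Z @ u
        cov_u = cov[2 + N:, 2 + N:]
        sd_delta = np.sqrt(np.clip(np.einsum("ti,ij,tj->t", Z, cov_u, Z), 0.0, None))
    else:
        delta = np.zeros(T)
        sd_delta = np.zeros(T)
    var_beta = max(float(cov[1, 1]), 1e-300)
    prof_alpha = float(cov[0, 1] / var_beta)
    prof_gamma = cov[2:2 + N, 1] / var_beta
    if has_delta:
        prof_delta = Z @ (cov[2 + N:, 1] / var_beta)
    else:
        prof_delta = np.zeros(T)
    tau_g, tau_d = np.exp(log_taus)
    return LaplaceFit(
        alpha=float(theta[0]),
        beta=float(theta[1]),
        gamma=gamma,
        delta=delta,
        sd_alpha=float(sd[0]),
        sd_beta=float(sd[1]),
        sd_gamma=sd[2:2 + N],
        sd_delta=sd_delta,
        tau_gamma=float(tau_g),
        tau_delta=float(tau_d),
        log_evidence=lev,
        grad_norm=gnorm,
        n_iterations=it,
        beta_profile_alpha=prof_alpha,
        beta_profile_gamma=prof_gamma,
        beta_profile_delta=prof_delta,
    )
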