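"""Hierarchical Bayesian fitting of the effort-choice models.

The model is a probit hierarchical Bernoulli model: subject ``i`` chooses
the reference action with probability
``Phi((U(n * E_i(F_R)) - U(E_i(F_T))) / gamma_i)`` where
``E_i(F) = F**alpha_i + beta_i`` and ``U`` is one of four utility
transforms.  Subject parameters are drawn from population normals
``alpha_i ~ N(mu_alpha, sigma_alpha)`` (likewise beta, gamma) with wide
priors: ``mu_alpha ~ N(1, 10)``, ``mu_beta ~ N(0, 100)`` and half-Cauchy
(0, 20) priors on ``mu_gamma`` and the three population SDs.

Sampling uses the affine-invariant ensemble sampler (emcee) on a centered
parameterization: subject parameters are sampled directly alongside the
population parameters (positive scale parameters on the log scale with the
Jacobian correction), and subject-level values are truncated to a small
positive floor inside the likelihood so effort stays positive.  The
centered form is appropriate here because every subject contributes
hundreds of trials, so subject parameters are strongly identified and the
hierarchical density has no funnel; a non-centered form would instead put
the density mode at arbitrarily large population SDs.  ``McmcConfig``
keeps the conventional chains/draws vocabulary:
``n_warmup``/``n_samples`` are ensemble sweeps and retained draws are
thinned to about ``n_chains * n_samples`` for summaries and WAIC.

Model comparison uses WAIC on the deviance scale,
``WAIC = -2 (lppd - p_waic)``, with the effective-parameter term from the
per-trial posterior variance of the log-likelihood; WAIC differences map to
evidence ratios via ``exp(-dWAIC / 2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp

from .effort import PARAM_FLOOR, SubjectParams, UtilityModel, equivalent_force

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "ModelFit",
    "log_likelihood",
    "fit_hierarchical",
    "waic",
    "relative_likelihood",
    "predict_choice_accuracy",
    "posterior_summaries",
    "PosteriorSummary",
]

_POP_NAMES = ("mu_alpha", "mu_beta", "mu_gamma",
              "sigma_alpha", "sigma_beta", "sigma_gamma")


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters; defaults are deliberately wide."""

    mu_alpha_loc: float = 1.0
    mu_alpha_scale: float = 10.0
    mu_beta_loc: float = 0.0
    mu_beta_scale: float = 100.0
    half_cauchy_scale: float = 20.0   # mu_gamma and all three sigmas

    def __post_init__(self) -> None:
        if min(self.mu_alpha_scale, self.mu_beta_scale, self.half_cauchy_scale) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings (conventional chains x draws vocabulary)."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_samples) < 1:
            raise ValueError("chains, warmup and samples must be positive")


REDUCED_MCMC = McmcConfig(n_chains=2, n_warmup=500, n_samples=500)


@dataclass
class ModelFit:
    """Posterior draws, pointwise log-likelihood and diagnostics for one model."""

    model: UtilityModel
    subject_ids: list[str]
    posterior: dict[str, np.ndarray]   # population: (chain, draw); subject: (chain, draw, subj)
    log_lik: np.ndarray                # (total draws, n_trials)
    diagnostics: dict[str, float]
    trials: pd.DataFrame | None = None
    waic_: float | None = field(default=None, repr=False)

    def flat(self, name: str) -> np.ndarray:
        """Draws with chain/draw axes merged (draw-major)."""
        a = self.posterior[name]
        return a.reshape(-1, *a.shape[2:])

    def population_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        lo = (1 - prob) / 2
        d = self.flat(name)
        return float(np.quantile(d, lo)), float(np.quantile(d, 1 - lo))

    def subject_median_params(self) -> dict[str, SubjectParams]:
        a = np.median(self.flat("alpha"), axis=0)
        b = np.median(self.flat("beta"), axis=0)
        g = np.median(self.flat("gamma"), axis=0)
        return {sid: SubjectParams(alpha=max(a[i], PARAM_FLOOR),
                                   beta=max(b[i], PARAM_FLOOR),
                                   gamma=max(g[i], PARAM_FLOOR))
                for i, sid in enumerate(self.subject_ids)}


# --- likelihood ----------------------------------------------------------

def _encode_trials(trials: pd.DataFrame) -> tuple[np.ndarray, ...]:
    subjects = sorted(trials["subject_id"].unique())
    sindex = {s: i for i, s in enumerate(subjects)}
    sidx = trials["subject_id"].map(sindex).to_numpy(int)
    f_ref = trials["F_R_N"].to_numpy(float)
    f_test = trials["F_T_N"].to_numpy(float)
    n_rep = trials["n_ref_repeats"].to_numpy(float)
    y = (trials["choice"] == "reference").to_numpy(float)
    return subjects, sidx, f_ref, f_test, n_rep, y


def _utility_diff(e_ref, e_test, model: UtilityModel):
    """Vectorized U(E_ref) - U(E_test); efforts must be positive."""
    if model is UtilityModel.DIFFERENCE:
        return e_test - e_ref
    if model is UtilityModel.HYPERBOLIC:
        return 1.0 / e_ref - 1.0 / e_test
    if model is UtilityModel.LOG_DIFFERENCE:
        return np.log(e_test) - np.log(e_ref)
    # hyperbolic on log effort; guard the singularity at E = 1
    lr, lt = np.log(e_ref), np.log(e_test)
    tiny = 1e-12
    lr = np.where(np.abs(lr) < tiny, tiny, lr)
    lt = np.where(np.abs(lt) < tiny, tiny, lt)
    return 1.0 / lr - 1.0 / lt


_PROB_FLOOR_LOG = np.log(1e-9)  # predicted choice probabilities floored at 1e-9


def _pointwise_loglik(alpha, beta, gamma, f_ref, f_test, n_rep, y,
                      model: UtilityModel):
    """Bernoulli-probit log-likelihood; parameter arrays broadcast over trials.

    Predicted probabilities are floored at 1e-9 so that tail posterior
    draws (e.g. an effort offset truncated at the positivity floor, making
    a hyperbolic utility astronomical at F = 0) cannot produce unbounded
    per-trial deviances that would destabilize the WAIC variance term.
    """
    e_ref = n_rep * (np.power(f_ref, alpha) + beta)
    e_test = np.power(f_test, alpha) + beta
    x = _utility_diff(e_ref, e_test, model) / gamma
    ll = y * log_ndtr(x) + (1.0 - y) * log_ndtr(-x)
    return np.maximum(ll, _PROB_FLOOR_LOG)


def log_likelihood(trials: pd.DataFrame,
                   params: dict[str, SubjectParams],
                   model: UtilityModel | str) -> np.ndarray:
    """Per-trial log Bernoulli mass under the probit choice rule.

    Every trial's subject must appear in ``params``.  Utility domain
    problems surface as -inf entries with a warning rather than an
    exception.
    """
    model = UtilityModel(model)
    if len(trials) == 0:
        return np.empty(0)
    missing = set(trials["subject_id"]) - set(params)
    if missing:
        raise KeyError(f"no parameters for subjects {sorted(missing)}")
    _, sidx, f_ref, f_test, n_rep, y = _encode_trials(trials)
    subjects = sorted(trials["subject_id"].unique())
    alpha = np.array([params[s].alpha for s in subjects])[sidx]
    beta = np.array([params[s].beta for s in subjects])[sidx]
    gamma = np.array([params[s].gamma for s in subjects])[sidx]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = _pointwise_loglik(alpha, beta, gamma, f_ref, f_test, n_rep, y, model)
    bad = ~np.isfinite(ll)
    if np.any(bad):
        warnings.warn(f"{bad.sum()} trials with undefined likelihood set to -inf")
        ll = np.where(bad, -np.inf, ll)
    return ll


# --- posterior -----------------------------------------------------------

def _unpack(theta: np.ndarray, n_subj: int):
    """theta (..., 6 + 3*n_subj) -> population params and subject params.

    Layout: mu_alpha, mu_beta, log mu_gamma, log sigma_(alpha|beta|gamma),
    then the per-subject alpha, beta, gamma blocks (centered; truncated to
    the positivity floor when used).
    """
    mu_a = theta[..., 0]
    mu_b = theta[..., 1]
    mu_g = np.exp(theta[..., 2])
    sig_a = np.exp(theta[..., 3])
    sig_b = np.exp(theta[..., 4])
    sig_g = np.exp(theta[..., 5])
    raw = theta[..., 6:]
    alpha = np.clip(raw[..., :n_subj], PARAM_FLOOR, None)
    beta = np.clip(raw[..., n_subj:2 * n_subj], PARAM_FLOOR, None)
    gamma = np.clip(raw[..., 2 * n_subj:], PARAM_FLOOR, None)
    return (mu_a, mu_b, mu_g, sig_a, sig_b, sig_g), (alpha, beta, gamma)


def _log_prior(theta: np.ndarray, priors: PriorSpec, n_subj: int) -> np.ndarray:
    mu_a = theta[..., 0]
    mu_b = theta[..., 1]
    mu_g = np.exp(theta[..., 2])
    lp = -0.5 * ((mu_a - priors.mu_alpha_loc) / priors.mu_alpha_scale) ** 2
    lp = lp - 0.5 * ((mu_b - priors.mu_beta_loc) / priors.mu_beta_scale) ** 2
    # half-Cauchy(0, s) on mu_gamma, sigma_*; sampled as logs -> +log x Jacobian
    s = priors.half_cauchy_scale
    for k in range(2, 6):
        lx = theta[..., k]
        x = np.exp(lx)
        lp = lp - np.log1p((x / s) ** 2) + lx
    if n_subj:
        raw = theta[..., 6:]
        for block, (mu, lsig) in enumerate(
                ((mu_a, theta[..., 3]), (mu_b, theta[..., 4]),
                 (mu_g, theta[..., 5]))):
            p = raw[..., block * n_subj:(block + 1) * n_subj]
            sig = np.exp(lsig)
            lp = lp - n_subj * lsig
            lp = lp - 0.5 * np.sum(((p - mu[..., None]) / sig[..., None]) ** 2,
                                   axis=-1)
    return lp


def _make_log_post(priors: PriorSpec, model: UtilityModel, n_subj: int,
                   sidx, f_ref, f_test, n_rep, y):
    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        # guard against overflow in exp of the log-scale parameters
        if np.any(np.abs(theta) > 50):
            out = np.full(theta.shape[0], -np.inf)
            ok = np.all(np.abs(theta) <= 50, axis=-1)
            if np.any(ok):
                out[ok] = log_post(theta[ok])
            return out
        lp = _log_prior(theta, priors, n_subj)
        if n_subj:
            _, (alpha, beta, gamma) = _unpack(theta, n_subj)
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                ll = _pointwise_loglik(alpha[:, sidx], beta[:, sidx],
                                       gamma[:, sidx], f_ref, f_test, n_rep, y,
                                       model)
            ll = np.where(np.isfinite(ll), ll, -1e10)
            lp = lp + ll.sum(axis=-1)
        return lp

    return log_post


def _initial_point(n_subj: int) -> np.ndarray:
    x0 = np.zeros(6 + 3 * n_subj)
    x0[0] = 1.5                       # mu_alpha
    x0[1] = 8.0                       # mu_beta
    x0[2] = np.log(1.5)               # mu_gamma
    x0[3:6] = np.log([0.5, 3.0, 0.8])  # sigmas
    if n_subj:
        x0[6:6 + n_subj] = 1.5
        x0[6 + n_subj:6 + 2 * n_subj] = 8.0
        x0[6 + 2 * n_subj:] = 1.5
    return x0


def _subject_map_estimates(model: UtilityModel, sidx, f_ref, f_test, n_rep, y,
                           n_subj: int) -> np.ndarray:
    """Independent per-subject MAP fits of (alpha, beta, gamma).

    Used only to initialize the ensemble: starting the walkers from
    differentiated subject estimates keeps the centered hierarchy away from
    the degenerate complete-pooling configuration (the density singularity
    at sigma -> 0 with all subjects equal), which likelihood differences
    between subjects otherwise rule out.  A weak regularizing prior keeps
    the 3-parameter fits well-posed for subjects with one-sided choices.
    """
    from scipy.optimize import minimize

    prior_loc = np.array([1.5, 8.0, 1.5])
    prior_scale = np.array([2.0, 15.0, 3.0])
    bounds = [(0.2, 6.0), (PARAM_FLOOR, 80.0), (0.05, 40.0)]
    out = np.empty((n_subj, 3))
    for i in range(n_subj):
        m = sidx == i
        fr, ft, nr, yy = f_ref[m], f_test[m], n_rep[m], y[m]

        def neg(p):
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                ll = _pointwise_loglik(p[0], p[1], p[2], fr, ft, nr, yy, model)
            ll = np.where(np.isfinite(ll), ll, -1e10).sum()
            return -ll + 0.5 * np.sum(((p - prior_loc) / prior_scale) ** 2)

        res = minimize(neg, prior_loc, method="L-BFGS-B", bounds=bounds)
        out[i] = res.x if np.isfinite(res.fun) else prior_loc
    return out


def fit_hierarchical(trials: pd.DataFrame,
                     model: UtilityModel | str = UtilityModel.LOG_DIFFERENCE,
                     priors: PriorSpec | None = None,
                     cfg: McmcConfig | None = None) -> ModelFit:
    """Sample the hierarchical probit model posterior for one utility model.

    Runs a short optimisation to locate a posterior mode, then the ensemble
    sampler for ``n_warmup`` burn-in sweeps and ``n_samples`` retained
    sweeps, thinned to about ``n_chains * n_samples`` draws.  Emits an
    R-hat diagnostic warning (threshold 1.05) instead of failing.
    """
    import emcee

    model = UtilityModel(model)
    priors = priors or PriorSpec()
    cfg = cfg or McmcConfig()

    if len(trials):
        subjects, sidx, f_ref, f_test, n_rep, y = _encode_trials(trials)
    else:
        subjects, sidx, f_ref, f_test, n_rep, y = [], None, None, None, None, None
    n_subj = len(subjects)
    ndim = 6 + 3 * n_subj
    log_post = _make_log_post(priors, model, n_subj, sidx, f_ref, f_test, n_rep, y)

    rng = np.random.default_rng(cfg.seed)
    x0 = _initial_point(n_subj)
    scales = np.full(ndim, 0.1)
    if n_subj:
        est = _subject_map_estimates(model, sidx, f_ref, f_test, n_rep, y,
                                     n_subj)
        mu = est.mean(axis=0)
        # spread floors keep the initial sigmas off the funnel tip
        sig = np.maximum(est.std(axis=0, ddof=1) if n_subj > 1 else np.zeros(3),
                         [0.1, 1.0, 0.3])
        x0[0], x0[1], x0[2] = mu[0], mu[1], np.log(mu[2])
        x0[3:6] = np.log(sig)
        x0[6:6 + n_subj] = est[:, 0]
        x0[6 + n_subj:6 + 2 * n_subj] = est[:, 1]
        x0[6 + 2 * n_subj:] = est[:, 2]
        scales[6:6 + n_subj] = 0.25 * sig[0]
        scales[6 + n_subj:6 + 2 * n_subj] = 0.25 * sig[1]
        scales[6 + 2 * n_subj:] = 0.25 * sig[2]

    nwalkers = max(2 * ndim + 2, 48)
    nwalkers += nwalkers % 2
    p0 = x0 + scales * rng.standard_normal((nwalkers, ndim))

    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post, vectorize=True)
    sampler.random_state = np.random.RandomState(cfg.seed).get_state()
    state = sampler.run_mcmc(p0, cfg.n_warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, cfg.n_samples, progress=False)

    thin = max(1, int(round(nwalkers / cfg.n_chains)))
    chain = sampler.get_chain(thin=thin)          # (steps, walkers, ndim)
    nsteps = chain.shape[0]

    # group walkers into n_chains pseudo-chains for split diagnostics
    per = nwalkers // cfg.n_chains
    used = per * cfg.n_chains
    grouped = chain[:, :used, :].reshape(nsteps, cfg.n_chains, per, ndim)
    grouped = np.moveaxis(grouped, 1, 0).reshape(cfg.n_chains, nsteps * per, ndim)

    pop, (alpha, beta, gamma) = _unpack(grouped, n_subj)
    posterior = dict(zip(_POP_NAMES, pop))
    posterior["alpha"], posterior["beta"], posterior["gamma"] = alpha, beta, gamma

    diagnostics = _diagnostics(posterior)
    if diagnostics["rhat_max"] > 1.05:
        warnings.warn(
            f"R-hat {diagnostics['rhat_max']:.3f} > 1.05 on population "
            "parameters; consider more warmup sweeps")

    if n_subj:
        af = alpha.reshape(-1, n_subj)[:, sidx]
        bf = beta.reshape(-1, n_subj)[:, sidx]
        gf = gamma.reshape(-1, n_subj)[:, sidx]
        with np.errstate(divide="ignore", invalid="ignore"):
            log_lik = _pointwise_loglik(af, bf, gf, f_ref, f_test, n_rep, y, model)
        log_lik = np.where(np.isfinite(log_lik), log_lik, -1e10)
    else:
        log_lik = np.empty((grouped.shape[0] * grouped.shape[1], 0))

    return ModelFit(model=model, subject_ids=list(subjects),
                    posterior=posterior, log_lik=log_lik,
                    diagnostics=diagnostics, trials=trials)


def _diagnostics(posterior: dict[str, np.ndarray]) -> dict[str, float]:
    """Split-R-hat and bulk ESS on the population parameters via arviz."""
    import arviz as az

    rhats, esss = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in _POP_NAMES:
            d = posterior[name]
            rhats.append(float(az.rhat(az.convert_to_dataset(d[..., None]))["x"].max()))
            esss.append(float(az.ess(az.convert_to_dataset(d[..., None]))["x"].min()))
    return {"rhat_max": float(np.nanmax(rhats)),
            "ess_min": float(np.nanmin(esss))}


# --- model comparison ----------------------------------------------------

def waic(fit: ModelFit | np.ndarray) -> float:
    """WAIC on the deviance scale: -2 (lppd - p_waic).

    ``lppd`` is the summed log pointwise predictive density and ``p_waic``
    the summed per-trial posterior variance of the log-likelihood.
    """
    ll = fit.log_lik if isinstance(fit, ModelFit) else np.asarray(fit, float)
    if ll.ndim != 2:
        raise ValueError("log-likelihood must be (draws, trials)")
    s = ll.shape[0]
    if s < 2:
        raise ValueError("WAIC needs at least two posterior draws")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    value = -2.0 * (lppd - p_waic)
    if isinstance(fit, ModelFit):
        fit.waic_ = value
    return value


def relative_likelihood(waic_a: float, waic_b: float) -> float:
    """Evidence ratio of model a relative to model b: exp(-(WAIC_a - WAIC_b)/2)."""
    return float(np.exp(-(waic_a - waic_b) / 2.0))


def waic_table(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """WAIC comparison table with evidence ratios relative to the best model."""
    rows = [{"model": name, "waic": waic(f)} for name, f in fits.items()]
    df = pd.DataFrame(rows).sort_values("waic").reset_index(drop=True)
    best = df["waic"].iloc[0]
    df["relative_likelihood"] = np.exp(-(df["waic"] - best) / 2.0)
    return df


def predict_choice_accuracy(trials: pd.DataFrame, fit: ModelFit) -> float:
    """Percent of choices predicted by the fitted equivalent-force boundary.

    Prediction: reference iff the test force exceeds the subject's fitted
    equivalent force (posterior-median parameters); exact ties predict the
    test choice.
    """
    params = fit.subject_median_params()
    missing = set(trials["subject_id"]) - set(params)
    if missing:
        raise KeyError(f"fit lacks subjects {sorted(missing)}")
    preds = []
    for sid, f_ref, f_test, n in zip(trials["subject_id"], trials["F_R_N"],
                                     trials["F_T_N"], trials["n_ref_repeats"]):
        feq = equivalent_force(f_ref, params[sid], int(n))
        preds.append("reference" if f_test > feq else "test")
    actual = trials["choice"].to_numpy()
    return float(100.0 * np.mean(np.asarray(preds) == actual))


# --- summaries -----------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Compound population posteriors and the equivalent-force curve band."""

    f_grid: np.ndarray
    compound: dict[str, np.ndarray]        # mixture samples per parameter
    curve_median: np.ndarray
    curve_lo: np.ndarray
    curve_hi: np.ndarray
    curve_draws: np.ndarray                # (draws, grid)
    subject_params: dict[str, SubjectParams]


def posterior_summaries(fit: ModelFit, f_grid, n_ref_repeats: int = 2,
                        seed: int = 0, prob: float = 0.95) -> PosteriorSummary:
    """Compound posteriors and the equivalent-force curve with credible band.

    The compound posterior of each parameter is the mixture over posterior
    draws of ``N(mu, sigma)`` (one mixture sample per draw, truncated to
    positivity).  Draw-wise equivalent-force curves use the compound
    (alpha, beta) samples; the band is the central ``prob`` interval on the
    grid.
    """
    rng = np.random.default_rng(seed)
    f_grid = np.asarray(f_grid, float)
    comp = {}
    for base in ("alpha", "beta", "gamma"):
        mu = fit.flat(f"mu_{base}")
        sig = fit.flat(f"sigma_{base}")
        comp[base] = np.clip(rng.normal(mu, sig), PARAM_FLOOR, None)
    n = n_ref_repeats
    a = comp["alpha"][:, None]
    b = comp["beta"][:, None]
    curves = np.power(n * np.power(f_grid[None, :], a) + (n - 1) * b, 1.0 / a)
    lo = (1 - prob) / 2
    return PosteriorSummary(
        f_grid=f_grid,
        compound=comp,
        curve_median=np.median(curves, axis=0),
        curve_lo=np.quantile(curves, lo, axis=0),
        curve_hi=np.quantile(curves, 1 - lo, axis=0),
        curve_draws=curves,
        subject_params=fit.subject_median_params(),
    )


def population_summary_table(fit: ModelFit) -> pd.DataFrame:
    """Median and 95% CI of the population-level parameters."""
    rows = []
    for name in _POP_NAMES:
        d = fit.flat(name)
        rows.append({"parameter": name,
                     "median": float(np.median(d)),
                     "ci_2.5": float(np.quantile(d, 0.025)),
                     "ci_97.5": float(np.quantile(d, 0.975))})
    return pd.DataFrame(rows)
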