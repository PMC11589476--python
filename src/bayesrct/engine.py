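"""Log posteriors and a self-contained adaptive MCMC sampler.

Two model families are supported:

* a hierarchical Bernoulli/logit model for 60-day mortality with a
  non-centred site random intercept (``u_site = tau * z_site``,
  ``z ~ N(0,1)``, ``tau ~ half-normal``), optionally extended with one
  covariate main effect and a treatment-by-covariate interaction; and
* an Efron-tie-corrected Cox partial likelihood for time to discharge
  alive, with site fixed effects in the linear predictor.

Sampling is adaptive random-walk Metropolis: the global coefficient block
uses a jointly adapted proposal covariance, the log of the site-effect
scale a scalar proposal, and the site deviations a simultaneous
per-site-accepted vector update (valid because the likelihood factorises
over sites given the global parameters).  All adaptation is confined to
warm-up and frozen afterwards; runs are reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .priors import (
    COEFFICIENT_PRIOR_SCALE,
    INTERCEPT_PRIOR_SCALE,
    SITE_SD_PRIOR_SCALE,
    PriorSpec,
    mortality_prior_family,
)

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "Diagnostics",
    "SamplerSettings",
    "log_posterior_logistic",
    "log_partial_likelihood_cox",
    "sample",
    "diagnose",
    "save_draws_csv",
]

_LOG_2PI = float(np.log(2 * np.pi))


@dataclass
class ModelSpec:
    """What to fit: outcome family, adjustment structure, and priors."""

    outcome: str = "mortality"  # or "discharge"
    treatment_prior: PriorSpec = field(
        default_factory=lambda: mortality_prior_family()["sceptical"]
    )
    site_term: str = "random_intercept"  # "random_intercept" | "fixed_effects" | "none"
    covariate: str | None = None
    covariate_values: np.ndarray | None = None  # transformed+centred, aligned to ds rows
    intercept_prior_scale: float = INTERCEPT_PRIOR_SCALE
    coef_prior_scale: float = COEFFICIENT_PRIOR_SCALE
    tau_prior_scale: float = SITE_SD_PRIOR_SCALE

    def __post_init__(self) -> None:
        if self.outcome not in ("mortality", "discharge"):
            raise ValueError("outcome must be 'mortality' or 'discharge'")
        if self.site_term not in ("random_intercept", "fixed_effects", "none"):
            raise ValueError("unknown site_term")
        if self.outcome == "mortality" and self.site_term == "fixed_effects":
            raise ValueError("site fixed effects are supported for the discharge model")
        if self.outcome == "mortality" and self.treatment_prior.effect_scale != "log_odds":
            raise ValueError("mortality models need a log-odds treatment prior")
        if self.outcome == "discharge" and self.treatment_prior.effect_scale != "log_hazard":
            raise ValueError("discharge models need a log-hazard treatment prior")


@dataclass
class SamplerSettings:
    """Chains/iterations and adaptation targets.

    Defaults: 4 chains x 2500 post-warm-up draws after 2500 adaptation
    iterations; proposal scales target 0.28 acceptance for the joint
    global block and 0.44 for scalar/per-site updates.
    """

    n_chains: int = 4
    n_iterations: int = 2500
    warmup: int = 2500
    target_accept_joint: float = 0.28
    target_accept_scalar: float = 0.44


@dataclass
class PosteriorDraws:
    """Named parameter draws indexed by (chain, iteration) plus metadata.

    Scalar parameters are (chains, iterations) arrays; vector parameters
    ("z" for site deviations, "site_coef" for Cox site fixed effects) are
    (chains, iterations, k).
    """

    draws: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape[:2] for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError("all parameters must share the (chain, iteration) shape")
        for name, arr in self.draws.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite draws for {name!r}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iterations(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: (chains*iterations,) or (..., k)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])


@dataclass
class Diagnostics:
    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    ess_tail: dict[str, float]
    acceptance_rate: dict[str, list[float]]
    acceptable: bool
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess_bulk": self.ess_bulk,
            "ess_tail": self.ess_tail,
            "acceptance_rate": self.acceptance_rate,
            "acceptable": self.acceptable,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# logistic model


class _LogisticData:
    """Design arrays for the hierarchical logistic model."""

    def __init__(self, ds, model: ModelSpec):
        df = ds.df
        if df["death60"].isna().any():
            raise ValueError(
                "missing outcomes present; exclude incomplete cases before fitting"
            )
        self.y = df["death60"].to_numpy(dtype=float)
        self.arm = df["arm"].to_numpy(dtype=float)
        self.n = len(df)
        if model.covariate is not None:
            x = model.covariate_values
            if x is None:
                raise ValueError("covariate declared but covariate_values not provided")
            x = np.asarray(x, dtype=float)
            if len(x) != self.n:
                raise ValueError("covariate_values must align with the dataset rows")
            self.x = x
        else:
            self.x = None
        self.hier = model.site_term == "random_intercept"
        if self.hier and self.n > 0:
            counts = df["site_id"].value_counts()
            # order sites by decreasing size, ties by label: index 0 = reference
            order = sorted(counts.index, key=lambda s: (-counts[s], s))
            self.site_labels = list(order)
            lookup = {s: i for i, s in enumerate(order)}
            self.site_idx = df["site_id"].map(lookup).to_numpy(dtype=np.intp)
            self.n_sites = len(order)
        else:
            self.site_labels = []
            self.site_idx = np.zeros(self.n, dtype=np.intp)
            self.n_sites = 0
        # global design matrix columns: intercept, arm, (x, arm*x)
        cols = [np.ones(self.n), self.arm]
        if self.x is not None:
            cols += [self.x, self.arm * self.x]
        self.X_global = np.column_stack(cols) if self.n else np.zeros((0, len(cols)))
        self.n_global = self.X_global.shape[1]

    def loglik(self, eta: np.ndarray) -> float:
        return float(self.y @ eta - np.logaddexp(0.0, eta).sum())

    def loglik_rows(self, eta: np.ndarray) -> np.ndarray:
        return self.y * eta - np.logaddexp(0.0, eta)


def _normal_logpdf(x, loc, scale):
    return -0.5 * ((x - loc) / scale) ** 2 - np.log(scale) - 0.5 * _LOG_2PI


def _halfnormal_logpdf(x, scale):
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


def _global_prior_params(model: ModelSpec, n_global: int):
    locs = np.zeros(n_global)
    scales = np.full(n_global, model.coef_prior_scale)
    scales[0] = model.intercept_prior_scale
    locs[1] = model.treatment_prior.location
    scales[1] = model.treatment_prior.scale
    return locs, scales


def log_posterior_logistic(params: dict, ds, model: ModelSpec) -> float:
    """Joint log density of data and parameters for the logistic model.

    ``params`` maps 'alpha', 'beta' (and 'gamma', 'delta' for interaction
    models) to scalars, and for hierarchical models 'tau' to a scalar and
    'z' to a per-site array ordered by decreasing site size (ties by
    label).  With an empty dataset the value equals the joint log prior.
    """
    data = _LogisticData(ds, model)
    names = ["alpha", "beta"] + (["gamma", "delta"] if data.x is not None else [])
    theta = np.array([float(params[k]) for k in names])
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameters")
    eta = data.X_global @ theta
    locs, scales = _global_prior_params(model, data.n_global)
    lp = float(_normal_logpdf(theta, locs, scales).sum())
    if data.hier:
        tau = float(params["tau"])
        z = np.asarray(params["z"], dtype=float)
        if not (np.isfinite(tau) and np.all(np.isfinite(z))):
            raise ValueError("non-finite parameters")
        if tau < 0:
            return -np.inf
        if len(z) != data.n_sites:
            raise ValueError(f"expected {data.n_sites} site deviations, got {len(z)}")
        eta = eta + tau * z[data.site_idx]
        lp += float(_normal_logpdf(z, 0.0, 1.0).sum())
        lp += float(_halfnormal_logpdf(tau, model.tau_prior_scale))
    return data.loglik(eta) + lp


def _run_logistic_chain(data: _LogisticData, model: ModelSpec, settings: SamplerSettings,
                        rng: np.random.Generator):
    d = data.n_global
    locs, scales = _global_prior_params(model, d)
    hier = data.hier and data.n_sites > 0
    S = data.n_sites

    theta = 0.1 * rng.standard_normal(d)
    log_tau = np.log(0.5) + 0.1 * rng.standard_normal() if hier else 0.0
    z = 0.1 * rng.standard_normal(S) if hier else np.zeros(0)

    tau = np.exp(log_tau) if hier else 0.0
    zrow = z[data.site_idx] if hier else 0.0
    eta = data.X_global @ theta + (tau * zrow if hier else 0.0)
    cur_ll = data.loglik(eta)

    def lp_global(t):
        return float(_normal_logpdf(t, locs, scales).sum())

    def lp_tau(lt):
        # half-normal on tau with log-scale Jacobian
        t = np.exp(lt)
        return float(_halfnormal_logpdf(t, model.tau_prior_scale)) + lt

    cur_lpg = lp_global(theta)
    cur_lpt = lp_tau(log_tau) if hier else 0.0

    # adaptation state
    step_g = 0.5
    chol = np.eye(d) * 0.3
    step_t = 0.3
    step_z = np.full(S, 0.5)
    step_r = 0.3
    step_c = 0.3
    mean_acc = np.zeros(3)
    n_kept = settings.n_iterations
    total = settings.warmup + n_kept
    # Welford accumulators for the global covariance
    w_n, w_mean, w_m2 = 0, np.zeros(d), np.zeros((d, d))

    out_theta = np.empty((n_kept, d))
    out_tau = np.empty(n_kept) if hier else None
    out_z = np.empty((n_kept, S)) if hier else None
    acc_counts = np.zeros(3)

    for it in range(total):
        warm = it < settings.warmup
        gamma_t = (it + 1) ** -0.7

        # --- global coefficient block (joint, two sub-updates per sweep)
        for _ in range(2):
            prop = theta + step_g * (chol @ rng.standard_normal(d))
            eta_p = eta + data.X_global @ (prop - theta)
            ll_p = data.loglik(eta_p)
            lpg_p = lp_global(prop)
            acc = np.log(rng.random()) < (ll_p + lpg_p) - (cur_ll + cur_lpg)
            if acc:
                theta, eta, cur_ll, cur_lpg = prop, eta_p, ll_p, lpg_p
            if warm:
                step_g *= np.exp(gamma_t * (float(acc) - settings.target_accept_joint))
        if warm:
            if it == settings.warmup // 2:
                # windowed adaptation: discard covariance gathered while the
                # chain was still finding the typical set
                w_n, w_mean, w_m2 = 0, np.zeros(d), np.zeros((d, d))
            w_n += 1
            delta = theta - w_mean
            w_mean += delta / w_n
            w_m2 += np.outer(delta, theta - w_mean)
            if w_n > 200 and it % 50 == 0:
                cov = w_m2 / (w_n - 1) + 1e-8 * np.eye(d)
                chol = np.linalg.cholesky(cov)
        else:
            acc_counts[0] += acc

        if hier:
            # --- log site-effect scale: several cheap sub-updates per sweep
            # (the scale mixes slowest; each update is a single vector op)
            for _ in range(3):
                lt_p = log_tau + step_t * rng.standard_normal()
                tau_p = np.exp(lt_p)
                eta_p = eta + (tau_p - tau) * zrow
                ll_p = data.loglik(eta_p)
                lpt_p = lp_tau(lt_p)
                acc = np.log(rng.random()) < (ll_p + lpt_p) - (cur_ll + cur_lpt)
                if acc:
                    log_tau, tau, eta, cur_ll, cur_lpt = lt_p, tau_p, eta_p, ll_p, lpt_p
                if warm:
                    step_t *= np.exp(gamma_t * (float(acc) - settings.target_accept_scalar))
            if not warm:
                acc_counts[1] += acc

            # --- site deviations, simultaneous independent per-site updates
            zp = z + step_z * rng.standard_normal(S)
            d_eta = tau * (zp - z)[data.site_idx]
            eta_p = eta + d_eta
            d_rows = data.loglik_rows(eta_p) - data.loglik_rows(eta)
            site_dll = np.bincount(data.site_idx, weights=d_rows, minlength=S)
            log_r = site_dll - 0.5 * (zp**2 - z**2)
            acc_z = np.log(rng.random(S)) < log_r
            if acc_z.any():
                row_upd = acc_z[data.site_idx]
                eta = np.where(row_upd, eta_p, eta)
                z = np.where(acc_z, zp, z)
                zrow = z[data.site_idx]
                cur_ll += float(site_dll[acc_z].sum())
            if warm:
                step_z *= np.exp(gamma_t * (acc_z.astype(float) - settings.target_accept_scalar))
            else:
                acc_counts[2] += acc_z.mean()

            # --- interweaved centred-parameterisation update of tau: hold
            # u = tau * z fixed (likelihood unchanged) and update tau from
            # its conditional given u, then set z = u / tau'.  This mixes
            # the scale when sites are data-rich, where the non-centred
            # update alone stalls.
            if S > 0:
                u_sq = float(((tau * z) ** 2).sum())

                def lp_tau_centred(lt):
                    t = np.exp(lt)
                    return (
                        -S * lt - u_sq / (2 * t**2)
                        + float(_halfnormal_logpdf(t, model.tau_prior_scale)) + lt
                    )

                cur_lpc = lp_tau_centred(log_tau)
                lt_p = log_tau + step_c * rng.standard_normal()
                acc = np.log(rng.random()) < lp_tau_centred(lt_p) - cur_lpc
                if acc:
                    u = tau * z
                    log_tau = lt_p
                    tau = np.exp(log_tau)
                    z = u / tau
                    zrow = z[data.site_idx]
                    cur_lpt = lp_tau(log_tau)
                if warm:
                    step_c *= np.exp(gamma_t * (float(acc) - settings.target_accept_scalar))

            # --- translation move along the alpha / site-deviation ridge:
            # alpha -> alpha + e, z -> z - e/tau leaves every linear
            # predictor unchanged, so only the priors enter the ratio
            eps = step_r * rng.standard_normal()
            a_p = theta[0] + eps
            z_p = z - eps / tau
            d_lp = (
                _normal_logpdf(a_p, locs[0], scales[0])
                - _normal_logpdf(theta[0], locs[0], scales[0])
                - 0.5 * float((z_p**2 - z**2).sum())
            )
            acc = np.log(rng.random()) < d_lp
            if acc:
                theta = theta.copy()
                theta[0] = a_p
                z = z_p
                zrow = z[data.site_idx]
                cur_lpg = lp_global(theta)
            if warm:
                step_r *= np.exp(gamma_t * (float(acc) - settings.target_accept_scalar))

        if not warm:
            k = it - settings.warmup
            out_theta[k] = theta
            if hier:
                out_tau[k] = tau
                out_z[k] = z

    rates = acc_counts / n_kept
    return out_theta, out_tau, out_z, rates


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties)


class _CoxData:
    """Pre-sorted risk-set structure for the Efron partial likelihood.

    ``time``/``event`` are the subdistribution-prepared values; ``X`` is
    the full design (treatment column first, then site fixed effects).
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, X: np.ndarray,
                 col_names: list[str]):
        if event.sum() == 0:
            raise ValueError("no events in the dataset; cannot form a partial likelihood")
        order = np.argsort(time, kind="stable")
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.X = X[order]
        self.col_names = col_names
        self.n, self.p = self.X.shape
        # unique event times and their tie structure
        ev_times = np.unique(self.time[self.event])
        self.first_at_risk = np.searchsorted(self.time, ev_times, side="left")
        self.event_rows = np.flatnonzero(self.event)
        group_of_event = np.searchsorted(ev_times, self.time[self.event_rows])
        self.group_of_event = group_of_event
        m = np.bincount(group_of_event, minlength=len(ev_times))
        self.m = m
        # flattened Efron fractions l/m for l = 0..m-1 per group
        self.frac_flat = np.concatenate([np.arange(k) / k for k in m])
        self.group_of_flat = np.repeat(np.arange(len(ev_times)), m)

    def log_partial_likelihood(self, eta: np.ndarray) -> float:
        eta = eta - eta.max() if len(eta) else eta
        w = np.exp(eta)
        suffix = np.cumsum(w[::-1])[::-1]
        s_risk = suffix[self.first_at_risk]
        s_d = np.bincount(self.group_of_event, weights=w[self.event_rows],
                          minlength=len(self.m))
        terms = np.log(s_risk[self.group_of_flat] - self.frac_flat * s_d[self.group_of_flat])
        return float(eta[self.event_rows].sum() - terms.sum())


def log_partial_likelihood_cox(beta_terms: np.ndarray, ds) -> float:
    """Efron-corrected Cox log partial likelihood for the discharge event.

    ``ds`` is a TrialDataset; the data are subdistribution-prepared
    internally (deaths and in-hospital patients censored at day 60) and
    the linear predictor includes site fixed-effect terms: ``beta_terms``
    is ordered as (treatment, site coefficients) per the design built by
    the discharge model (reference site and zero-event pooled stratum
    excluded).  A dataset with zero discharge events is rejected.
    """
    from .discharge import build_cox_design

    design = build_cox_design(ds)
    beta_terms = np.asarray(beta_terms, dtype=float)
    if len(beta_terms) != design.p:
        raise ValueError(f"expected {design.p} coefficients ({design.col_names})")
    return design.log_partial_likelihood(design.X @ beta_terms)


def _run_cox_chain(data: _CoxData, model: ModelSpec, settings: SamplerSettings,
                   rng: np.random.Generator):
    p = data.p
    locs = np.zeros(p)
    prior_scales = np.full(p, model.coef_prior_scale)
    locs[0] = model.treatment_prior.location
    prior_scales[0] = model.treatment_prior.scale

    b = 0.1 * rng.standard_normal(p)
    eta = data.X @ b
    cur_ll = data.log_partial_likelihood(eta)
    cur_lp = _normal_logpdf(b, locs, prior_scales)

    step = np.full(p, 0.2)
    n_kept = settings.n_iterations
    total = settings.warmup + n_kept
    out = np.empty((n_kept, p))
    acc_count = 0.0

    for it in range(total):
        warm = it < settings.warmup
        gamma_t = (it + 1) ** -0.7
        for j in range(p):
            bj_p = b[j] + step[j] * rng.standard_normal()
            eta_p = eta + (bj_p - b[j]) * data.X[:, j]
            ll_p = data.log_partial_likelihood(eta_p)
            lp_p = _normal_logpdf(bj_p, locs[j], prior_scales[j])
            acc = np.log(rng.random()) < (ll_p + lp_p) - (cur_ll + cur_lp[j])
            if acc:
                b = b.copy()
                b[j] = bj_p
                eta, cur_ll = eta_p, ll_p
                cur_lp[j] = lp_p
            if warm:
                step[j] *= np.exp(gamma_t * (float(acc) - settings.target_accept_scalar))
            elif j == 0:
                acc_count += acc
        if not warm:
            out[it - settings.warmup] = b
    return out, acc_count / n_kept


# ---------------------------------------------------------------------------
# public sampling surface


def sample(model: ModelSpec, ds, n_chains: int = 4, n_iterations: int = 2500,
           warmup: int | None = None, seed: int = 0) -> PosteriorDraws:
    """Draw from the model's posterior with adaptive random-walk Metropolis.

    Returns post-warm-up draws for all parameters; fully reproducible for
    a fixed seed (chains use independent spawned RNG streams and run
    sequentially).  Requires at least two chains so that split-R-hat is
    defined downstream.
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    settings = SamplerSettings(
        n_chains=n_chains,
        n_iterations=n_iterations,
        warmup=n_iterations if warmup is None else warmup,
    )
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    meta = {
        "seed": seed,
        "outcome": model.outcome,
        "site_term": model.site_term,
        "treatment_prior": {
            "stance": model.treatment_prior.stance,
            "location": model.treatment_prior.location,
            "scale": model.treatment_prior.scale,
        },
        "n_chains": n_chains,
        "n_iterations": settings.n_iterations,
        "warmup": settings.warmup,
        "warnings": [],
    }

    if model.outcome == "mortality":
        data = _LogisticData(ds, model)
        meta["site_labels"] = data.site_labels
        meta["reference_site"] = data.site_labels[0] if data.site_labels else None
        meta["n_analysed"] = data.n
        names = ["alpha", "beta"] + (["gamma", "delta"] if data.x is not None else [])
        thetas, taus, zs, rate_rows = [], [], [], []
        for ss in streams:
            th, ta, zz, rates = _run_logistic_chain(
                data, model, settings, np.random.default_rng(ss)
            )
            thetas.append(th)
            taus.append(ta)
            zs.append(zz)
            rate_rows.append(rates)
        draws = {
            name: np.stack([t[:, i] for t in thetas]) for i, name in enumerate(names)
        }
        if data.hier:
            draws["tau"] = np.stack(taus)
            draws["z"] = np.stack(zs)
        meta["acceptance_rate"] = {"global": [float(r[0]) for r in rate_rows]}
        if data.hier:
            meta["acceptance_rate"]["tau"] = [float(r[1]) for r in rate_rows]
            meta["acceptance_rate"]["z"] = [float(r[2]) for r in rate_rows]
    else:
        from .discharge import build_cox_design

        design = build_cox_design(ds)
        meta["n_analysed"] = design.n
        meta["n_events"] = int(design.event.sum())
        meta["design_columns"] = design.col_names
        chains, rates = [], []
        for ss in streams:
            out, rate = _run_cox_chain(design, model, settings, np.random.default_rng(ss))
            chains.append(out)
            rates.append(float(rate))
        stacked = np.stack(chains)  # (C, I, p)
        draws = {"beta": stacked[:, :, 0]}
        if design.p > 1:
            draws["site_coef"] = stacked[:, :, 1:]
        meta["acceptance_rate"] = {"beta": rates}

    for block, rs in meta["acceptance_rate"].items():
        for r in rs:
            if not 0.1 <= r <= 0.6:
                msg = f"acceptance rate {r:.2f} for block {block!r} outside [0.1, 0.6]"
                meta["warnings"].append(msg)
                warnings.warn(msg, stacklevel=2)
    return PosteriorDraws(draws=draws, meta=meta)


def diagnose(draws: PosteriorDraws, rhat_threshold: float = 1.01,
             ess_threshold: float = 400.0) -> Diagnostics:
    """Split-R-hat and bulk/tail effective sample sizes per parameter.

    The verdict is acceptable when every R-hat is below the threshold and
    every bulk ESS above it.  Vector parameters are reported per
    component; requires at least two chains.
    """
    if draws.n_chains < 2:
        raise ValueError("split-R-hat needs at least 2 chains")
    idata = az.from_dict(posterior=draws.draws)
    rhat_ds = az.rhat(idata)
    essb_ds = az.ess(idata, method="bulk")
    esst_ds = az.ess(idata, method="tail")

    def flatten(dataset) -> dict[str, float]:
        out = {}
        for name, da in dataset.items():
            vals = np.atleast_1d(da.values)
            if vals.size == 1:
                out[name] = float(vals.ravel()[0])
            else:
                for i, v in enumerate(vals.ravel()):
                    out[f"{name}[{i}]"] = float(v)
        return out

    rhat = flatten(rhat_ds)
    ess_bulk = flatten(essb_ds)
    ess_tail = flatten(esst_ds)
    warns = list(draws.meta.get("warnings", []))
    acceptable = all(np.isfinite(v) and v < rhat_threshold for v in rhat.values()) and all(
        v > ess_threshold for v in ess_bulk.values()
    )
    return Diagnostics(
        rhat=rhat,
        ess_bulk=ess_bulk,
        ess_tail=ess_tail,
        acceptance_rate=draws.meta.get("acceptance_rate", {}),
        acceptable=acceptable,
        warnings=warns,
    )


def save_draws_csv(draws: PosteriorDraws, path) -> None:
    """Persist draws in long format: chain, iteration, parameter, value."""
    rows = []
    for name, arr in draws.draws.items():
        if arr.ndim == 2:
            c, i = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]),
                               indexing="ij")
            rows.append(pd.DataFrame({
                "chain": c.ravel(), "iteration": i.ravel(),
                "parameter": name, "value": arr.ravel(),
            }))
        else:
            for k in range(arr.shape[2]):
                c, i = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]),
                                   indexing="ij")
                rows.append(pd.DataFrame({
                    "chain": c.ravel(), "iteration": i.ravel(),
                    "parameter": f"{name}[{k}]", "value": arr[:, :, k].ravel(),
                }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
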