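"""Primary-outcome model: 60-day mortality under a family of priors.

The estimand is the *conditional* treatment effect at the largest
(reference) site: per posterior draw the usual-arm and high-arm death
risks are evaluated at that site's linear predictor, then converted to a
risk ratio, a risk difference (in percentage points) and an odds ratio.
Threshold probabilities are draw fractions against a minimally clinically
important difference (MCID) of 2 percentage points on the risk
difference: any harm is RD > 0, important harm RD >= MCID, important
benefit RD <= -MCID, and no important difference the strict in-between.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

from .cohort import TrialDataset
from .engine import ModelSpec, PosteriorDraws, sample
from .priors import PriorSpec, mortality_prior_family

__all__ = [
    "Interval",
    "EffectSummary",
    "fit_primary",
    "arm_risks",
    "effect_summaries",
    "run_prior_family",
    "DEFAULT_MCID",
]

DEFAULT_MCID = 2.0  # percentage points of 60-day mortality

Interval = namedtuple("Interval", ["median", "lower", "upper"])


def _interval(values: np.ndarray, mass: float = 0.95) -> Interval:
    lo, med, hi = np.percentile(values, [100 * (1 - mass) / 2, 50, 100 * (1 + mass) / 2])
    return Interval(float(med), float(lo), float(hi))


@dataclass
class EffectSummary:
    """Posterior summary of the conditional treatment effect on mortality."""

    risk_high: Interval
    risk_usual: Interval
    rr: Interval
    rd: Interval  # percentage points
    or_: Interval
    p_any_harm: float
    p_any_benefit: float
    p_important_harm: float
    p_important_benefit: float
    p_no_important_difference: float
    mcid: float
    n_analysed: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("risk_high", "risk_usual", "rr", "rd", "or_"):
            d[key] = dict(zip(("median", "lower", "upper"), d[key]))
        return d

    def to_csv_row(self, label: str = "") -> dict:
        """One row shaped like a published results table."""
        fmt = lambda iv, k=1: f"{iv.median:.{k}f} ({iv.lower:.{k}f} to {iv.upper:.{k}f})"
        return {
            "analysis": label,
            "risk_high_pct": fmt(Interval(*[100 * v for v in self.risk_high])),
            "risk_usual_pct": fmt(Interval(*[100 * v for v in self.risk_usual])),
            "rr": fmt(self.rr, 2),
            "rd_pct": fmt(self.rd),
            "p_any_harm_pct": round(100 * self.p_any_harm),
            "p_important_benefit_pct": round(100 * self.p_important_benefit),
            "p_important_harm_pct": round(100 * self.p_important_harm),
            "p_no_important_difference_pct": round(100 * self.p_no_important_difference),
            "n_analysed": self.n_analysed,
        }


def fit_primary(
    ds: TrialDataset,
    prior: PriorSpec | None = None,
    *,
    n_chains: int = 4,
    n_iterations: int = 2500,
    warmup: int | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the site-random-intercept logistic model on complete cases.

    Records with a missing 60-day outcome are excluded and counted in the
    returned metadata.  Datasets with no deaths or all deaths warn about
    separation but still return draws (the prior regularises).
    """
    prior = prior or mortality_prior_family()["sceptical"]
    complete = ds.complete_outcome()
    n_excluded = len(ds) - len(complete)
    y = complete.df["death60"]
    if len(complete) and (y.sum() == 0 or y.sum() == len(y)):
        warnings.warn(
            "outcome is constant (complete separation); estimates are prior-driven",
            stacklevel=2,
        )
    model = ModelSpec(outcome="mortality", treatment_prior=prior)
    draws = sample(model, complete, n_chains=n_chains, n_iterations=n_iterations,
                   warmup=warmup, seed=seed)
    draws.meta["n_excluded_outcome"] = n_excluded
    return draws


def arm_risks(draws: PosteriorDraws, reference_site: str | None = None):
    """Per-draw (p_usual, p_high) death risks at the reference site.

    ``p_usual = expit(eta_ref)`` and ``p_high = expit(eta_ref + beta)``
    where ``eta_ref`` is the reference site's usual-arm linear predictor
    (covariate terms, when present, are zero at their centring point).
    """
    alpha = draws.stacked("alpha")
    beta = draws.stacked("beta")
    if "z" in draws.draws:
        labels = draws.meta["site_labels"]
        ref = reference_site if reference_site is not None else draws.meta["reference_site"]
        if ref not in labels:
            raise ValueError(f"unknown reference site {ref!r}")
        idx = labels.index(ref)
        eta_ref = alpha + draws.stacked("tau") * draws.stacked("z")[:, idx]
    else:
        if reference_site is not None:
            raise ValueError("model has no site term; reference site not applicable")
        eta_ref = alpha
    return expit(eta_ref), expit(eta_ref + beta)


def effect_summaries(
    arm_risk_draws: tuple[np.ndarray, np.ndarray],
    mcid: float = DEFAULT_MCID,
    n_analysed: int | None = None,
) -> EffectSummary:
    """Convert per-draw arm risks into effect scales and threshold
    probabilities.

    Threshold conventions: any harm is the fraction of draws with RD > 0
    (strict), important harm RD >= mcid, important benefit RD <= -mcid,
    and no important difference the strict interval in between, so the
    three-way partition sums to one by draw counting.
    """
    if mcid <= 0:
        raise ValueError("mcid must be positive (percentage points)")
    p_usual, p_high = (np.asarray(a, dtype=float) for a in arm_risk_draws)
    rd = 100.0 * (p_high - p_usual)
    ok = p_usual > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} draws with zero usual-arm risk excluded from RR",
            stacklevel=2,
        )
    rr = p_high[ok] / p_usual[ok]
    odds_ok = (p_usual < 1) & (p_high < 1) & ok
    or_ = (p_high[odds_ok] / (1 - p_high[odds_ok])) / (p_usual[odds_ok] / (1 - p_usual[odds_ok]))
    n = len(rd)
    return EffectSummary(
        risk_high=_interval(p_high),
        risk_usual=_interval(p_usual),
        rr=_interval(rr),
        rd=_interval(rd),
        or_=_interval(or_),
        p_any_harm=float((rd > 0).sum() / n),
        p_any_benefit=float((rd < 0).sum() / n),
        p_important_harm=float((rd >= mcid).sum() / n),
        p_important_benefit=float((rd <= -mcid).sum() / n),
        p_no_important_difference=float(((rd > -mcid) & (rd < mcid)).sum() / n),
        mcid=mcid,
        n_analysed=n_analysed,
    )


def run_prior_family(
    ds: TrialDataset,
    family: dict[str, PriorSpec] | None = None,
    mcid: float = DEFAULT_MCID,
    **sampler_kwargs,
) -> dict[str, EffectSummary]:
    """Fit one primary model per prior stance on identical data.

    All stances share the same sampler seed so differences between the
    returned summaries reflect only the priors.
    """
    family = family or mortality_prior_family()
    out = {}
    for stance, prior in family.items():
        draws = fit_primary(ds, prior, **sampler_kwargs)
        out[stance] = effect_summaries(
            arm_risks(draws), mcid=mcid, n_analysed=draws.meta["n_analysed"]
        )
    return out
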