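"""Synthetic trial cohorts and summary-based reconstruction.

The patient-level data of the trial this package re-analyses are not
publicly deposited, so every analysis here runs on one of two stand-ins:

* :func:`generate_cohort` — a fully synthetic cohort with known ground
  truth: stratified 1:1 randomisation within sites, 60-day mortality drawn
  from a hierarchical logistic model, and in-hospital discharge/death
  times from constant cause-specific hazards truncated at day 60.
* :func:`reconstruct_from_summaries` — an approximate cohort rebuilt from
  the printed arm sizes and arm-level mortality point estimates, with
  deaths assigned uniformly at random across each arm.

Both produce a :class:`TrialDataset`, the common input to every model
stage, and can be round-tripped through a plain CSV.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "TrialDataset",
    "GeneratorConfig",
    "ArmSummary",
    "CSV_COLUMNS",
    "generate_cohort",
    "reconstruct_from_summaries",
    "inject_missingness",
    "read_cohort_csv",
    "write_cohort_csv",
    "site_size_plan",
    "expected_death_rate",
    "discharge_cif",
]

CSV_COLUMNS = [
    "patient_id",
    "site_id",
    "arm",
    "death60",
    "t_discharge",
    "discharge_event",
    "died_in_hospital",
    "sofa",
    "creatinine",
    "bmi",
    "aki",
]

FOLLOW_UP_DAYS = 60.0

# Covariate generation constants (documented in docs/methods.md):
# SOFA discretised around mean 9; creatinine log-normal(ln 90, 0.5) umol/L;
# BMI log-normal(ln 33, 0.25) kg/m^2; AKI flagged when creatinine exceeds
# 1.5x an assumed 80 umol/L baseline (KDIGO stage >= 1 is a 1.5x rise).
SOFA_MEAN, SOFA_SD = 9.0, 3.5
CREATININE_LOG_MEAN, CREATININE_LOG_SD = float(np.log(90.0)), 0.5
BMI_LOG_MEAN, BMI_LOG_SD = float(np.log(33.0)), 0.25
AKI_CREATININE_THRESHOLD = 1.5 * 80.0


class ConfigError(ValueError):
    """Raised for impossible generator / reconstruction configurations."""


@dataclass
class TrialDataset:
    """Patient-level trial records backed by a pandas DataFrame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("site_id", "arm") if c not in self.df.columns]
        if missing:
            raise ValueError(f"mandatory columns absent: {missing}")
        arms = set(pd.unique(self.df["arm"].dropna()))
        if not arms <= {0, 1}:
            raise ValueError(f"arm must be binary 0/1, found values {sorted(arms)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def site_sizes(self) -> pd.Series:
        return self.df["site_id"].value_counts()

    @property
    def reference_site(self) -> str:
        """Largest site; ties broken by the lowest site label."""
        counts = self.site_sizes
        top = counts[counts == counts.max()].index
        return sorted(top)[0]

    @property
    def n_missing_outcome(self) -> int:
        return int(self.df["death60"].isna().sum())

    def complete_outcome(self) -> "TrialDataset":
        return TrialDataset(self.df[self.df["death60"].notna()].reset_index(drop=True))

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy())


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for the synthetic cohort generator.

    Defaults emulate the re-analysed trial: 645 vs 656 participants across
    85 sites with one dominant reference site, a usual-arm 60-day mortality
    near 32%, a small harmful treatment log-OR, and positive
    treatment-by-creatinine / treatment-by-SOFA interactions.
    """

    n_per_arm: tuple[int, int] = (645, 656)
    n_sites: int = 85
    largest_site_size: int = 120
    site_size_decay: float = 0.97
    site_sd: float = 0.5  # tau_true, log-odds units
    beta_true: float = 0.103  # treatment log-OR (~OR 1.11)
    alpha_true: float = -0.745  # reference-site usual-arm log-odds (~32%)
    # covariate main effects (log-odds per unit of the centred covariate)
    main_log2_creatinine: float = 0.25
    main_sofa: float = 0.15
    main_bmi: float = 0.0
    # treatment x covariate interaction coefficients (log-odds per unit)
    interaction_log2_creatinine: float = 0.131  # ~OR 1.14 per doubling
    interaction_sofa: float = 0.039  # ~OR 1.04 per point
    interaction_bmi: float = -0.005
    # cause-specific hazards, events/day, (usual, high)
    discharge_hazard: tuple[float, float] = (0.025, 0.0228)
    death_hazard: tuple[float, float] = (0.05, 0.05)
    n_missing_outcome: int = 0
    n_missing_creatinine: int = 0
    seed: int = 0

    def validate(self) -> None:
        n = sum(self.n_per_arm)
        if min(self.n_per_arm) < 0 or self.n_sites < 1:
            raise ConfigError("counts must be non-negative and n_sites >= 1")
        if n == 0:
            raise ConfigError("empty cohort requested")
        if self.largest_site_size > n:
            raise ConfigError("largest site exceeds cohort size")
        if not (0 < self.site_size_decay <= 1):
            raise ConfigError("site_size_decay must lie in (0, 1]")
        if self.site_sd < 0:
            raise ConfigError("site_sd must be non-negative")
        if min(self.discharge_hazard) < 0 or min(self.death_hazard) < 0:
            raise ConfigError("hazards must be non-negative")
        if max(self.discharge_hazard) <= 0:
            raise ConfigError("discharge hazards must not both be zero")
        if self.n_missing_outcome > n or self.n_missing_creatinine > n:
            raise ConfigError("more missing records requested than records")

    def to_yaml(self) -> str:
        data = asdict(self)
        data["n_per_arm"] = list(self.n_per_arm)
        data["discharge_hazard"] = list(self.discharge_hazard)
        data["death_hazard"] = list(self.death_hazard)
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        data = yaml.safe_load(text)
        if "seed" not in data:
            raise ConfigError("generator config must specify a seed")
        for key in ("n_per_arm", "discharge_hazard", "death_hazard"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class ArmSummary:
    """Arm sizes and arm-level event proportions printed in a results table."""

    n_high: int
    n_usual: int
    risk_high: float
    risk_low: float

    def __post_init__(self) -> None:
        if not (0 <= self.risk_high <= 1 and 0 <= self.risk_low <= 1):
            raise ConfigError("risks must lie in [0, 1]")
        if self.n_high < 0 or self.n_usual < 0:
            raise ConfigError("arm sizes must be non-negative")


def site_size_plan(
    total: int,
    n_sites: int,
    largest_site_size: int = 120,
    decay: float = 0.97,
) -> np.ndarray:
    """Deterministic skewed site-size plan.

    The first (reference) site gets ``largest_site_size`` patients; the
    remainder is split over the other sites proportionally to a geometric
    decay, allocated by largest remainder, every site getting at least one
    patient.  With a single site the whole cohort is the reference site.
    """
    if n_sites < 1:
        raise ConfigError("need at least one site")
    if n_sites == 1:
        return np.array([total])
    if largest_site_size >= total:
        raise ConfigError("largest site must leave room for the other sites")
    rest = total - largest_site_size
    m = n_sites - 1
    if rest < m:
        raise ConfigError("not enough patients to populate every site")
    weights = decay ** np.arange(m)
    ideal = rest * weights / weights.sum()
    sizes = np.floor(ideal).astype(int)
    # largest remainder, ties broken by site order
    remainder = ideal - sizes
    short = rest - sizes.sum()
    order = np.argsort(-remainder, kind="stable")
    sizes[order[:short]] += 1
    # guarantee occupancy and a unique largest site
    for i in np.flatnonzero(sizes == 0):
        donor = int(np.argmax(sizes))
        sizes[donor] -= 1
        sizes[i] += 1
    plan = np.concatenate([[largest_site_size], sizes])
    if plan[1:].max() >= largest_site_size:
        raise ConfigError("site-size plan does not yield a unique largest site")
    return plan


def _site_labels(n_sites: int) -> list[str]:
    width = max(3, len(str(n_sites)))
    return [f"site_{i + 1:0{width}d}" for i in range(n_sites)]


def _allocate_arms(sizes: np.ndarray, n_high: int, n_usual: int) -> list[np.ndarray]:
    """Within-site 1:1 allocation meeting the exact arm totals.

    Each site gets floor(size/2) patients per arm; the leftover patient of
    each odd-sized site goes to whichever arm still needs more, taking
    sites in plan order (deterministic).
    """
    total = int(sizes.sum())
    if n_high + n_usual != total:
        raise ConfigError("arm totals inconsistent with site plan")
    base_high = sizes // 2
    odd = np.flatnonzero(sizes % 2 == 1)
    need_high = n_high - int(base_high.sum())
    if not 0 <= need_high <= len(odd):
        raise ConfigError("cannot balance arms within sites for these totals")
    high_per_site = base_high.copy()
    high_per_site[odd[:need_high]] += 1
    out = []
    for size, nh in zip(sizes, high_per_site):
        arms = np.zeros(int(size), dtype=int)
        arms[: int(nh)] = 1
        out.append(arms)
    return out


def _draw_covariates(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    sofa = np.clip(np.round(rng.normal(SOFA_MEAN, SOFA_SD, n)), 0, 24).astype(int)
    creatinine = rng.lognormal(CREATININE_LOG_MEAN, CREATININE_LOG_SD, n)
    bmi = rng.lognormal(BMI_LOG_MEAN, BMI_LOG_SD, n)
    aki = (creatinine > AKI_CREATININE_THRESHOLD).astype(int)
    return {"sofa": sofa, "creatinine": creatinine, "bmi": bmi, "aki": aki}


def _death_logits(
    config: GeneratorConfig,
    arm: np.ndarray,
    site_effects_per_row: np.ndarray,
    cov: dict[str, np.ndarray],
) -> np.ndarray:
    """Linear predictor of 60-day death; covariates centred at their
    generative reference points so alpha_true keeps its interpretation."""
    c_crea = np.log2(cov["creatinine"]) - np.log2(90.0)
    c_sofa = cov["sofa"] - SOFA_MEAN
    c_bmi = cov["bmi"] - 30.0
    eta = (
        config.alpha_true
        + site_effects_per_row
        + config.beta_true * arm
        + config.main_log2_creatinine * c_crea
        + config.main_sofa * c_sofa
        + config.main_bmi * c_bmi
        + arm * config.interaction_log2_creatinine * c_crea
        + arm * config.interaction_sofa * c_sofa
        + arm * config.interaction_bmi * c_bmi
    )
    return eta


def _truncated_exponential(rng: np.random.Generator, rate: float, upper: float, n: int) -> np.ndarray:
    u = rng.random(n)
    return -np.log1p(-u * (1 - np.exp(-rate * upper))) / rate


def generate_cohort(config: GeneratorConfig) -> TrialDataset:
    """Generate a fully synthetic cohort with known ground truth.

    60-day death is Bernoulli under the hierarchical logistic model of
    :func:`_death_logits`; the hospital trajectory is then drawn
    conditionally: deaths get an in-hospital death time from a truncated
    exponential, survivors a discharge time from the arm's discharge
    hazard (remaining in hospital at day 60 if it exceeds follow-up).
    A zero death hazard for an arm switches deaths off in that arm.
    Reproducible for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_high, n_usual = config.n_per_arm
    total = n_high + n_usual
    sizes = site_size_plan(
        total, config.n_sites, config.largest_site_size, config.site_size_decay
    )
    labels = _site_labels(config.n_sites)
    arms_per_site = _allocate_arms(sizes, n_high, n_usual)

    site_id = np.repeat(labels, sizes)
    site_idx = np.repeat(np.arange(config.n_sites), sizes)
    arm = np.concatenate(arms_per_site)

    site_effects = rng.normal(0.0, config.site_sd, config.n_sites)
    site_effects[0] = 0.0  # reference site anchors alpha_true
    cov = _draw_covariates(rng, total)

    eta = _death_logits(config, arm, site_effects[site_idx], cov)
    p_death = expit(eta)
    death_hazard = np.asarray(config.death_hazard, dtype=float)[arm]
    p_death = np.where(death_hazard > 0, p_death, 0.0)
    death60 = (rng.random(total) < p_death).astype(float)

    discharge_hazard = np.asarray(config.discharge_hazard, dtype=float)[arm]
    t = np.full(total, FOLLOW_UP_DAYS)
    discharge_event = np.zeros(total, dtype=int)
    died = death60 == 1
    if died.any():
        rates = death_hazard[died]
        u = rng.random(int(died.sum()))
        t[died] = -np.log1p(-u * (1 - np.exp(-rates * FOLLOW_UP_DAYS))) / rates
    alive = ~died
    t_d = rng.exponential(1.0, total) / discharge_hazard
    discharged = alive & (t_d <= FOLLOW_UP_DAYS)
    t[discharged] = t_d[discharged]
    discharge_event[discharged] = 1

    df = pd.DataFrame(
        {
            "patient_id": [f"p{i + 1:05d}" for i in range(total)],
            "site_id": site_id,
            "arm": arm,
            "death60": death60,
            "t_discharge": t,
            "discharge_event": discharge_event,
            "died_in_hospital": died.astype(int),
            "sofa": cov["sofa"],
            "creatinine": cov["creatinine"],
            "bmi": cov["bmi"],
            "aki": cov["aki"],
        }
    )
    ds = TrialDataset(df)
    if config.n_missing_outcome or config.n_missing_creatinine:
        ds = inject_missingness(
            ds,
            config.n_missing_outcome,
            config.n_missing_creatinine,
            seed=rng.integers(2**31),
        )
    return ds


def expected_death_rate(config: GeneratorConfig, ds: TrialDataset) -> float:
    """Closed-form death rate of the generator conditional on the realised
    covariates and allocation: the mean of expit(eta) over the cohort.

    Valid only when the cohort's sites were generated with zero site SD or
    when averaging over site effects is not required (site_sd = 0).
    """
    if config.site_sd != 0:
        raise ValueError("closed form requires site_sd = 0")
    df = ds.df
    cov = {
        "sofa": df["sofa"].to_numpy(),
        "creatinine": df["creatinine"].to_numpy(),
        "bmi": df["bmi"].to_numpy(),
    }
    eta = _death_logits(config, df["arm"].to_numpy(), 0.0, cov)
    return float(expit(eta).mean())


def discharge_cif(config: GeneratorConfig, ds: TrialDataset, arm: int, t: np.ndarray) -> np.ndarray:
    """Generator closed-form cumulative incidence of discharge alive for one
    arm at times ``t``: (1 - E[p_death]) * (1 - exp(-lambda_d t))."""
    if config.site_sd != 0:
        raise ValueError("closed form requires site_sd = 0")
    df = ds.df[ds.df["arm"] == arm]
    cov = {
        "sofa": df["sofa"].to_numpy(),
        "creatinine": df["creatinine"].to_numpy(),
        "bmi": df["bmi"].to_numpy(),
    }
    eta = _death_logits(config, np.full(len(df), arm), 0.0, cov)
    p_death = float(expit(eta).mean()) if config.death_hazard[arm] > 0 else 0.0
    lam = config.discharge_hazard[arm]
    return (1.0 - p_death) * (1.0 - np.exp(-lam * np.asarray(t, dtype=float)))


def reconstruct_from_summaries(
    summary: ArmSummary,
    n_sites: int = 85,
    largest_site_size: int = 120,
    seed: int = 0,
    site_size_decay: float = 0.97,
) -> TrialDataset:
    """Rebuild an approximate patient-level cohort from arm-level summaries.

    Per-arm death counts are the nearest integers to n * risk (ties to
    even); deaths are assigned uniformly at random (seeded) across the
    arm's patients, so any apparent between-site variation is purely
    sampling noise.  Site sizes follow :func:`site_size_plan`; covariates
    and hospital trajectories are filled in from the documented default
    distributions so downstream analyses always have complete columns.
    """
    total = summary.n_high + summary.n_usual
    if n_sites < 1:
        raise ConfigError("need at least one site")
    rng = np.random.default_rng(seed)
    sizes = site_size_plan(total, n_sites, largest_site_size, site_size_decay)
    labels = _site_labels(n_sites)
    arms_per_site = _allocate_arms(sizes, summary.n_high, summary.n_usual)
    site_id = np.repeat(labels, sizes)
    arm = np.concatenate(arms_per_site)

    deaths_high = int(np.round(summary.n_high * summary.risk_high))
    deaths_usual = int(np.round(summary.n_usual * summary.risk_low))
    death60 = np.zeros(total)
    for a, k in ((1, deaths_high), (0, deaths_usual)):
        idx = np.flatnonzero(arm == a)
        chosen = rng.choice(idx, size=k, replace=False)
        death60[chosen] = 1.0

    cov = _draw_covariates(rng, total)
    # hospital trajectories from the default hazard plan, conditioned on death60
    cfg = GeneratorConfig()
    death_hazard = np.asarray(cfg.death_hazard, dtype=float)[arm]
    discharge_hazard = np.asarray(cfg.discharge_hazard, dtype=float)[arm]
    t = np.full(total, FOLLOW_UP_DAYS)
    discharge_event = np.zeros(total, dtype=int)
    died = death60 == 1
    if died.any():
        rates = death_hazard[died]
        u = rng.random(int(died.sum()))
        t[died] = -np.log1p(-u * (1 - np.exp(-rates * FOLLOW_UP_DAYS))) / rates
    t_d = rng.exponential(1.0, total) / discharge_hazard
    discharged = (~died) & (t_d <= FOLLOW_UP_DAYS)
    t[discharged] = t_d[discharged]
    discharge_event[discharged] = 1

    df = pd.DataFrame(
        {
            "patient_id": [f"p{i + 1:05d}" for i in range(total)],
            "site_id": site_id,
            "arm": arm,
            "death60": death60,
            "t_discharge": t,
            "discharge_event": discharge_event,
            "died_in_hospital": died.astype(int),
            "sofa": cov["sofa"],
            "creatinine": cov["creatinine"],
            "bmi": cov["bmi"],
            "aki": cov["aki"],
        }
    )
    return TrialDataset(df)


def inject_missingness(
    ds: TrialDataset,
    n_missing_outcome: int,
    n_missing_creatinine: int,
    seed: int = 0,
) -> TrialDataset:
    """Set exactly the requested numbers of death60 / creatinine values
    missing, chosen uniformly at random (seeded); all other fields are
    untouched."""
    n = len(ds)
    if n_missing_outcome < 0 or n_missing_creatinine < 0:
        raise ConfigError("missing counts must be non-negative")
    if n_missing_outcome > n or n_missing_creatinine > n:
        raise ConfigError("more missing records requested than records")
    out = ds.copy()
    rng = np.random.default_rng(seed)
    if n_missing_outcome:
        idx = rng.choice(n, size=n_missing_outcome, replace=False)
        out.df.loc[out.df.index[idx], "death60"] = np.nan
    if n_missing_creatinine:
        idx = rng.choice(n, size=n_missing_creatinine, replace=False)
        out.df.loc[out.df.index[idx], "creatinine"] = np.nan
    return out


def write_cohort_csv(ds: TrialDataset, path) -> None:
    """Write the patient-level CSV (UTF-8, empty string = missing).

    Output is byte-deterministic for a given dataset: floats are written
    with :func:`repr` precision via pandas' default formatter.
    """
    df = ds.df.reindex(columns=CSV_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path) -> TrialDataset:
    """Read the patient-level CSV; empty cells denote missing values.

    Unknown columns raise a warning and are kept; absent mandatory columns
    (site_id, arm) or a non-binary arm fail hard.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "site_id": str})
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        warnings.warn(f"unknown columns in cohort CSV: {unknown}", stacklevel=2)
    for col in ("site_id", "arm"):
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} absent from cohort CSV")
    for col in ("arm", "discharge_event", "died_in_hospital", "sofa", "aki"):
        if col in df.columns and df[col].notna().all():
            df[col] = df[col].astype(int)
    return TrialDataset(df)
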