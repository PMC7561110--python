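"""Synthetic primary-care prescription data with a known hierarchical truth.

The generator emulates a CPRD-like layout — patients registered with
prescribers, prescribers nested in practices, practices nested in regions —
and draws each patient's latent propensity of becoming a long-term opioid
user from the same three-level random-intercept logistic model the inference
stage assumes:

    logit P(long-term) = intercept + x·beta + u_region + u_practice + u_prescriber

with mean-zero normal random intercepts at each level.  Prescription refill
patterns are then emitted conditional on the latent Bernoulli long-term
indicator, so that the downstream phenotype (≥3 scripts in a 90-day window,
or one script lasting ≥90 days, in days 31–365) recovers the latent status
with probability ≈ 1.  This makes the whole pipeline testable end-to-end:
variance components and covariate log-odds-ratios estimated downstream can
be compared against the configured truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import ALL_CLASSED_OPIOIDS

__all__ = [
    "SimConfig",
    "RefillModel",
    "GroundTruth",
    "Population",
    "SimulatedStudy",
    "ConfigurationError",
    "ConsistencyError",
    "generate_population",
    "generate_prescriptions",
    "generate_condition_flags",
    "simulate_study",
    "write_study",
    "KNOWN_CONDITIONS",
]


class ConfigurationError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


#: Condition / baseline-drug flags the generator and cohort stage understand.
KNOWN_CONDITIONS = (
    "alcohol_dependency",
    "substance_use",
    "depression",
    "suicide_self_harm",
    "fibromyalgia",
    "back_pain",
    "migraine",
    "rheumatological",
    "diabetes",
    "major_surgery",
    "benzodiazepine",
    "gabapentinoid",
    "psychotropic",
    "cancer",
    "non_melanoma_skin_cancer",
)

#: Cancer-type flags get a 10-year placement window; everything else 1 year.
_LONG_WINDOW_CONDITIONS = {"cancer", "non_melanoma_skin_cancer"}

#: Drug flags may legitimately fall on the index date itself.
_DRUG_FLAGS = {"benzodiazepine", "gabapentinoid", "psychotropic"}

# representative product per ingredient: (unit_strength, daily_count, route)
_PRODUCTS = {
    "codeine": (30.0, 4, "oral"),
    "dihydrocodeine": (30.0, 4, "oral"),
    "meptazinol": (200.0, 3, "oral"),
    "tramadol": (50.0, 4, "oral"),
    "tapentadol": (50.0, 2, "oral"),
    "morphine": (10.0, 3, "oral"),
    "oxycodone": (10.0, 2, "oral"),
    "hydromorphone": (2.0, 2, "oral"),
    "diamorphine": (10.0, 2, "oral"),
    "pethidine": (50.0, 3, "oral"),
    "buprenorphine": (10.0, 1, "transdermal"),  # µg/hour patch
    "fentanyl": (25.0, 1, "transdermal"),  # µg/hour patch
    "methadone": (5.0, 3, "oral"),
}
_PATCH_WEAR = {"fentanyl": 3, "buprenorphine": 7}


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _default_beta() -> dict:
    # mirrors the largest adjusted effects reported for this outcome
    return {
        "gabapentinoid": math.log(2.52),
        "fibromyalgia": math.log(1.81),
        "substance_use": math.log(1.72),
        "depression": math.log(1.30),
    }


def _default_prevalences() -> dict:
    return {
        "gabapentinoid": 0.10,
        "fibromyalgia": 0.02,
        "substance_use": 0.03,
        "depression": 0.15,
        "benzodiazepine": 0.08,
        "psychotropic": 0.12,
        "alcohol_dependency": 0.03,
        "suicide_self_harm": 0.02,
        "back_pain": 0.20,
        "migraine": 0.05,
        "rheumatological": 0.03,
        "diabetes": 0.08,
        "major_surgery": 0.05,
        "cancer": 0.02,
        "non_melanoma_skin_cancer": 0.01,
    }


def _default_drug_mix() -> dict:
    # codeine-dominated, as in UK primary care
    return {
        "codeine": 0.55,
        "dihydrocodeine": 0.12,
        "tramadol": 0.16,
        "morphine": 0.06,
        "oxycodone": 0.04,
        "buprenorphine": 0.02,
        "fentanyl": 0.02,
        "tapentadol": 0.01,
        "meptazinol": 0.005,
        "diamorphine": 0.005,
        "hydromorphone": 0.005,
        "pethidine": 0.005,
    }


@dataclass
class RefillModel:
    """Refill behaviour conditional on the latent long-term indicator.

    Long-term patients receive roughly monthly scripts of ``supply_days``
    supply for about a year (``persist_two_year_rate`` of them continue into
    the second year); short-term patients receive one or two scripts confined
    to the first 30 days, and with probability ``sparse_later_rate`` up to
    two widely spaced later scripts that can satisfy neither long-term rule.
    """

    long_term_scripts_min: int = 10
    long_term_scripts_max: int = 14
    refill_interval_days: int = 28
    jitter_days: int = 3
    supply_days: int = 28
    persist_two_year_rate: float = 0.4
    sparse_later_rate: float = 0.3


@dataclass
class SimConfig:
    """Full data-generating configuration for one synthetic study."""

    seed: int = 0
    n_regions: int = 3
    practices_per_region: int = 4
    prescribers_per_practice: int = 3
    patients_per_prescriber: int = 25
    sigma2_region: float = 0.01
    sigma2_practice: float = 0.05
    sigma2_prescriber: float = 0.25
    intercept: float = field(default_factory=lambda: _logit(0.146))
    beta: dict = field(default_factory=_default_beta)
    covariate_prevalences: dict = field(default_factory=_default_prevalences)
    drug_mix: dict = field(default_factory=_default_drug_mix)
    duration_days_distribution: dict = field(default_factory=lambda: {"kind": "fixed", "days": 28})
    refill_model: RefillModel = field(default_factory=RefillModel)
    calendar_span: tuple = (2006, 2017)
    covariate_correlation: float = 0.0  # shared-latent-factor loading, [0, 1)
    corruption_rate: float = 0.05
    methadone_rate: float = 0.01
    prior_use_rate: float = 0.05
    remote_history_rate: float = 0.05
    under18_rate: float = 0.02
    censor_rate: float = 0.05

    def __post_init__(self):
        if isinstance(self.refill_model, dict):
            self.refill_model = RefillModel(**self.refill_model)
        self.calendar_span = tuple(self.calendar_span)
        counts = {
            "n_regions": self.n_regions,
            "practices_per_region": self.practices_per_region,
            "prescribers_per_practice": self.prescribers_per_practice,
            "patients_per_prescriber": self.patients_per_prescriber,
        }
        for name, v in counts.items():
            if int(v) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        for name in ("sigma2_region", "sigma2_practice", "sigma2_prescriber"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name, p in {
            **self.covariate_prevalences,
            "corruption_rate": self.corruption_rate,
            "methadone_rate": self.methadone_rate,
            "prior_use_rate": self.prior_use_rate,
            "remote_history_rate": self.remote_history_rate,
            "under18_rate": self.under18_rate,
            "censor_rate": self.censor_rate,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {name}={p} outside [0, 1]")
        for cond in self.covariate_prevalences:
            if cond not in KNOWN_CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r} in covariate_prevalences")
        for cov in self.beta:
            if cov not in KNOWN_CONDITIONS:
                raise ConfigurationError(f"beta refers to unknown covariate {cov!r}")
        if not 0.0 <= self.covariate_correlation < 1.0:
            raise ConfigurationError("covariate_correlation must lie in [0, 1)")
        mix_total = sum(self.drug_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ConfigurationError(f"drug_mix probabilities sum to {mix_total}, not 1")
        for ing in self.drug_mix:
            if ing not in ALL_CLASSED_OPIOIDS:
                raise ConfigurationError(f"drug_mix ingredient {ing!r} is not a classed opioid")
        if self.calendar_span[1] < self.calendar_span[0]:
            raise ConfigurationError("calendar_span must be (first_year, last_year) with first ≤ last")

    @property
    def n_practices(self) -> int:
        return self.n_regions * self.practices_per_region

    @property
    def n_prescribers(self) -> int:
        return self.n_practices * self.prescribers_per_practice

    @property
    def n_patients(self) -> int:
        return self.n_prescribers * self.patients_per_prescriber

    @property
    def study_start(self) -> date:
        return date(self.calendar_span[0], 1, 1)

    @property
    def study_end(self) -> date:
        return date(self.calendar_span[1], 12, 31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calendar_span"] = list(self.calendar_span)
        return d


@dataclass
class GroundTruth:
    """The latent state of a simulated study (the recovery-test oracle)."""

    u_region: dict
    u_practice: dict
    u_prescriber: dict
    patients: pd.DataFrame  # per-patient covariates, linkage, p, y, index date
    population_fingerprint: str = ""  # sha256 of the patient table it belongs to

    def to_json_dict(self) -> dict:
        pats = self.patients.copy()
        pats["index_date"] = pats["index_date"].astype(str)
        return {
            "u_region": self.u_region,
            "u_practice": self.u_practice,
            "u_prescriber": self.u_prescriber,
            "patients": pats.to_dict(orient="list"),
        }


@dataclass
class Population:
    region: pd.DataFrame
    practice: pd.DataFrame
    staff: pd.DataFrame
    patient: pd.DataFrame


@dataclass
class SimulatedStudy:
    config: SimConfig
    population: Population
    ground_truth: GroundTruth
    therapy: pd.DataFrame
    conditions: pd.DataFrame
    denominators: pd.DataFrame


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _fingerprint(df: pd.DataFrame) -> str:
    import hashlib

    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _check_consistent(population: Population, ground_truth: GroundTruth):
    if ground_truth.population_fingerprint != _fingerprint(population.patient):
        raise ConsistencyError("population and ground truth do not belong to the same generation run")


def generate_population(config: SimConfig) -> tuple[Population, GroundTruth]:
    """Draw the nested population and every latent quantity downstream of it."""
    rng = _rng(config, 1)
    span_days = (config.study_end - config.study_start).days

    region_ids = [f"R{i + 1:02d}" for i in range(config.n_regions)]
    practice_ids = [f"PR{i + 1:04d}" for i in range(config.n_practices)]
    staff_ids = [f"ST{i + 1:05d}" for i in range(config.n_prescribers)]

    u_region = rng.normal(0.0, math.sqrt(config.sigma2_region), config.n_regions)
    u_practice = rng.normal(0.0, math.sqrt(config.sigma2_practice), config.n_practices)
    u_prescriber = rng.normal(0.0, math.sqrt(config.sigma2_prescriber), config.n_prescribers)

    region_tbl = pd.DataFrame({"region_id": region_ids, "region_name": [f"Region {i + 1}" for i in range(config.n_regions)]})
    practice_region = np.repeat(np.arange(config.n_regions), config.practices_per_region)
    practice_tbl = pd.DataFrame(
        {"practice_id": practice_ids, "region_id": [region_ids[r] for r in practice_region]}
    )
    staff_practice = np.repeat(np.arange(config.n_practices), config.prescribers_per_practice)
    staff_tbl = pd.DataFrame(
        {"staff_id": staff_ids, "practice_id": [practice_ids[p] for p in staff_practice]}
    )

    n = config.n_patients
    patient_ids = [f"PT{i + 1:07d}" for i in range(n)]
    pat_staff_idx = np.repeat(np.arange(config.n_prescribers), config.patients_per_prescriber)
    pat_practice_idx = staff_practice[pat_staff_idx]
    pat_region_idx = practice_region[pat_practice_idx]

    # ages: mostly adults; a small fraction under 18 exercises the age rule
    age = rng.integers(18, 91, n).astype(float)
    minor = rng.random(n) < config.under18_rate
    age[minor] = rng.integers(12, 18, n)[minor]
    sex = np.where(rng.random(n) < 0.57, "F", "M")
    ethnicity = rng.choice(
        ["white", "asian", "black", "mixed", "other", "missing"],
        size=n,
        p=[0.80, 0.05, 0.03, 0.01, 0.02, 0.09],
    )
    townsend = rng.choice(["1", "2", "3", "4", "5", "missing"], size=n, p=[0.19, 0.19, 0.19, 0.19, 0.16, 0.08])

    # covariate indicator draws at configured prevalences; with a positive
    # correlation a Gaussian copula with one shared factor induces
    # dependence while preserving every marginal prevalence
    from scipy.stats import norm

    cov_flags = {}
    c = config.covariate_correlation
    shared = rng.normal(0.0, 1.0, n) if c > 0 else np.zeros(n)
    for cond in KNOWN_CONDITIONS:
        p = config.covariate_prevalences.get(cond, 0.0)
        if c > 0:
            z = math.sqrt(c) * shared + math.sqrt(1.0 - c) * rng.normal(0.0, 1.0, n)
            cov_flags[cond] = (z < norm.ppf(p)).astype(int) if p > 0 else np.zeros(n, dtype=int)
        else:
            cov_flags[cond] = (rng.random(n) < p).astype(int)

    # index dates; special histories constrain the index so that earlier
    # scripts always fall before the study start (see module docstring)
    special = rng.random(n)
    prior_use = special < config.prior_use_rate
    remote = (special >= config.prior_use_rate) & (special < config.prior_use_rate + config.remote_history_rate)
    last_index_offset = max(span_days - 730, 1)
    index_offset = rng.integers(0, last_index_offset, n)
    prior_gap = np.zeros(n, dtype=int)
    g1 = rng.integers(400, 701, n)  # inside the 24-month washout -> excluded
    g2 = rng.integers(800, 1101, n)  # beyond the washout -> retained
    prior_gap[prior_use] = g1[prior_use]
    prior_gap[remote] = g2[remote]
    off1 = rng.integers(0, 1000000, n)
    index_offset[prior_use] = off1[prior_use] % np.maximum(g1[prior_use] - 390, 1)
    index_offset[remote] = off1[remote] % np.maximum(g2[remote] - 790, 1)
    index_dates = [config.study_start + timedelta(days=int(d)) for d in index_offset]

    methadone_user = rng.random(n) < config.methadone_rate

    # latent linear predictor and long-term indicator
    eta = np.full(n, config.intercept)
    for cov, b in config.beta.items():
        eta = eta + b * cov_flags[cov]
    eta = eta + u_region[pat_region_idx] + u_practice[pat_practice_idx] + u_prescriber[pat_staff_idx]
    p_long = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p_long).astype(int)

    # registration: starts well before index, ends at study end or censoring
    reg_start = [d - timedelta(days=int(k)) for d, k in zip(index_dates, rng.integers(1100, 3600, n))]
    censored = rng.random(n) < config.censor_rate
    censor_days = rng.integers(100, 701, n)
    reg_end = [
        min(config.study_end, d + timedelta(days=int(k))) if c else config.study_end
        for d, k, c in zip(index_dates, censor_days, censored)
    ]

    patient_tbl = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "staff_id": [staff_ids[i] for i in pat_staff_idx],
            "sex": sex,
            "age_at_index": age.astype(int),
            "birth_year": [d.year - int(a) for d, a in zip(index_dates, age)],
            "ethnicity": ethnicity,
            "townsend_quintile": townsend,
            "registration_start": [d.isoformat() for d in reg_start],
            "registration_end": [d.isoformat() for d in reg_end],
        }
    )

    truth_pat = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "staff_id": [staff_ids[i] for i in pat_staff_idx],
            "practice_id": [practice_ids[i] for i in pat_practice_idx],
            "region_id": [region_ids[i] for i in pat_region_idx],
            "index_date": index_dates,
            "age_at_index": age.astype(int),
            "p_long_term": p_long,
            "latent_long_term": y,
            "prior_use": prior_use.astype(int),
            "remote_history": remote.astype(int),
            "prior_gap_days": prior_gap,
            "methadone_user": methadone_user.astype(int),
            "censored": censored.astype(int),
            **{f"x_{c}": cov_flags[c] for c in KNOWN_CONDITIONS},
        }
    )

    truth = GroundTruth(
        u_region=dict(zip(region_ids, u_region.tolist())),
        u_practice=dict(zip(practice_ids, u_practice.tolist())),
        u_prescriber=dict(zip(staff_ids, u_prescriber.tolist())),
        patients=truth_pat,
        population_fingerprint=_fingerprint(patient_tbl),
    )
    pop = Population(region=region_tbl, practice=practice_tbl, staff=staff_tbl, patient=patient_tbl)
    return pop, truth


def _draw_duration(config: SimConfig, rng: np.random.Generator) -> int:
    spec = config.duration_days_distribution
    kind = spec.get("kind", "fixed")
    if kind == "fixed":
        return int(spec.get("days", 28))
    if kind == "uniform_int":
        return int(rng.integers(int(spec["low"]), int(spec["high"]) + 1))
    raise ConfigurationError(f"unknown duration distribution kind {kind!r}")


def _script_row(pid, staff_id, ingredient, day_offset, index_date, duration):
    strength, daily_count, route = _PRODUCTS[ingredient]
    if route == "transdermal":
        quantity = math.ceil(duration / _PATCH_WEAR[ingredient])
        daily = ""
    else:
        quantity = daily_count * duration
        daily = daily_count
    return {
        "patient_id": pid,
        "prescriber_id": staff_id,
        "ingredient": ingredient,
        "route": route,
        "unit_strength": strength,
        "quantity": quantity,
        "daily_count": daily,
        "issue_date": (index_date + timedelta(days=int(day_offset))).isoformat(),
    }


def generate_prescriptions(
    config: SimConfig, population: Population, ground_truth: GroundTruth
) -> pd.DataFrame:
    """Emit the therapy table conditional on each patient's latent status."""
    _check_consistent(population, ground_truth)
    rng = _rng(config, 2)
    rm = config.refill_model
    mix_ings = list(config.drug_mix)
    mix_p = np.array([config.drug_mix[i] for i in mix_ings])

    rows: list[dict] = []
    for pat in ground_truth.patients.itertuples(index=False):
        pid, staff_id, index_date = pat.patient_id, pat.staff_id, pat.index_date
        ingredient = mix_ings[rng.choice(len(mix_ings), p=mix_p)]
        duration = _draw_duration(config, rng)
        if pat.latent_long_term:
            n_scripts = int(rng.integers(rm.long_term_scripts_min, rm.long_term_scripts_max + 1))
            if rng.random() < rm.persist_two_year_rate:
                n_scripts = 2 * n_scripts
            day = 0
            for k in range(n_scripts):
                rows.append(_script_row(pid, staff_id, ingredient, day, index_date, duration))
                gap = rm.refill_interval_days + int(rng.integers(-rm.jitter_days, rm.jitter_days + 1))
                day += max(gap, 20)
        else:
            rows.append(_script_row(pid, staff_id, ingredient, 0, index_date, duration))
            if rng.random() < 0.4:  # second acute script, still inside the blanked month
                rows.append(_script_row(pid, staff_id, ingredient, int(rng.integers(10, 22)), index_date, duration))
            if rng.random() < rm.sparse_later_rate:
                # scripts too sparse (and too short) for either long-term rule
                day = int(rng.integers(100, 260))
                rows.append(_script_row(pid, staff_id, ingredient, day, index_date, duration))
                if rng.random() < 0.5:
                    rows.append(_script_row(pid, staff_id, ingredient, day + int(rng.integers(120, 300)), index_date, duration))
        if pat.prior_use or pat.remote_history:
            rows.append(_script_row(pid, staff_id, ingredient, -int(pat.prior_gap_days), index_date, duration))
        if pat.methadone_user:
            rows.append(_script_row(pid, staff_id, "methadone", 0, index_date, duration))

    therapy = pd.DataFrame(rows)

    # inject messy records to exercise the cleaning rules
    if config.corruption_rate > 0 and len(therapy):
        therapy["daily_count"] = therapy["daily_count"].astype(object)
        oral = (therapy["route"] == "oral").to_numpy()
        hit = (rng.random(len(therapy)) < config.corruption_rate) & oral
        kind = rng.random(len(therapy))
        blank_daily = hit & (kind < 0.6)
        zero_qty = hit & (kind >= 0.6)
        therapy.loc[blank_daily, "daily_count"] = ""
        therapy.loc[zero_qty, "quantity"] = 0
    return therapy.reset_index(drop=True)


def generate_condition_flags(
    config: SimConfig, population: Population, ground_truth: GroundTruth
) -> pd.DataFrame:
    """Condition-flag table (patient, condition, date) from the latent draws.

    Flags were drawn at the configured prevalences during population
    generation; here they are placed on dates inside the covariate lookback
    window relative to each patient's index date (10 years for cancer flags,
    1 year otherwise; baseline drug flags may fall on the index date itself).
    """
    _check_consistent(population, ground_truth)
    rng = _rng(config, 3)
    rows = []
    for pat in ground_truth.patients.itertuples(index=False):
        for cond in KNOWN_CONDITIONS:
            if not getattr(pat, f"x_{cond}"):
                continue
            if cond in _LONG_WINDOW_CONDITIONS:
                back = int(rng.integers(40, 3600))
            elif cond in _DRUG_FLAGS:
                back = int(rng.integers(0, 330))
            else:
                back = int(rng.integers(1, 360))
            rows.append(
                {
                    "patient_id": pat.patient_id,
                    "condition": cond,
                    "flag_date": (pat.index_date - timedelta(days=back)).isoformat(),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "condition", "flag_date"])


def _denominators(config: SimConfig, population: Population) -> pd.DataFrame:
    start = pd.to_datetime(population.patient["registration_start"])
    end = pd.to_datetime(population.patient["registration_end"])
    rows = []
    for year in range(config.calendar_span[0], config.calendar_span[1] + 1):
        y0, y1 = pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31)
        n = int(((start <= y1) & (end >= y0)).sum())
        rows.append({"year": year, "n_registered": n})
    return pd.DataFrame(rows)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run every generation stage under one config (fully seed-deterministic)."""
    population, truth = generate_population(config)
    therapy = generate_prescriptions(config, population, truth)
    conditions = generate_condition_flags(config, population, truth)
    denominators = _denominators(config, population)
    return SimulatedStudy(
        config=config,
        population=population,
        ground_truth=truth,
        therapy=therapy,
        conditions=conditions,
        denominators=denominators,
    )


def write_study(study: SimulatedStudy, out_dir) -> dict:
    """Write the study tables and ground-truth sidecar; return path map."""
    from .io import write_table  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "region": study.population.region,
        "practice": study.population.practice,
        "staff": study.population.staff,
        "patient": study.population.patient,
        "therapy": study.therapy,
        "conditions": study.conditions,
        "denominators": study.denominators,
    }
    for name, df in tables.items():
        paths[name] = write_table(df, out / f"{name}.csv", schema=name)
    gt_path = out / "ground_truth.json"
    tmp = gt_path.with_suffix(".json.tmp")
    payload = {"config": study.config.to_dict(), **study.ground_truth.to_json_dict()}
    tmp.write_text(json.dumps(payload, indent=1, sort_keys=True))
    tmp.replace(gt_path)
    paths["ground_truth"] = gt_path
    return paths
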