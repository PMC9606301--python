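"""Synthea-schema-compatible synthetic patient populations.

Generates multi-domain longitudinal EHR exports (patients, encounters,
conditions, observations, procedures, medications, immunizations,
allergies) with a planted logistic disease-risk structure: a handful of
risk-factor codes tilt each patient's probability of carrying the target
disease, every other event is nuisance noise drawn from a Zipf-weighted
code vocabulary.  The output is what the rest of the pipeline consumes,
so no external download is ever required.

The generator is NOT a re-implementation of the Synthea engine; it
emulates the *shape* of its CSV exports (coded, timestamped, per-domain
event tables) plus a controllable signal that a classifier can learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .vocab import build_vocabulary

DAYS_PER_YEAR = 365.25
_SECONDS_PER_YEAR = DAYS_PER_YEAR * 86400.0

DOMAIN_TABLES = (
    "patients",
    "encounters",
    "conditions",
    "observations",
    "procedures",
    "medications",
    "immunizations",
    "allergies",
)

#: event tables in their canonical tie-break order
EVENT_TABLES = ("conditions", "observations", "procedures", "medications", "immunizations", "allergies")


@dataclass(frozen=True)
class DiseaseSpec:
    """A target disease: its identifying codes and population prevalence."""

    name: str
    snomed_codes: tuple[str, ...]
    prevalence: float

    def __post_init__(self):
        codes = tuple(str(c) for c in self.snomed_codes)
        object.__setattr__(self, "snomed_codes", codes)
        if not codes:
            raise ValueError("disease needs at least one SNOMED code")
        if len(set(codes)) != len(codes):
            raise ValueError("disease codes must be unique")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")


LUNG_CANCER = DiseaseSpec("lung_cancer", ("162573006", "254637007", "424132000"), 0.037)
STROKE = DiseaseSpec("stroke", ("230690007",), 0.13)


# Risk-factor codes the generator knows how to plant as events.  Most are
# screening-style observations recorded for nearly every patient, with the
# *value* carrying the risk signal (exposed patients get the risky value):
# that way the codes rank high in patient-occurrence counts and survive
# occurrence-based variable selection, as screening variables do in real
# EHRs.  Entries: (name, domain, datatype, unit, risky value, benign value);
# a None benign value means the code is planted only in exposed patients
# (presence-only signal), which is also the fallback for unknown codes.
_RISK_FACTOR_CATALOG = {
    "72166-2": ("Tobacco smoking status", "observations", "categorical", "", "Current every day smoker", "Never smoker"),
    "19926-5": ("FEV1/FVC ratio", "observations", "numeric", "%", ("normal", 0.55, 0.05), ("normal", 0.82, 0.05)),
    "8480-6": ("Systolic blood pressure", "observations", "numeric", "mmHg", ("normal", 155.0, 10.0), ("normal", 118.0, 12.0)),
    "2339-0": ("Glucose", "observations", "numeric", "mg/dL", ("normal", 185.0, 30.0), ("normal", 95.0, 10.0)),
    "39156-5": ("Body mass index", "observations", "numeric", "kg/m2", ("normal", 34.0, 3.0), ("normal", 25.0, 3.0)),
    "8462-4": ("Diastolic blood pressure", "observations", "numeric", "mmHg", ("normal", 95.0, 8.0), ("normal", 76.0, 8.0)),
    "8663-7": ("Cigarettes smoked per day", "observations", "numeric", "/d", ("normal", 25.0, 8.0), ("normal", 1.0, 1.5)),
    "2085-9": ("HDL cholesterol", "observations", "numeric", "mg/dL", ("normal", 35.0, 8.0), ("normal", 55.0, 10.0)),
    "2571-8": ("Triglycerides", "observations", "numeric", "mg/dL", ("normal", 220.0, 40.0), ("normal", 120.0, 30.0)),
    "4548-4": ("Hemoglobin A1c", "observations", "numeric", "%", ("normal", 8.2, 1.0), ("normal", 5.4, 0.4)),
    "2160-0": ("Serum creatinine", "observations", "numeric", "mg/dL", ("normal", 1.6, 0.3), ("normal", 0.9, 0.15)),
    "2708-6": ("Oxygen saturation", "observations", "numeric", "%", ("normal", 91.0, 2.0), ("normal", 97.0, 1.5)),
    "8867-4": ("Heart rate", "observations", "numeric", "/min", ("normal", 95.0, 10.0), ("normal", 72.0, 8.0)),
    "9279-1": ("Respiratory rate", "observations", "numeric", "/min", ("normal", 22.0, 3.0), ("normal", 15.0, 2.0)),
    "8884-9": ("Heart rate rhythm", "observations", "categorical", "", "irregularly irregular", "regular"),
    "74013-4": ("Alcohol use status", "observations", "categorical", "", "heavy daily drinking", "none"),
    "8670-2": ("Family history of cancer", "observations", "categorical", "", "family history present", "no family history"),
    "55277-8": ("Physical activity level", "observations", "categorical", "", "sedentary", "active"),
    "63586-2": ("Occupational exposure", "observations", "categorical", "", "exposed", "none"),
    "13645005": ("Chronic obstructive pulmonary disease", "conditions", "categorical", "", "present", None),
    "185086009": ("Chronic obstructive bronchitis", "conditions", "categorical", "", "present", None),
    "59621000": ("Essential hypertension", "conditions", "categorical", "", "present", None),
    "53741008": ("Coronary heart disease", "conditions", "categorical", "", "present", None),
}

#: pseudo-feature handled at profile time, not as an event; the risk model
#: scores it as the indicator age >= 50
AGE_FEATURE = "age"


@dataclass(frozen=True)
class RiskModel:
    """Planted logistic risk structure.

    Case probability is ``expit(intercept + sum_j coef_j * x_j + eps)``
    with ``x_j`` the binary exposure to feature code j (for ``"age"``,
    the indicator age >= 50) and ``eps ~ N(0, noise_sd)``.  The working
    intercept is re-calibrated at generation time so the mean probability
    equals the configured prevalence.  ``noise_sd == 0`` switches to the
    deterministic regime: cases are exactly the patients above the
    (1 - prevalence) quantile of the linear score, which makes the
    classes a function of the planted features (separable by a tree).
    """

    feature_codes: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float = 0.0
    noise_sd: float = 0.8
    exposure_rates: tuple[float, ...] | None = None
    observe_rates: tuple[float, ...] | None = None
    #: exposure synergies (code, ..., code, log-odds added when ALL listed
    #: exposures are present); pairs model e.g. the smoking x age
    #: concentration of lung-cancer risk, triples the deeper conditional
    #: pathways (smoker over 50 with obstructive disease)
    interactions: tuple[tuple, ...] = ()

    def __post_init__(self):
        codes = tuple(str(c) for c in self.feature_codes)
        object.__setattr__(self, "feature_codes", codes)
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if not codes:
            raise ValueError("risk model needs at least one feature code")
        if len(codes) != len(self.coefficients):
            raise ValueError("one coefficient per feature code required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("exposure_rates", "observe_rates"):
            val = getattr(self, name)
            if val is None:
                val = tuple((0.2 if name == "exposure_rates" else 0.9) for _ in codes)
                object.__setattr__(self, name, val)
            else:
                val = tuple(float(r) for r in val)
                object.__setattr__(self, name, val)
                if len(val) != len(codes):
                    raise ValueError(f"one {name[:-1]} per feature code required")
        inter = []
        for entry in self.interactions:
            if len(entry) < 3:
                raise ValueError("interaction needs at least two codes and a coefficient")
            members, coef = tuple(str(c) for c in entry[:-1]), float(entry[-1])
            for m in members:
                if m not in codes:
                    raise ValueError(f"interaction references unknown feature code {m!r}")
            inter.append((*members, coef))
        object.__setattr__(self, "interactions", tuple(inter))


def default_risk_model(disease: str = "lung_cancer") -> RiskModel:
    """Literature-shaped default risk structures for the two study diseases.

    Coefficients are log-odds per exposure, sized like published relative
    risks (heavy smoking dominates lung-cancer risk; blood pressure,
    rhythm and glucose dominate stroke risk); age enters as the
    indicator >= 50 years.
    """
    if disease == "lung_cancer":
        return RiskModel(
            feature_codes=(
                "72166-2",  # smoking status
                "8663-7",  # cigarettes per day
                "19926-5",  # FEV1/FVC
                "13645005",  # COPD
                "185086009",  # chronic bronchitis
                "8670-2",  # family history of cancer
                "63586-2",  # occupational exposure
                "74013-4",  # alcohol use
                "2708-6",  # oxygen saturation
                "9279-1",  # respiratory rate
                "8867-4",  # heart rate
                "55277-8",  # physical activity
                "8480-6",  # systolic BP
                "8462-4",  # diastolic BP
                "39156-5",  # BMI
                "2085-9",  # HDL
                "2571-8",  # triglycerides
                "4548-4",  # HbA1c
                "2160-0",  # creatinine
                AGE_FEATURE,
            ),
            coefficients=(1.0, 0.8, 0.8, 1.0, 0.7, 0.8, 0.7, 0.6, 0.7, 0.6, 0.5, 0.6, 0.6, 0.5, 0.7, 0.6, 0.6, 0.7, 0.6, 1.0),
            exposure_rates=(0.25, 0.25, 0.15, 0.10, 0.07, 0.15, 0.15, 0.20, 0.15, 0.20, 0.25, 0.30, 0.35, 0.30, 0.30, 0.25, 0.25, 0.15, 0.15, 1.0),
            observe_rates=(0.90, 0.80, 0.85, 1.0, 1.0, 0.70, 0.75, 0.80, 0.85, 0.85, 0.90, 0.80, 0.95, 0.95, 0.85, 0.85, 0.85, 0.85, 0.85, 1.0),
            # most of the risk lives in subgroup synergies (smokers over 50,
            # smokers with obstructive disease, combined exposures...), so a
            # model keeps discovering new high-risk subgroups as data grows;
            # the three-way pathways are the deep conditional structure that
            # default-capacity boosting only partially captures
            interactions=(
                ("72166-2", AGE_FEATURE, 3.0),
                ("72166-2", "13645005", 3.0),
                ("72166-2", "185086009", 2.5),
                ("8670-2", "63586-2", 2.5),
                ("19926-5", "8663-7", 2.5),
                ("2708-6", "13645005", 2.0),
                ("4548-4", "39156-5", 2.0),
                ("8480-6", "8462-4", 1.5),
                ("72166-2", AGE_FEATURE, "13645005", 3.5),
                ("72166-2", AGE_FEATURE, "8670-2", 3.0),
                ("63586-2", "19926-5", AGE_FEATURE, 3.0),
                ("72166-2", "74013-4", "39156-5", 2.5),
            ),
            noise_sd=0.3,
        )
    if disease == "stroke":
        return RiskModel(
            feature_codes=(
                "8480-6",  # systolic BP
                "8462-4",  # diastolic BP
                "8884-9",  # heart rhythm
                "2339-0",  # glucose
                "4548-4",  # HbA1c
                "72166-2",  # smoking status
                "39156-5",  # BMI
                "2571-8",  # triglycerides
                "2085-9",  # HDL
                "2160-0",  # creatinine
                "8867-4",  # heart rate
                "55277-8",  # physical activity
                "59621000",  # hypertension diagnosis
                "53741008",  # coronary heart disease
                AGE_FEATURE,
            ),
            coefficients=(1.0, 0.7, 1.2, 0.9, 0.8, 0.8, 0.8, 0.6, 0.6, 0.7, 0.6, 0.7, 1.0, 0.9, 1.2),
            exposure_rates=(0.35, 0.30, 0.08, 0.12, 0.15, 0.25, 0.30, 0.25, 0.25, 0.15, 0.25, 0.30, 0.35, 0.12, 1.0),
            observe_rates=(0.95, 0.95, 0.80, 0.90, 0.85, 0.90, 0.85, 0.85, 0.85, 0.85, 0.90, 0.80, 1.0, 1.0, 1.0),
            # hypertension and arrhythmia risk concentrates with age;
            # smoking compounds diagnosed hypertension; metabolic risk is
            # a glucose/HbA1c/BMI subgroup effect with deeper three-way
            # pathways (hypertensive smokers over 50, ...)
            interactions=(
                ("8480-6", AGE_FEATURE, 2.5),
                ("8884-9", AGE_FEATURE, 3.0),
                ("72166-2", "59621000", 2.5),
                ("2339-0", "4548-4", 2.2),
                ("4548-4", "39156-5", 2.0),
                ("53741008", "8480-6", 2.0),
                ("8480-6", "72166-2", AGE_FEATURE, 3.0),
                ("2339-0", "39156-5", AGE_FEATURE, 2.5),
                ("53741008", "8884-9", AGE_FEATURE, 2.5),
            ),
            noise_sd=0.3,
        )
    raise ValueError(f"no default risk model for {disease!r}")


@dataclass(frozen=True)
class PopulationConfig:
    """One batch of synthetic patients (~one Synthea export)."""

    n_patients: int
    seed: int
    min_age: float = 30.0
    max_age: float = 90.0
    target_disease: DiseaseSpec = LUNG_CANCER
    risk_model: RiskModel | None = None
    events_per_patient_year: float = 3.6
    start_year: int = 1990
    end_year: int = 2020
    vocab_size: int = 760

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.min_age < self.max_age:
            raise ValueError("min_age must be < max_age")
        if self.events_per_patient_year <= 0:
            raise ValueError("events_per_patient_year must be positive")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must be < end_year")
        if self.risk_model is None:
            try:
                rm = default_risk_model(self.target_disease.name)
            except ValueError:
                rm = default_risk_model("lung_cancer")
            object.__setattr__(self, "risk_model", rm)


@dataclass
class DomainBundle:
    """The eight Synthea-style domain tables for one population batch."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    conditions: pd.DataFrame
    observations: pd.DataFrame
    procedures: pd.DataFrame
    medications: pd.DataFrame
    immunizations: pd.DataFrame
    allergies: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        if name not in DOMAIN_TABLES:
            raise KeyError(f"unknown domain table {name!r}")
        return getattr(self, name)

    def event_tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in EVENT_TABLES}

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def case_ids(self, disease: DiseaseSpec) -> pd.Index:
        mask = self.conditions["code"].isin(disease.snomed_codes)
        return pd.Index(sorted(self.conditions.loc[mask, "patient_id"].unique()))

    def validate(self) -> None:
        """Raise if referential integrity or lifetime bounds are violated."""
        pids = set(self.patients["id"])
        eids = set(self.encounters["encounter_id"])
        if not set(self.encounters["patient_id"]) <= pids:
            raise ValueError("encounter references unknown patient")
        birth = self.patients.set_index("id")["birthdate"]
        for name, tab in self.event_tables().items():
            if len(tab) == 0:
                continue
            if not set(tab["patient_id"]) <= pids:
                raise ValueError(f"{name}: unknown patient_id")
            if not set(tab["encounter_id"]) <= eids:
                raise ValueError(f"{name}: unknown encounter_id")
            tcol = "time" if "time" in tab.columns else "start"
            if (tab[tcol].to_numpy() < birth.loc[tab["patient_id"]].to_numpy()).any():
                raise ValueError(f"{name}: event before birth")


def expected_cases(n_patients: int, prevalence: float) -> float:
    """Expected number of target-disease patients in a population."""
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must lie in [0, 1]")
    return n_patients * prevalence


def _calibrate_intercept(score: np.ndarray, prevalence: float) -> float:
    """Offset b such that mean(expit(score + b)) == prevalence."""

    def gap(b):
        return expit(score + b).mean() - prevalence

    lo, hi = -60.0, 60.0
    return brentq(gap, lo, hi, xtol=1e-10)


def _assign_cases(score: np.ndarray, prevalence: float, noise_sd: float, rng) -> np.ndarray:
    if noise_sd == 0:
        thr = np.quantile(score, 1.0 - prevalence)
        return score > thr
    b = _calibrate_intercept(score, prevalence)
    return rng.random(score.size) < expit(score + b)


def generate_population(config: PopulationConfig) -> DomainBundle:
    """Generate one population batch.

    Deterministic: identical (config, seed) pairs yield identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    rm = config.risk_model
    disease = config.target_disease

    sim_end = pd.Timestamp(year=config.end_year, month=1, day=1)
    ages = rng.uniform(config.min_age, config.max_age, n)
    birth_ns = sim_end.value - (ages * _SECONDS_PER_YEAR * 1e9).astype(np.int64)
    birthdates = pd.to_datetime(birth_ns).floor("D")
    pid = np.array([f"p{config.seed}-{i:06d}" for i in range(n)])

    # history window per patient (ages during which events occur)
    span_cap = float(config.end_year - config.start_year)
    hist_start = np.minimum(np.maximum(25.0, ages - span_cap), ages - 5.0)
    span = ages - hist_start

    # ---- planted risk structure -------------------------------------
    exposures = np.empty((n, len(rm.feature_codes)), dtype=bool)
    for j, (code, rate) in enumerate(zip(rm.feature_codes, rm.exposure_rates)):
        if code == AGE_FEATURE:
            exposures[:, j] = ages >= 50.0
        else:
            exposures[:, j] = rng.random(n) < rate
    score = exposures @ np.asarray(rm.coefficients) + rm.intercept
    code_pos = {c: j for j, c in enumerate(rm.feature_codes)}
    for entry in rm.interactions:
        members, coef = entry[:-1], entry[-1]
        joint = np.ones(n, dtype=bool)
        for m in members:
            joint &= exposures[:, code_pos[m]]
        score = score + coef * joint
    if rm.noise_sd > 0:
        score = score + rng.normal(0.0, rm.noise_sd, n)
    is_case = _assign_cases(score, disease.prevalence, rm.noise_sd, rng)

    # diagnosis falls in the last third of the history, so at least
    # two-thirds of the record span precedes it
    diag_age = ages - rng.uniform(0.0, span / 3.0)

    # ---- event streams ----------------------------------------------
    vocab = build_vocabulary(config.vocab_size)
    reserved = set(rm.feature_codes) | set(disease.snomed_codes)
    vocab = vocab[~vocab["code"].isin(reserved)].reset_index(drop=True)
    weights = vocab["weight"].to_numpy()
    weights = weights / weights.sum()

    n_events = rng.poisson(config.events_per_patient_year * span)
    total = int(n_events.sum())
    ev_pid = np.repeat(np.arange(n), n_events)
    ev_age = hist_start[ev_pid] + rng.random(total) * span[ev_pid]
    ev_code_idx = rng.choice(len(vocab), size=total, p=weights)

    vcode = vocab["code"].to_numpy()
    vname = vocab["name"].to_numpy()
    vdomain = vocab["domain"].to_numpy()
    vdtype = vocab["datatype"].to_numpy()
    vunit = vocab["unit"].to_numpy()
    vmu = vocab["mu"].to_numpy()
    vsigma = vocab["sigma"].to_numpy()
    vcats = vocab["categories"].to_numpy(dtype=object)

    ev_dtype = vdtype[ev_code_idx]
    ev_value = np.full(total, "present", dtype=object)
    num_mask = ev_dtype == "numeric"
    if num_mask.any():
        draws = rng.normal(vmu[ev_code_idx[num_mask]], vsigma[ev_code_idx[num_mask]])
        draws = np.maximum(draws, 0.1)
        ev_value[num_mask] = np.char.mod("%.1f", draws)
    cat_obs_mask = (vdomain[ev_code_idx] == "observations") & ~num_mask
    if cat_obs_mask.any():
        # flat category lookup: one uniform draw indexes into each code's pool
        ncats = np.array([max(len(c), 1) for c in vcats])
        offsets = np.concatenate([[0], np.cumsum(ncats)[:-1]])
        flat = np.array([v for cats in vcats for v in (cats or ("present",))], dtype=object)
        idxs = np.flatnonzero(cat_obs_mask)
        ci = ev_code_idx[idxs]
        picks = (rng.random(idxs.size) * ncats[ci]).astype(np.int64)
        ev_value[idxs] = flat[offsets[ci] + picks]

    frames = [
        pd.DataFrame(
            {
                "pidx": ev_pid,
                "age": ev_age,
                "code": vcode[ev_code_idx],
                "description": vname[ev_code_idx],
                "domain": vdomain[ev_code_idx],
                "value": ev_value,
                "unit": vunit[ev_code_idx],
                "datatype": ev_dtype,
            }
        )
    ]

    # risk-factor events: planted in the first two-thirds of the history
    # so they always precede a case's diagnosis
    for j, code in enumerate(rm.feature_codes):
        if code == AGE_FEATURE:
            continue
        name, domain, dtype, unit, risky, benign = _RISK_FACTOR_CATALOG.get(
            code, (f"Risk factor {code}", "conditions", "categorical", "", "present", None)
        )
        if benign is None:
            participants = np.flatnonzero(exposures[:, j])
        else:
            participants = np.flatnonzero(rng.random(n) < rm.observe_rates[j])
        if participants.size == 0:
            continue
        reps = rng.integers(1, 4, participants.size)
        rp = np.repeat(participants, reps)
        r_age = hist_start[rp] + rng.random(rp.size) * (2.0 / 3.0) * span[rp]
        r_exposed = exposures[rp, j]
        if dtype == "numeric":
            mu = np.where(r_exposed, risky[1], benign[1])
            sd = np.where(r_exposed, risky[2], benign[2])
            vals = np.maximum(rng.normal(mu, sd), 0.01)
            r_value = np.char.mod("%.2f", vals).astype(object)
        else:
            r_value = np.where(r_exposed, risky, benign if benign is not None else risky).astype(object)
        frames.append(
            pd.DataFrame(
                {
                    "pidx": rp,
                    "age": r_age,
                    "code": code,
                    "description": name,
                    "domain": domain,
                    "value": r_value,
                    "unit": unit,
                    "datatype": dtype,
                }
            )
        )

    # the target-disease diagnosis itself (cases only)
    case_idx = np.flatnonzero(is_case)
    if case_idx.size:
        dcodes = np.asarray(disease.snomed_codes)[rng.integers(0, len(disease.snomed_codes), case_idx.size)]
        frames.append(
            pd.DataFrame(
                {
                    "pidx": case_idx,
                    "age": diag_age[case_idx],
                    "code": dcodes,
                    "description": disease.name.replace("_", " "),
                    "domain": "conditions",
                    "value": "present",
                    "unit": "",
                    "datatype": "categorical",
                }
            )
        )

    events = pd.concat(frames, ignore_index=True)
    ev_ns = birth_ns[events["pidx"].to_numpy()] + (events["age"].to_numpy() * _SECONDS_PER_YEAR * 1e9).astype(np.int64)
    ev_ns = (ev_ns // 1_000_000_000) * 1_000_000_000  # second resolution
    events["time"] = pd.to_datetime(ev_ns)
    # patient ids are equal-length and share a prefix, so sorting by the
    # integer index matches lexicographic order on the id strings
    order = np.lexsort((events["code"].to_numpy(), ev_ns, events["pidx"].to_numpy()))
    events = events.iloc[order].reset_index(drop=True)
    events["patient_id"] = pid[events["pidx"].to_numpy()]

    # one encounter per (patient, calendar day)
    day_ord = events["time"].to_numpy().astype("datetime64[D]").astype(np.int64)
    key = events["pidx"].to_numpy() * 200_000 + (day_ord - day_ord.min())
    _, enc_codes = np.unique(key, return_inverse=True)
    events["encounter_id"] = np.char.mod(f"e{config.seed}-%07d", enc_codes)

    enc = (
        events.groupby("encounter_id", sort=True)
        .agg(patient_id=("patient_id", "first"), start=("time", "min"), stop=("time", "max"))
        .reset_index()
    )
    enc["stop"] = enc["stop"] + pd.Timedelta(hours=1)
    enc["type"] = np.where(rng.random(len(enc)) < 0.25, "wellness", "ambulatory")

    patients = pd.DataFrame(
        {
            "id": pid,
            "birthdate": birthdates,
            "gender": np.where(rng.random(n) < 0.5, "F", "M"),
            "race": rng.choice(["white", "black", "asian", "hispanic", "other"], size=n, p=[0.6, 0.13, 0.06, 0.17, 0.04]),
            "zip": np.char.mod("%05d", rng.integers(10000, 99999, n)),
        }
    )

    def _domain_frame(domain: str) -> pd.DataFrame:
        sub = events[events["domain"] == domain]
        if domain == "observations":
            out = sub[["patient_id", "encounter_id", "time", "code", "description", "value", "unit", "datatype"]]
        else:
            out = sub[["patient_id", "encounter_id", "time", "code", "description"]].rename(columns={"time": "start"})
        return out.reset_index(drop=True)

    bundle = DomainBundle(
        patients=patients,
        encounters=enc[["encounter_id", "patient_id", "start", "stop", "type"]],
        conditions=_domain_frame("conditions"),
        observations=_domain_frame("observations"),
        procedures=_domain_frame("procedures"),
        medications=_domain_frame("medications"),
        immunizations=_domain_frame("immunizations"),
        allergies=_domain_frame("allergies"),
    )
    return bundle


# ---------------------------------------------------------------------
# CSV export / import (Synthea dialect: header row, ISO-8601 timestamps)
# ---------------------------------------------------------------------

_TIME_COLUMNS = {"birthdate", "start", "stop", "time"}
_TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"


def write_domain_files(bundle: DomainBundle, directory: str | Path) -> dict[str, int]:
    """Write the eight domain CSVs; returns {filename: row count}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    for name in DOMAIN_TABLES:
        tab = bundle.table(name)
        path = directory / f"{name}.csv"
        tab.to_csv(path, index=False, date_format=_TIME_FORMAT)
        manifest[path.name] = len(tab)
    return manifest


def read_domain_files(directory: str | Path) -> DomainBundle:
    """Read a directory of Synthea-dialect domain CSVs back into a bundle."""
    directory = Path(directory)
    tables = {}
    for name in DOMAIN_TABLES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        tab = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in tab.columns:
            if col in _TIME_COLUMNS:
                tab[col] = pd.to_datetime(tab[col], format="ISO8601")
        tables[name] = tab
    return DomainBundle(**tables)


# ---------------------------------------------------------------------
# YAML config mirror
# ---------------------------------------------------------------------


def load_population_config(path: str | Path) -> PopulationConfig:
    """Build a PopulationConfig from a YAML file mirroring its fields."""
    raw = yaml.safe_load(Path(path).read_text())
    if "target_disease" in raw:
        d = raw["target_disease"]
        raw["target_disease"] = DiseaseSpec(d["name"], tuple(str(c) for c in d["snomed_codes"]), float(d["prevalence"]))
    if "risk_model" in raw and raw["risk_model"] is not None:
        r = raw["risk_model"]
        raw["risk_model"] = RiskModel(
            feature_codes=tuple(str(c) for c in r["feature_codes"]),
            coefficients=tuple(float(c) for c in r["coefficients"]),
            intercept=float(r.get("intercept", 0.0)),
            noise_sd=float(r.get("noise_sd", 0.8)),
            exposure_rates=tuple(float(x) for x in r["exposure_rates"]) if r.get("exposure_rates") else None,
            observe_rates=tuple(float(x) for x in r["observe_rates"]) if r.get("observe_rates") else None,
        )
    return PopulationConfig(**raw)
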