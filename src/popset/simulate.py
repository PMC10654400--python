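"""Seeded synthetic surgical cohorts with known (planted) ground truth.

The generator emulates the record structure of a multicenter perioperative
EHR extract: demographics and preoperative variables, one procedure (CPT)
code plus a Zipf-distributed set of diagnosis (ICD-10-like) comorbidity
codes, and repeated daily pain observations on postoperative days 0-4 that
are censored by hospital discharge. Latent daily pain is an additive model —
a baseline trajectory, planted per-code effects, linear effects of
standardized age and preoperative pain, and Gaussian noise — clamped to the
0-10 NRS. A configured fraction of observations is rendered as the
six-category pain strings (latent value rounded to the nearest even integer,
then inverted through the string map, so the conversion is exactly
invertible). ICU-admission and intraoperative-death flags are set at
configured rates so the exclusion rules are exercised.

None of this claims to model the data-generating process of any real
cohort; it plants known structure so that recovery can be tested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .records import (
    N_DAYS,
    PAIN_VALUE_TO_STRING,
    PatientRecord,
)

RACES = ("White", "Black", "Hispanic", "Asian", "Other")
RACE_P = (0.822, 0.051, 0.040, 0.031, 0.056)
SERVICES = (
    "Orthopedic Surgery",
    "General Surgery",
    "Urology",
    "Gynecology",
    "Thoracic Surgery",
    "Neurosurgery",
    "Surgical Oncology",
    "Other",
)
SERVICE_P = (0.243, 0.150, 0.105, 0.095, 0.075, 0.071, 0.059, 0.202)
URGENCIES = ("elective", "urgent", "emergent")
URGENCY_P = (0.80, 0.15, 0.05)

# population moments used both to draw demographics and to standardize them
AGE_MEAN, AGE_SD = 55.9, 17.0
WEIGHT_MEAN, WEIGHT_SD = 81.4, 24.5
HEIGHT_MEAN, HEIGHT_SD = 1.69, 0.11
PREOP_MEAN, PREOP_SD = 2.0, 2.5


@dataclass
class SimConfig:
    """Cohort-generator configuration; defaults are the study conditions.

    ``effect_codes`` maps a code name (e.g. ``"CPT-0001"``, ``"ICD-0003"``)
    to a 5-vector of additive NRS effects on days 0-4 carried by every
    patient with that code.
    """

    n_patients: int = 2000
    n_codes: int = 200
    n_cpt: int = 20
    zipf_exponent: float = 1.1
    codes_per_patient_mean: float = 6.0
    effect_codes: dict[str, tuple] = field(default_factory=dict)
    baseline_trajectory: tuple = (5.2, 5.3, 5.5, 5.2, 5.2)
    noise_sd: float = 1.5
    obs_noise_sd: float = 1.0
    pain_string_fraction: float = 0.09
    obs_per_day_mean: float = 4.0
    discharge_hazard: float = 0.35
    discharge_pain_coupling: float = 0.0  # >0: higher latent pain, longer stay
    icu_rate: float = 0.068
    death_rate: float = 0.00017
    demog_beta_age: float = 0.3
    demog_beta_preop: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "zipf_exponent",
            "codes_per_patient_mean",
            "noise_sd",
            "obs_noise_sd",
            "obs_per_day_mean",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        for name in ("pain_string_fraction", "icu_rate", "death_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a proportion in [0,1]")
        if not 0 < self.discharge_hazard < 1:
            raise ValueError("discharge_hazard must be in (0,1)")
        if self.n_cpt > self.n_codes or self.n_cpt < 1:
            raise ValueError("need 1 <= n_cpt <= n_codes")
        traj = np.asarray(self.baseline_trajectory, dtype=float)
        if traj.shape != (N_DAYS,) or not np.all((traj >= 0) & (traj <= 10)):
            raise ValueError("baseline_trajectory must be 5 values in [0,10]")
        for code, eff in self.effect_codes.items():
            if np.asarray(eff, dtype=float).shape != (N_DAYS,):
                raise ValueError(f"effect for {code} must be a 5-vector")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated cohort."""

    latent_pain: np.ndarray  # (n_patients, 5)
    discharge_day: np.ndarray  # (n_patients,)
    effect_codes: dict[str, tuple]
    carriers: dict[str, np.ndarray]  # effect code -> boolean carrier vector
    patient_ids: list[str]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "latent_pain": self.latent_pain.tolist(),
                    "discharge_day": self.discharge_day.tolist(),
                    "effect_codes": {c: list(map(float, e)) for c, e in self.effect_codes.items()},
                    "carriers": {c: v.astype(int).tolist() for c, v in self.carriers.items()},
                    "patient_ids": self.patient_ids,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            latent_pain=np.asarray(d["latent_pain"], dtype=float),
            discharge_day=np.asarray(d["discharge_day"], dtype=int),
            effect_codes={c: tuple(e) for c, e in d["effect_codes"].items()},
            carriers={c: np.asarray(v, dtype=bool) for c, v in d["carriers"].items()},
            patient_ids=list(d["patient_ids"]),
        )


def zipf_probabilities(n: int, exponent: float) -> np.ndarray:
    """Exact Zipf pmf over ranks 1..n (normalization by direct summation)."""
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def cpt_code_name(rank: int) -> str:
    return f"CPT-{rank:04d}"


def icd_code_name(rank: int) -> str:
    return f"ICD-{rank:04d}"


def _round_to_even(v: float) -> int:
    return int(min(10, max(0, 2 * round(v / 2))))


def generate_cohort(config: SimConfig) -> tuple[list[PatientRecord], SimTruth]:
    """Generate a seeded cohort and its ground truth.

    Each patient carries exactly one CPT-like procedure code (Zipf-drawn over
    the CPT family) and a Poisson number of distinct ICD-like comorbidity
    codes drawn without replacement under Zipf weights over the ICD family.
    Identical config (including seed) reproduces the cohort exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_icd = config.n_codes - config.n_cpt
    if n_icd < 1:
        raise ValueError("need at least one ICD-like code (n_codes > n_cpt)")
    p_cpt = zipf_probabilities(config.n_cpt, config.zipf_exponent)
    p_icd = zipf_probabilities(n_icd, config.zipf_exponent)
    baseline = np.asarray(config.baseline_trajectory, dtype=float)
    effects = {c: np.asarray(e, dtype=float) for c, e in config.effect_codes.items()}
    mean_icd = max(config.codes_per_patient_mean - 1.0, 0.0)

    records: list[PatientRecord] = []
    latent_all = np.zeros((n, N_DAYS))
    discharge_all = np.zeros(n, dtype=int)
    carrier_flags = {c: np.zeros(n, dtype=bool) for c in effects}
    patient_ids = []

    for i in range(n):
        pid = f"P{i:06d}"
        patient_ids.append(pid)
        age = float(np.clip(rng.normal(AGE_MEAN, AGE_SD), 18, 95))
        weight = float(np.clip(rng.normal(WEIGHT_MEAN, WEIGHT_SD), 35, 200))
        height = float(np.clip(rng.normal(HEIGHT_MEAN, HEIGHT_SD), 1.40, 2.10))
        sex = "female" if rng.random() < 0.558 else "male"
        race = str(rng.choice(RACES, p=RACE_P))
        preop_missing = rng.random() < 0.05
        preop_pain = None if preop_missing else float(
            np.clip(round(rng.normal(PREOP_MEAN, PREOP_SD)), 0, 10)
        )
        service = str(rng.choice(SERVICES, p=SERVICE_P))
        urgency = str(rng.choice(URGENCIES, p=URGENCY_P))
        inpatient = bool(rng.random() < 0.592)

        codes: dict[str, str] = {}
        cpt_rank = int(rng.choice(config.n_cpt, p=p_cpt)) + 1
        codes[cpt_code_name(cpt_rank)] = "CPT"
        k = int(min(rng.poisson(mean_icd), n_icd))
        if k > 0:
            icd_ranks = rng.choice(n_icd, size=k, replace=False, p=p_icd) + 1
            for r in icd_ranks:
                codes[icd_code_name(int(r))] = "ICD10"

        z_age = (age - AGE_MEAN) / AGE_SD
        z_preop = ((preop_pain if preop_pain is not None else PREOP_MEAN) - PREOP_MEAN) / PREOP_SD
        latent = baseline.copy()
        for c, eff in effects.items():
            if c in codes:
                latent = latent + eff
                carrier_flags[c][i] = True
        latent = latent + config.demog_beta_age * z_age + config.demog_beta_preop * z_preop
        latent = latent + rng.normal(0.0, config.noise_sd, size=N_DAYS) if config.noise_sd > 0 else latent
        latent = np.clip(latent, 0, 10)
        latent_all[i] = latent

        # discharge: per-day hazard, optionally inflated by latent pain
        day = 0
        while day < 1000:
            h = config.discharge_hazard
            if config.discharge_pain_coupling > 0:
                logit = math.log(h / (1 - h)) - config.discharge_pain_coupling * (
                    latent[min(day, N_DAYS - 1)] - 5.0
                )
                h = 1.0 / (1.0 + math.exp(-logit))
            if rng.random() < h:
                break
            day += 1
        discharge_all[i] = day

        pain_obs: list[tuple[int, object]] = []
        for d in range(min(day, N_DAYS - 1) + 1):
            n_obs = int(rng.poisson(config.obs_per_day_mean))
            for _ in range(n_obs):
                v = latent[d] + (rng.normal(0.0, config.obs_noise_sd) if config.obs_noise_sd > 0 else 0.0)
                v = float(np.clip(v, 0, 10))
                if rng.random() < config.pain_string_fraction:
                    pain_obs.append((d, PAIN_VALUE_TO_STRING[_round_to_even(v)]))
                else:
                    pain_obs.append((d, float(round(v))))

        records.append(
            PatientRecord(
                patient_id=pid,
                age=age,
                weight=weight,
                height=height,
                sex=sex,
                race=race,
                preop_pain=preop_pain,
                service=service,
                urgency=urgency,
                inpatient=inpatient,
                codes=codes,
                pain_obs=pain_obs,
                died_intraop=bool(rng.random() < config.death_rate),
                icu_admit=bool(rng.random() < config.icu_rate),
            )
        )

    truth = SimTruth(
        latent_pain=latent_all,
        discharge_day=discharge_all,
        effect_codes={c: tuple(map(float, e)) for c, e in effects.items()},
        carriers=carrier_flags,
        patient_ids=patient_ids,
    )
    return records, truth


def config_from_dict(d: dict) -> SimConfig:
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["baseline_trajectory"] = list(d["baseline_trajectory"])
    d["effect_codes"] = {c: list(e) for c, e in d["effect_codes"].items()}
    return d
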