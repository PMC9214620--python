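"""Synthetic EHR generator for end-to-end testing of the screen.

Emits the three raw tables the pipeline consumes — deliveries, medication
orders, diagnosis codes — from a known data-generating process: maternal
age is truncated normal; ART and infertility indicators are Bernoulli and
surface as diagnosis codes dated within the 315-day lookback; medication
exposures are per-medication Bernoulli draws that surface as orders dated
uniformly inside the 275–215-day preconception window; the multiple-birth
outcome follows the logistic model

    logit P(MB) = baseline + b_age·age + b_art·ART + b_inf·INF + Σ b_m·X_m

and surfaces as an MB diagnosis code dated exactly on the delivery date.
Decoy records (MB codes mid-pregnancy, diagnoses outside the lookback,
orders outside the window) can be layered on top; by construction they
must not change any downstream assignment.

Defaults reproduce the margins of a large single-center delivery cohort:
63,334 deliveries, MB 2.47%, any-exposure 2.96%, ART 0.39%, infertility
0.08%, maternal age 29.5 (SD 6.1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from . import defaults

AGE_BOUNDS = (12.0, 55.0)
_DATE0 = np.datetime64("2010-01-01")
_DATE_SPAN_DAYS = 2921  # deliveries spread over 2010-2017

# representative emitted codes per list (system, code)
_MB_CODES = [("ICD-10", "Z37.2"), ("ICD-10", "O30.0"), ("ICD-9-CM", "651.01")]
_ART_CODES = [("ICD-10", "O09.811"), ("ICD-9-CM", "V23.85")]
_INF_CODES = [("ICD-10", "N97.9"), ("ICD-9-CM", "628.9")]


def per_medication_prevalence(any_exposure: float, n_medications: int) -> float:
    """Per-medication Bernoulli prevalence giving a target any-exposure
    margin under independent draws: 1-(1-p)^m = any_exposure."""
    return 1.0 - (1.0 - any_exposure) ** (1.0 / n_medications)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic data-generating process.

    ``exposure_prevalence`` is a scalar applied to every medication or a
    medication_id → probability map; ``beta_medication`` holds planted
    log-odds effects and defaults to 0 for unlisted medications.
    """

    n_deliveries: int = 63334
    n_medications: int = defaults.DEFAULT_N_MEDICATIONS
    gold_standard_ids: tuple[str, ...] = ()
    exposure_prevalence: float | Mapping[str, float] = 2.443e-4
    baseline_mb_logit: float = float(special.logit(0.0247))
    beta_age: float = 0.0
    beta_art: float = float(np.log(8.0))
    beta_infertility: float = float(np.log(2.0))
    beta_medication: Mapping[str, float] = field(default_factory=dict)
    art_prevalence: float = 0.0039
    infertility_prevalence: float = 0.0008
    age_mean: float = 29.5
    age_sd: float = 6.1
    seed: int = 0
    decoy_fraction: float = 0.0
    deliveries_per_patient: int = 1
    exposure_blocks: tuple[tuple[str, ...], ...] = ()
    block_correlation: float = 0.0

    def __post_init__(self):
        if self.n_deliveries < 1:
            raise ValueError("n_deliveries must be >= 1")
        if self.n_medications < 1:
            raise ValueError("n_medications must be >= 1")
        for name in ("art_prevalence", "infertility_prevalence", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for p in self._prevalence_values():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"exposure prevalence must be in [0, 1), got {p}")
        unknown = set(self.gold_standard_ids) - set(self.medication_ids())
        if unknown:
            raise ValueError(f"gold_standard_ids not in the formulary: {sorted(unknown)}")

    def _prevalence_values(self):
        if isinstance(self.exposure_prevalence, Mapping):
            return list(self.exposure_prevalence.values())
        return [self.exposure_prevalence]

    def medication_ids(self) -> list[str]:
        return defaults.medication_ids(self.annotations())

    def annotations(self) -> pd.DataFrame:
        return defaults.default_annotations(self.n_medications)

    def prevalence_vector(self, med_ids: list[str]) -> np.ndarray:
        if isinstance(self.exposure_prevalence, Mapping):
            return np.array([float(self.exposure_prevalence.get(m, 0.0)) for m in med_ids])
        return np.full(len(med_ids), float(self.exposure_prevalence))

    def beta_vector(self, med_ids: list[str]) -> np.ndarray:
        return np.array([float(self.beta_medication.get(m, 0.0)) for m in med_ids])


@dataclass
class SyntheticCohort:
    """Generated raw tables plus the hidden truth used to create them."""

    deliveries: pd.DataFrame
    orders: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: dict[str, float]
    latent: pd.DataFrame  # per-delivery simulated mb/art/infertility/exposure-any
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write deliveries.csv, orders.csv, diagnoses.csv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (("deliveries", self.deliveries),
                            ("orders", self.orders),
                            ("diagnoses", self.diagnoses)):
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            paths[name] = path
        tpath = outdir / "truth.json"
        tpath.write_text(json.dumps(self.truth, sort_keys=True, indent=1))
        paths["truth"] = tpath
        return paths


def _draw_codes(rng: np.random.Generator, reps: list[tuple[str, str]], n: int):
    idx = rng.integers(0, len(reps), size=n)
    systems = np.array([r[0] for r in reps])[idx]
    codes = np.array([r[1] for r in reps])[idx]
    return systems, codes


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; identical config ⇒ identical tables."""
    rng = np.random.default_rng(config.seed)
    n = config.n_deliveries
    annotations = config.annotations()
    med_ids = defaults.medication_ids(annotations)
    prev = config.prevalence_vector(med_ids)
    beta_m = config.beta_vector(med_ids)

    # patients and deliveries
    k = max(1, config.deliveries_per_patient)
    n_patients = -(-n // k)
    patient_ids = np.array([f"P{i:07d}" for i in range(n_patients)])
    patients = np.repeat(patient_ids, k)[:n]
    delivery_ids = np.array([f"D{i:07d}" for i in range(n)])
    a, b = ((AGE_BOUNDS[0] - config.age_mean) / config.age_sd,
            (AGE_BOUNDS[1] - config.age_mean) / config.age_sd)
    ages = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                               size=n, random_state=rng)
    first_dates = _DATE0 + rng.integers(0, _DATE_SPAN_DAYS, size=n).astype("timedelta64[D]")
    if k > 1:
        # uniform 540-day spacing between a patient's successive deliveries
        order_within = np.arange(n) % k
        dates = first_dates + (order_within * 540).astype("timedelta64[D]")
    else:
        dates = first_dates

    # covariate and exposure draws
    art = rng.random(n) < config.art_prevalence
    inf = rng.random(n) < config.infertility_prevalence
    u_own = rng.random((n, len(med_ids)))
    u = u_own
    if config.exposure_blocks and config.block_correlation > 0:
        u = u_own.copy()
        col_of = {m: j for j, m in enumerate(med_ids)}
        for block in config.exposure_blocks:
            shared = rng.random(n)
            use_shared = rng.random(n) < config.block_correlation
            for m in block:
                j = col_of[m]
                u[:, j] = np.where(use_shared, shared, u_own[:, j])
    exposed = u < prev[None, :]

    # outcome from the planted logistic model
    logit_p = (config.baseline_mb_logit + config.beta_age * ages
               + config.beta_art * art + config.beta_infertility * inf
               + exposed @ beta_m)
    mb = rng.random(n) < special.expit(logit_p)

    deliveries = pd.DataFrame({
        "patient_id": patients,
        "delivery_id": delivery_ids,
        "delivery_date": pd.Series(dates).dt.strftime("%Y-%m-%d"),
        "maternal_age": np.round(ages, 2),
    })

    # orders: one per exposed (delivery, medication), dated in-window
    d_idx, m_idx = np.nonzero(exposed)
    offsets = rng.integers(215, 276, size=len(d_idx))
    order_dates = dates[d_idx] - offsets.astype("timedelta64[D]")
    names_by_med = annotations.groupby("medication_id")["name"].apply(list).to_dict()
    drug_names = np.array([
        names_by_med[med_ids[j]][rng.integers(0, len(names_by_med[med_ids[j]]))]
        for j in m_idx
    ], dtype=object) if len(m_idx) else np.array([], dtype=object)
    orders = pd.DataFrame({
        "patient_id": patients[d_idx],
        "drug_name": drug_names,
        "order_date": pd.Series(order_dates).dt.strftime("%Y-%m-%d"),
    })

    # diagnoses: MB at delivery date; ART/INF within the 315-day lookback
    dx_frames = []
    mb_idx = np.nonzero(mb)[0]
    if len(mb_idx):
        systems, codes = _draw_codes(rng, _MB_CODES, len(mb_idx))
        dx_frames.append(pd.DataFrame({
            "patient_id": patients[mb_idx], "code_system": systems, "code": codes,
            "date": pd.Series(dates[mb_idx]).dt.strftime("%Y-%m-%d"),
        }))
    for mask, reps in ((art, _ART_CODES), (inf, _INF_CODES)):
        idx = np.nonzero(mask)[0]
        if len(idx):
            systems, codes = _draw_codes(rng, reps, len(idx))
            back = rng.integers(0, 316, size=len(idx)).astype("timedelta64[D]")
            dx_frames.append(pd.DataFrame({
                "patient_id": patients[idx], "code_system": systems, "code": codes,
                "date": pd.Series(dates[idx] - back).dt.strftime("%Y-%m-%d"),
            }))
    diagnoses = (pd.concat(dx_frames, ignore_index=True) if dx_frames
                 else pd.DataFrame(columns=["patient_id", "code_system", "code", "date"]))

    latent = pd.DataFrame({
        "delivery_id": delivery_ids,
        "mb": mb.astype("int8"),
        "art": art.astype("int8"),
        "infertility": inf.astype("int8"),
        "any_exposure": exposed.any(axis=1).astype("int8"),
    })
    truth = {m: float(b) for m, b in zip(med_ids, beta_m)}
    cohort = SyntheticCohort(deliveries, orders, diagnoses, truth, latent, config)
    if config.decoy_fraction > 0:
        cohort = emit_decoys(cohort, config)
    return cohort


def emit_decoys(cohort: SyntheticCohort, config: SimulationConfig) -> SyntheticCohort:
    """Layer on records that must be invisible to every downstream stage:

    (a) MB codes dated mid-pregnancy for a fraction of non-MB deliveries,
    (b) ART/infertility codes dated beyond the 315-day lookback,
    (c) orders dated just outside the 275–215-day exposure window.

    A decoy fraction of 0 returns the cohort unchanged.
    """
    f = config.decoy_fraction
    if f == 0:
        return cohort
    rng = np.random.default_rng([config.seed, 977])
    deliveries = cohort.deliveries
    dates = pd.to_datetime(deliveries["delivery_date"]).to_numpy().astype("datetime64[D]")
    patients = deliveries["patient_id"].to_numpy()
    latent = cohort.latent.set_index("delivery_id")

    dx_new = []
    non_mb = np.nonzero(latent["mb"].to_numpy() == 0)[0]
    pick = non_mb[rng.random(len(non_mb)) < f]
    if len(pick):
        systems, codes = _draw_codes(rng, _MB_CODES, len(pick))
        back = rng.integers(30, 201, size=len(pick)).astype("timedelta64[D]")
        dx_new.append(pd.DataFrame({
            "patient_id": patients[pick], "code_system": systems, "code": codes,
            "date": pd.Series(dates[pick] - back).dt.strftime("%Y-%m-%d"),
        }))
    pick = np.nonzero(rng.random(len(deliveries)) < f)[0]
    if len(pick):
        reps = _ART_CODES + _INF_CODES
        systems, codes = _draw_codes(rng, reps, len(pick))
        back = rng.integers(316, 501, size=len(pick)).astype("timedelta64[D]")
        dx_new.append(pd.DataFrame({
            "patient_id": patients[pick], "code_system": systems, "code": codes,
            "date": pd.Series(dates[pick] - back).dt.strftime("%Y-%m-%d"),
        }))
    diagnoses = pd.concat([cohort.diagnoses, *dx_new], ignore_index=True)

    pick = np.nonzero(rng.random(len(deliveries)) < f)[0]
    orders = cohort.orders
    if len(pick):
        annotations = config.annotations()
        names = annotations["name"].to_numpy()
        offs = np.where(rng.random(len(pick)) < 0.5, 214, 276).astype("timedelta64[D]")
        decoy_orders = pd.DataFrame({
            "patient_id": patients[pick],
            "drug_name": names[rng.integers(0, len(names), size=len(pick))],
            "order_date": pd.Series(dates[pick] - offs).dt.strftime("%Y-%m-%d"),
        })
        orders = pd.concat([orders, decoy_orders], ignore_index=True)

    return replace(cohort, orders=orders, diagnoses=diagnoses)


def paper_scale_config(seed: int = 0, planted_or: float = 6.0,
                       n_deliveries: int = 63334) -> SimulationConfig:
    """Study-scale scenario: 123-medication formulary with the default
    cohort margins and a planted log-OR of log(planted_or) on each of the
    15 gold-standard fertility medications."""
    gold = tuple(defaults.default_gold_standard())
    prev = per_medication_prevalence(0.0296, defaults.DEFAULT_N_MEDICATIONS)
    return SimulationConfig(
        n_deliveries=n_deliveries,
        gold_standard_ids=gold,
        exposure_prevalence=prev,
        beta_medication={m: float(np.log(planted_or)) for m in gold},
        seed=seed,
    )
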