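"""Analysis-cohort construction from delivery and diagnosis tables.

The unit of analysis is the delivery.  The multiple-birth (MB) outcome is
coded from diagnosis billing codes dated at the delivery itself; codes
assigned earlier in the pregnancy are deliberately ignored, because an MB
code during gestation describes a multifetal pregnancy that may not end in
a multiple birth.  ART-resulting-pregnancy and infertility covariates use a
315-day lookback from the delivery date, covering the pregnancy plus a
periconception margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RECOGNIZED_SYSTEMS = {"ICD-9-CM", "ICD-10"}

#: days of diagnosis lookback before delivery for ART/infertility flags
DEFAULT_LOOKBACK_DAYS = 315


@dataclass(frozen=True)
class CodeList:
    """A named diagnosis code list.

    ``codes`` holds (code_system, code) pairs; a code ending in ``.`` is a
    family prefix: ``("ICD-10", "O30.")`` matches ``O30`` itself and any
    code starting with ``O30.``.
    """

    name: str
    codes: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.codes:
            raise ValueError(f"code list {self.name!r} is empty")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str) -> "CodeList":
        sub = frame[frame["list_name"] == name]
        return cls(name, frozenset(zip(sub["code_system"], sub["code"])))

    def match(self, diagnoses: pd.DataFrame) -> pd.Series:
        """Boolean mask of diagnosis rows matching this list.

        Unknown code systems are warned about once and never match.
        """
        systems = diagnoses["code_system"]
        unknown = sorted(set(systems) - RECOGNIZED_SYSTEMS)
        if unknown:
            warnings.warn(
                f"skipping diagnoses with unrecognized code system(s): {unknown}",
                stacklevel=2,
            )
        codes = diagnoses["code"].str.strip().str.upper()
        mask = pd.Series(False, index=diagnoses.index)
        for system, code in self.codes:
            code = code.strip().upper()
            in_system = systems == system
            if code.endswith("."):
                stem = code[:-1]
                mask |= in_system & (codes.eq(stem) | codes.str.startswith(code))
            else:
                mask |= in_system & codes.eq(code)
        return mask & systems.isin(RECOGNIZED_SYSTEMS)


def load_code_lists(frame: pd.DataFrame) -> dict[str, CodeList]:
    """Split a (list_name, code_system, code) frame into CodeList objects."""
    return {name: CodeList.from_frame(frame, name) for name in frame["list_name"].unique()}


def _as_datetime(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s, format="mixed") if not pd.api.types.is_datetime64_any_dtype(s) else s


def _flag_in_window(
    deliveries: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codelist: CodeList,
    min_days_before: int,
    max_days_before: int,
) -> pd.Series:
    """1 iff the delivery's patient has a matching code dated within
    [delivery - max_days_before, delivery - min_days_before], inclusive."""
    hits = diagnoses[codelist.match(diagnoses)]
    flags = pd.Series(0, index=deliveries["delivery_id"], dtype="int8", name=codelist.name)
    if hits.empty:
        return flags
    merged = deliveries[["delivery_id", "patient_id", "delivery_date"]].merge(
        hits[["patient_id", "date"]], on="patient_id", how="inner"
    )
    days_before = (merged["delivery_date"] - merged["date"]).dt.days
    ok = (days_before >= min_days_before) & (days_before <= max_days_before)
    flags.loc[flags.index.isin(merged.loc[ok, "delivery_id"])] = 1
    return flags


def assign_mb(
    deliveries: pd.DataFrame,
    diagnoses: pd.DataFrame,
    mb_codes: CodeList,
    tolerance_days: int = 0,
) -> pd.Series:
    """Binary MB outcome per delivery, indexed by delivery_id.

    A delivery is MB iff an MB-list code for the same patient is dated on
    the delivery date (± ``tolerance_days``, default exact).  MB codes at
    any other date — in particular during the pregnancy — are ignored.
    """
    deliveries = deliveries.assign(delivery_date=_as_datetime(deliveries["delivery_date"]))
    diagnoses = diagnoses.assign(date=_as_datetime(diagnoses["date"]))
    return _flag_in_window(
        deliveries, diagnoses, mb_codes, -tolerance_days, tolerance_days
    ).rename("mb")


def assign_art_infertility(
    deliveries: pd.DataFrame,
    diagnoses: pd.DataFrame,
    art_codes: CodeList,
    inf_codes: CodeList,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> pd.DataFrame:
    """Binary (art, infertility) covariates per delivery.

    A flag is set iff a matching code for the patient falls in
    [delivery_date - lookback_days, delivery_date], both ends inclusive.
    """
    deliveries = deliveries.assign(delivery_date=_as_datetime(deliveries["delivery_date"]))
    diagnoses = diagnoses.assign(date=_as_datetime(diagnoses["date"]))
    art = _flag_in_window(deliveries, diagnoses, art_codes, 0, lookback_days)
    inf = _flag_in_window(deliveries, diagnoses, inf_codes, 0, lookback_days)
    return pd.DataFrame({"art": art, "infertility": inf})


def build_cohort(
    deliveries: pd.DataFrame,
    diagnoses: pd.DataFrame,
    code_lists: dict[str, CodeList],
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    mb_tolerance_days: int = 0,
) -> pd.DataFrame:
    """Assemble the per-delivery analysis table.

    Returns one row per delivery with columns delivery_id, patient_id,
    delivery_date, maternal_age, mb, art, infertility.
    """
    if deliveries.empty:
        raise ValueError("delivery table is empty")
    if deliveries["delivery_id"].duplicated().any():
        raise ValueError("delivery_id values are not unique")
    deliveries = deliveries.assign(delivery_date=_as_datetime(deliveries["delivery_date"]))
    mb = assign_mb(deliveries, diagnoses, code_lists["MB"], mb_tolerance_days)
    cov = assign_art_infertility(
        deliveries, diagnoses, code_lists["ART"], code_lists["INFERTILITY"], lookback_days
    )
    out = deliveries[["delivery_id", "patient_id", "delivery_date", "maternal_age"]].copy()
    out["mb"] = mb.to_numpy()
    out["art"] = cov["art"].to_numpy()
    out["infertility"] = cov["infertility"].to_numpy()
    return out


def percentage(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage rounded for presentation; 0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, ndigits)


def summarize_cohort(
    cohort: pd.DataFrame,
    exposure_matrix,
    fertility_ids,
) -> pd.DataFrame:
    """Cohort summary over four strata: all deliveries, no medication
    exposure, any medication exposure, fertility-medication exposure.

    ``exposure_matrix`` is the unfiltered ExposureMatrix; fertility
    exposure is any exposure among ``fertility_ids`` columns present.
    Counts, percentages (2 dp) and maternal age mean (SD) per stratum.
    """
    frame = exposure_matrix.frame.reindex(cohort["delivery_id"], fill_value=0)
    any_exp = frame.to_numpy().any(axis=1)
    fert_cols = [m for m in fertility_ids if m in frame.columns]
    fert_exp = frame[fert_cols].to_numpy().any(axis=1) if fert_cols else np.zeros(len(frame), bool)

    strata = {
        "all": np.ones(len(cohort), bool),
        "no_exposure": ~any_exp,
        "any_exposure": any_exp,
        "fertility_exposure": fert_exp,
    }
    rows = []
    for label, mask in strata.items():
        sub = cohort[mask]
        n = len(sub)
        row = {"stratum": label, "n": n}
        for col in ("mb", "art", "infertility"):
            cnt = int(sub[col].sum()) if n else 0
            row[f"{col}_n"] = cnt
            row[f"{col}_pct"] = percentage(cnt, n)
        row["age_mean"] = round(float(sub["maternal_age"].mean()), 1) if n else float("nan")
        row["age_sd"] = round(float(sub["maternal_age"].std(ddof=1)), 1) if n > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
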