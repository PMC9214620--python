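"""Ingredient mapping, exposure windowing and the binary exposure matrix.

Exposure is defined by prescription date only: any order of an ingredient
falling 275 to 215 days before the delivery date (inclusive on both ends)
marks that delivery as exposed to that ingredient.  The window brackets
conception and the early first trimester for a term pregnancy, which is
where fertility medications concentrate.  Dose, route and duration are out
of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: exposure window, in days before delivery: (farthest, nearest)
DEFAULT_WINDOW = (275, 215)
#: minimum distinct exposed patients for a medication to be screened
DEFAULT_MIN_PATIENTS = 5


@dataclass(frozen=True)
class ExposureMatrix:
    """Delivery × medication binary exposure matrix.

    ``frame`` is indexed by delivery_id with one 0/1 column per
    medication; ``patients`` maps each delivery_id to its patient_id so
    per-medication exposed-patient counts use distinct patients, not
    deliveries.  ``threshold`` is set once :func:`filter_min_patients` has
    been applied; ``m`` (the Bonferroni family size) is the retained
    column count.
    """

    frame: pd.DataFrame
    patients: pd.Series
    threshold: int | None = None

    @property
    def medication_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def m(self) -> int:
        return self.frame.shape[1]

    def patient_counts(self) -> pd.Series:
        """Distinct exposed patients per medication."""
        pats = self.patients.reindex(self.frame.index)
        counts = {}
        for med in self.frame.columns:
            exposed = self.frame[med].to_numpy().astype(bool)
            counts[med] = int(pats[exposed].nunique())
        return pd.Series(counts, name="n_patients", dtype="int64")

    def any_exposure(self) -> pd.Series:
        return self.frame.any(axis=1)


def map_orders(orders: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Attach ingredient-level medication_id to raw orders.

    Matching is exact and case-insensitive on the annotation's name set
    (brand and generic names of one ingredient share a medication_id).
    Unmatched orders are excluded and their count logged and recorded in
    ``result.attrs["n_unmatched"]``.
    """
    key = annotations["name"].str.strip().str.lower()
    dup = key[key.duplicated()]
    if not dup.empty:
        collisions = annotations.loc[key.isin(dup), ["medication_id", "name"]]
        ambiguous = collisions.groupby(collisions["name"].str.lower())["medication_id"].nunique()
        if (ambiguous > 1).any():
            raise ValueError(
                "annotation names mapping to more than one medication_id: "
                f"{sorted(ambiguous[ambiguous > 1].index)}"
            )
    lookup = dict(zip(key, annotations["medication_id"]))
    mapped = orders.copy()
    mapped["medication_id"] = orders["drug_name"].str.strip().str.lower().map(lookup)
    n_unmatched = int(mapped["medication_id"].isna().sum())
    if n_unmatched:
        logger.info("excluded %d orders with unmatched drug names", n_unmatched)
    mapped = mapped.dropna(subset=["medication_id"]).reset_index(drop=True)
    mapped.attrs["n_unmatched"] = n_unmatched
    return mapped


def window_exposure(
    cohort: pd.DataFrame,
    mapped_orders: pd.DataFrame,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> ExposureMatrix:
    """Build the unfiltered binary exposure matrix.

    entry(delivery, medication) = 1 iff the delivery's patient has at
    least one order of that medication dated within [delivery − far,
    delivery − near] days, both endpoints inclusive.  Orders dated after
    the delivery draw a warning and are ignored.
    """
    far, near = window
    if far <= near:
        raise ValueError(f"window must satisfy far > near days-before-delivery, got {window}")
    if cohort["delivery_id"].duplicated().any():
        raise ValueError("cohort rows are not unique on delivery_id")

    cohort = cohort.copy()
    cohort["delivery_date"] = pd.to_datetime(cohort["delivery_date"], format="mixed")
    patients = cohort.set_index("delivery_id")["patient_id"]

    if mapped_orders.empty:
        frame = pd.DataFrame(index=patients.index, dtype="int8")
        frame.index.name = "delivery_id"
        return ExposureMatrix(frame, patients)

    orders = mapped_orders.copy()
    orders["order_date"] = pd.to_datetime(orders["order_date"], format="mixed")
    merged = cohort[["delivery_id", "patient_id", "delivery_date"]].merge(
        orders[["patient_id", "medication_id", "order_date"]], on="patient_id", how="inner"
    )
    days_before = (merged["delivery_date"] - merged["order_date"]).dt.days
    n_after = int((days_before < 0).sum())
    if n_after:
        warnings.warn(f"ignored {n_after} orders dated after the delivery", stacklevel=2)
    hits = merged[(days_before >= near) & (days_before <= far)]

    meds = sorted(orders["medication_id"].unique())
    frame = (
        hits.assign(one=1)
        .pivot_table(index="delivery_id", columns="medication_id", values="one", aggfunc="max", fill_value=0)
        .reindex(index=patients.index, columns=meds, fill_value=0)
        .astype("int8")
    )
    frame.columns.name = None
    return ExposureMatrix(frame, patients)


def filter_min_patients(
    matrix: ExposureMatrix, threshold: int = DEFAULT_MIN_PATIENTS
) -> ExposureMatrix:
    """Drop medications exposed in fewer than ``threshold`` distinct patients.

    The retained column count fixes the Bonferroni family size for the
    screen.  Idempotent at a given threshold.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = matrix.patient_counts()
    keep = [m for m in matrix.frame.columns if counts[m] >= threshold]
    return ExposureMatrix(matrix.frame[keep], matrix.patients, threshold=threshold)
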