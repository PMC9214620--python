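"""Gold-standard validation of the screen's significance calls.

The screen is scored as a binary classifier: a positive call is a
significant medication (nominal or Bonferroni mode), truth is membership
in the fertility-medication gold standard.  Metrics with a zero
denominator are reported as undefined (None), never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

MODES = ("nominal", "bonferroni")
_FLAG = {"nominal": "sig_nominal", "bonferroni": "sig_bonf"}
METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricBundle:
    """sensitivity, specificity, accuracy, precision, F1 in [0, 1];
    None where the defining denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        """Presentation rounding.

        F1 is recomputed from the rounded precision and sensitivity, the
        convention of published performance tables in this setting (full
        precision stays available on the bundle itself).
        """
        out = {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }
        p, s = out["precision"], out["sensitivity"]
        if p is not None and s is not None and (p + s) > 0:
            out["f1"] = round(2 * p * s / (p + s), ndigits)
        return out


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricBundle:
    """Classification metrics from a confusion matrix.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    accuracy = (tp+tn)/total; precision = tp/(tp+fp);
    F1 = 2·precision·sensitivity/(precision+sensitivity).
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricBundle(sens, spec, acc, prec, f1)


def score_screen(
    results: pd.DataFrame, gold_ids: Iterable[str], mode: str = "nominal"
) -> ConfusionMatrix:
    """Tally the screen's calls against the gold standard.

    Every scored medication contributes to exactly one cell; gold ids not
    present among the scored medications are an error.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    gold = set(gold_ids)
    scored = set(results["medication_id"])
    missing = sorted(gold - scored)
    if missing:
        raise ValueError(f"gold-standard ids not among scored medications: {missing}")
    called = set(results.loc[results[_FLAG[mode]] == 1, "medication_id"])
    tp = len(called & gold)
    fp = len(called - gold)
    fn = len(gold - called)
    tn = len(scored - called - gold)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def performance_table(
    screens: dict[str, pd.DataFrame], gold_ids: Iterable[str], ndigits: int = 2
) -> pd.DataFrame:
    """Model × P-mode performance table (one row per screen per mode).

    ``screens`` maps model labels to result frames; rows carry the raw
    confusion counts and the five metrics rounded for presentation.
    """
    rows = []
    for label, results in screens.items():
        for mode in MODES:
            cm = score_screen(results, gold_ids, mode)
            metrics = compute_metrics(cm).rounded(ndigits)
            rows.append({
                "model": label, "p_mode": mode,
                "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                **metrics,
            })
    return pd.DataFrame(rows)
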