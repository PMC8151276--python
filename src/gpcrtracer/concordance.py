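"""Overlap analysis between model predictions and screen confirmations.

Both sides are binary scaffold x family matrices; cells are tallied into a
2x2 table and summarized with the shared accuracy/sensitivity/specificity
formulas. A threshold sweep over the probability cutoff selects the value
maximizing balanced accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from gpcrtracer.classifier import binary_metrics
from gpcrtracer.errors import SchemaError
from gpcrtracer.promiscuity import ProbabilityProfile, profile_matrix

DEFAULT_FOLD_THRESHOLD = 1.5


@dataclass(frozen=True)
class ConcordanceTable:
    """Cellwise 2x2 tally of predictions against confirmations."""

    predictions: pd.DataFrame
    confirmations: pd.DataFrame
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_cells(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return binary_metrics(self.tp, self.fp, self.tn, self.fn)["accuracy"]

    @property
    def sensitivity(self) -> float:
        return binary_metrics(self.tp, self.fp, self.tn, self.fn)["sensitivity"]

    @property
    def specificity(self) -> float:
        return binary_metrics(self.tp, self.fp, self.tn, self.fn)["specificity"]

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def positive_confirmation_rate(self) -> float:
        """Percent of predicted positives confirmed by the screen."""
        predicted_positive = self.tp + self.fp
        if predicted_positive == 0:
            return float("nan")
        return 100.0 * self.tp / predicted_positive

    def report(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def consolidate_screen(
    results: pd.DataFrame,
    construct_family_map: Mapping[str, str],
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    scaffolds: list[str] | None = None,
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse screen results to a binary scaffold x family matrix.

    A family cell is positive iff any member construct, any candidate
    tracer, at any tested concentration reaches the fold threshold. The
    ``scaffold`` column groups tracer candidates derived from one parental
    compound. Unmapped constructs are excluded with a warning.
    """
    needed = {"scaffold", "construct", "fold_response"}
    missing = needed - set(results.columns)
    if missing:
        raise SchemaError(f"screen results missing columns: {sorted(missing)}")

    rows = results.copy()
    unmapped = sorted(set(rows["construct"]) - set(construct_family_map))
    if unmapped:
        warnings.warn(f"excluding unmapped constructs: {unmapped}", stacklevel=2)
        rows = rows[~rows["construct"].isin(unmapped)]
    rows["family"] = rows["construct"].map(construct_family_map)

    scaffold_index = scaffolds if scaffolds is not None else sorted(rows["scaffold"].unique())
    family_index = families if families is not None else sorted(rows["family"].unique())
    matrix = pd.DataFrame(0, index=scaffold_index, columns=family_index, dtype=int)
    hits = rows[rows["fold_response"] >= threshold]
    for scaffold, family in zip(hits["scaffold"], hits["family"]):
        if scaffold in matrix.index and family in matrix.columns:
            matrix.at[scaffold, family] = 1
    return matrix


def apply_overrides(
    confirmations: pd.DataFrame, overrides: pd.DataFrame
) -> pd.DataFrame:
    """Merge curated confirmations (columns: scaffold, family, confirmed)."""
    out = confirmations.copy()
    for _, row in overrides.iterrows():
        scaffold, family = row["scaffold"], row["family"]
        if scaffold not in out.index or family not in out.columns:
            raise SchemaError(
                f"override ({scaffold!r}, {family!r}) outside the matrix"
            )
        out.at[scaffold, family] = int(row["confirmed"])
    return out


def overlap(predictions: pd.DataFrame, confirmations: pd.DataFrame) -> ConcordanceTable:
    """Cellwise 2x2 tally; matrices must share shape and labels."""
    if predictions.shape != confirmations.shape:
        raise SchemaError(
            f"shape mismatch: {predictions.shape} vs {confirmations.shape}"
        )
    if list(predictions.index) != list(confirmations.index) or list(
        predictions.columns
    ) != list(confirmations.columns):
        raise SchemaError("prediction and confirmation labels differ")
    p = predictions.to_numpy().astype(bool)
    c = confirmations.to_numpy().astype(bool)
    return ConcordanceTable(
        predictions=predictions,
        confirmations=confirmations,
        tp=int((p & c).sum()),
        fp=int((p & ~c).sum()),
        fn=int((~p & c).sum()),
        tn=int((~p & ~c).sum()),
    )


def table_from_counts(
    predicted_positive: int,
    confirmed_positive: int,
    predicted_negative: int,
    confirmed_negative: int,
) -> ConcordanceTable:
    """2x2 table from marginal counts (predicted and confirmed-within)."""
    tp = confirmed_positive
    fp = predicted_positive - confirmed_positive
    tn = confirmed_negative
    fn = predicted_negative - confirmed_negative
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confirmed counts exceed predicted counts")
    return ConcordanceTable(
        predictions=pd.DataFrame(), confirmations=pd.DataFrame(),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def threshold_sweep(
    profiles: list[ProbabilityProfile],
    confirmations: pd.DataFrame,
    thresholds: list[float],
) -> tuple[dict[float, ConcordanceTable], float]:
    """Concordance per candidate probability threshold and the best one.

    Selection criterion is balanced accuracy (mean of sensitivity and
    specificity); ties break toward the lower threshold.
    """
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    families = list(confirmations.columns)
    results: dict[float, ConcordanceTable] = {}
    for t in thresholds:
        predictions = profile_matrix(profiles, families, threshold=t)
        predictions = predictions.reindex(index=confirmations.index)
        if predictions.isna().any().any():
            raise SchemaError("profiles do not cover all scaffolds")
        results[float(t)] = overlap(predictions.astype(int), confirmations)

    def criterion(t: float) -> tuple[float, float]:
        value = results[t].balanced_accuracy
        return ((-value if not np.isnan(value) else np.inf), t)

    best = min(results, key=criterion)
    return results, best
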