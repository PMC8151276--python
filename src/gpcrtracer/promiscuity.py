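"""Multi-family interaction prediction from classification probabilities.

A compound's per-family class probabilities (percent scale, summing to 100)
are thresholded — inclusively, at 4% by default — to flag candidate
promiscuous interactions beyond the single top-1 family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gpcrtracer.classifier import FamilyClassifier
from gpcrtracer.errors import ConfigurationError, SchemaError

DEFAULT_THRESHOLD_PERCENT = 4.0

_SUM_TOLERANCE = 1e-6


@dataclass(frozen=True)
class ProbabilityProfile:
    """Per-compound family probabilities on the percent scale."""

    compound_id: str
    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 100.0) > _SUM_TOLERANCE:
            raise ConfigurationError(
                f"profile for {self.compound_id!r} sums to {total}, not 100"
            )

    @classmethod
    def from_fractions(
        cls, compound_id: str, families, fractions
    ) -> "ProbabilityProfile":
        """Build from model probabilities on the 0..1 scale."""
        probs = {str(f): 100.0 * float(p) for f, p in zip(families, fractions)}
        return cls(compound_id=compound_id, probs=probs)


@dataclass(frozen=True)
class PredictionProfile:
    compound_id: str
    positive_families: frozenset[str]
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT


def predict_profile(
    profile: ProbabilityProfile,
    threshold: float = DEFAULT_THRESHOLD_PERCENT,
) -> PredictionProfile:
    """Flag every family whose probability is at or above the threshold."""
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    positive = frozenset(f for f, p in profile.probs.items() if p >= threshold)
    return PredictionProfile(
        compound_id=profile.compound_id,
        positive_families=positive,
        threshold_percent=threshold,
    )


def profile_matrix(
    profiles: list[ProbabilityProfile],
    families: list[str],
    threshold: float = DEFAULT_THRESHOLD_PERCENT,
) -> pd.DataFrame:
    """Binary compound x family call matrix at the given threshold."""
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    family_set = set(families)
    data = np.zeros((len(profiles), len(families)), dtype=int)
    ids = []
    for i, profile in enumerate(profiles):
        if set(profile.probs) != family_set:
            raise SchemaError(
                f"profile {profile.compound_id!r} covers a different family set"
            )
        ids.append(profile.compound_id)
        for j, fam in enumerate(families):
            if profile.probs[fam] >= threshold:
                data[i, j] = 1
    return pd.DataFrame(data, index=ids, columns=list(families))


def probability_table(profiles: list[ProbabilityProfile], families: list[str]) -> pd.DataFrame:
    """Compound x family percent-probability matrix (no thresholding)."""
    family_set = set(families)
    rows = []
    for profile in profiles:
        if set(profile.probs) != family_set:
            raise SchemaError(
                f"profile {profile.compound_id!r} covers a different family set"
            )
        rows.append([profile.probs[f] for f in families])
    return pd.DataFrame(rows, index=[p.compound_id for p in profiles], columns=list(families))


def profiles_from_classifier(
    clf: FamilyClassifier, matrix, compound_ids
) -> list[ProbabilityProfile]:
    """Percent-scale probability profiles for each row of the matrix."""
    proba = clf.predict_proba(np.asarray(matrix, dtype=float))
    return [
        ProbabilityProfile.from_fractions(str(cid), clf.class_labels, row)
        for cid, row in zip(compound_ids, proba)
    ]


def long_format(
    profiles: list[ProbabilityProfile],
    families: list[str],
    threshold: float = DEFAULT_THRESHOLD_PERCENT,
) -> pd.DataFrame:
    """Heatmap-ready long table {scaffold, family, probability, call}."""
    probs = probability_table(profiles, families)
    calls = profile_matrix(profiles, families, threshold=threshold)
    records = []
    for cid in probs.index:
        for fam in families:
            records.append(
                {
                    "scaffold": cid,
                    "family": fam,
                    "probability": probs.at[cid, fam],
                    "call": int(calls.at[cid, fam]),
                }
            )
    return pd.DataFrame(records)
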