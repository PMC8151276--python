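"""Raw interaction table -> balanced, stratified machine-learning dataset.

Stages: species/identifier/SMILES ingestion filtering, structure-level
deduplication per family, family-size thresholding, balanced per-family
selection, and a stratified train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from gpcrtracer.errors import PipelineError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["compound_id", "smiles", "receptor", "species", "family"]

DEFAULT_MIN_COMPOUNDS = 700
DEFAULT_N_PER_FAMILY = 530
DEFAULT_TRAIN_FRACTION = 0.70

_CANONICAL = "_canonical_smiles"


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES for a structure, or None if unparseable."""
    if not isinstance(smiles, str) or not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _require_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")


@dataclass(frozen=True)
class DatasetSplit:
    """Stratified train/test partition of a balanced dataset."""

    training: pd.DataFrame
    test: pd.DataFrame
    per_family_counts: dict[str, tuple[int, int]]
    seed: int

    def __post_init__(self) -> None:
        train_keys = set(zip(self.training["compound_id"], self.training["family"]))
        test_keys = set(zip(self.test["compound_id"], self.test["family"]))
        if train_keys & test_keys:
            raise PipelineError("training and test partitions overlap")

    def manifest(self) -> pd.DataFrame:
        """Single table with a ``partition`` column."""
        train = self.training.copy()
        train["partition"] = "train"
        test = self.test.copy()
        test["partition"] = "test"
        return pd.concat([train, test], ignore_index=True)


def filter_records(raw: pd.DataFrame, species: str = "human") -> pd.DataFrame:
    """Ingestion filter: human records with an id and a parseable structure.

    Drops non-matching species, missing/empty compound ids, and SMILES that
    fail to parse (the dropped-parse count is logged).
    """
    _require_schema(raw)
    out = raw.copy()
    out = out[out["species"].astype(str).str.lower() == species.lower()]
    has_id = out["compound_id"].notna() & (out["compound_id"].astype(str).str.len() > 0)
    out = out[has_id]

    canon = out["smiles"].map(canonical_smiles)
    n_bad = int(canon.isna().sum())
    if n_bad:
        logger.info("dropped %d records with unparseable SMILES", n_bad)
    out = out[canon.notna()].copy()
    out[_CANONICAL] = canon[canon.notna()]
    return out.reset_index(drop=True)


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (canonical structure, family) pair.

    A compound interacting with k families yields k records; within one
    family, all receptor-level rows and alternative SMILES spellings of the
    same structure collapse to the first occurrence.
    """
    _require_schema(records)
    out = records.copy()
    if _CANONICAL not in out.columns:
        canon = out["smiles"].map(canonical_smiles)
        if canon.isna().any():
            raise PipelineError("unparseable SMILES reached deduplicate; run filter_records first")
        out[_CANONICAL] = canon
    out = out.drop_duplicates(subset=[_CANONICAL, "family"], keep="first")
    return out.reset_index(drop=True)


def family_threshold_filter(
    records: pd.DataFrame, min_compounds: int = DEFAULT_MIN_COMPOUNDS
) -> pd.DataFrame:
    """Drop families with fewer than ``min_compounds`` unique compounds."""
    _require_schema(records)
    key = _CANONICAL if _CANONICAL in records.columns else "smiles"
    counts = records.groupby("family")[key].nunique()
    keep = counts[counts >= min_compounds].index
    out = records[records["family"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise PipelineError(
            f"no family reaches the minimum of {min_compounds} unique compounds"
        )
    return out


def balanced_select(
    records: pd.DataFrame,
    n_per_family: int = DEFAULT_N_PER_FAMILY,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform random selection of exactly ``n_per_family`` records per family."""
    _require_schema(records)
    rng = np.random.default_rng(seed)
    parts = []
    for family, group in records.groupby("family", sort=True):
        if len(group) < n_per_family:
            raise PipelineError(
                f"family {family!r} has {len(group)} records, "
                f"fewer than n_per_family={n_per_family}"
            )
        idx = rng.choice(len(group), size=n_per_family, replace=False)
        parts.append(group.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def stratified_split(
    selected: pd.DataFrame,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> DatasetSplit:
    """Per-family random split; floor(train_fraction * n) rows go to training."""
    _require_schema(selected)
    if not 0.0 < train_fraction <= 1.0:
        raise PipelineError("train_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    per_family: dict[str, tuple[int, int]] = {}
    for family, group in selected.groupby("family", sort=True):
        n_train = int(np.floor(train_fraction * len(group)))
        perm = rng.permutation(len(group))
        train_parts.append(group.iloc[np.sort(perm[:n_train])])
        test_parts.append(group.iloc[np.sort(perm[n_train:])])
        per_family[str(family)] = (n_train, len(group) - n_train)
    training = pd.concat(train_parts, ignore_index=True)
    if test_parts and sum(len(p) for p in test_parts):
        test = pd.concat(test_parts, ignore_index=True)
    else:
        test = selected.iloc[0:0].copy()
    return DatasetSplit(training=training, test=test, per_family_counts=per_family, seed=seed)


def build_dataset(
    raw: pd.DataFrame,
    min_compounds: int = DEFAULT_MIN_COMPOUNDS,
    n_per_family: int = DEFAULT_N_PER_FAMILY,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> DatasetSplit:
    """Run the full pipeline: filter, dedupe, threshold, balance, split."""
    records = filter_records(raw)
    records = deduplicate(records)
    records = family_threshold_filter(records, min_compounds=min_compounds)
    selected = balanced_select(records, n_per_family=n_per_family, seed=seed)
    return stratified_split(selected, train_fraction=train_fraction, seed=seed)
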