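"""Concatenated 758-position molecular fingerprint and variance filtering.

Layout of the vector, in order:

* positions 0..166 — MACCS structural keys (position 0 is the reserved,
  always-zero key of the public 167-position indexing convention);
* positions 167..245 — E-State atom-type counts (79 types, non-negative
  integers);
* positions 246..757 — FP4-style substructure bits evaluated from the
  vendored SMARTS pattern list (binary; unused tail positions stay zero).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter

from gpcrtracer.errors import EncodingError, SchemaError

MACCS_BITS = 167
ESTATE_BITS = 79
FP4_BITS = 512
TOTAL_BITS = MACCS_BITS + ESTATE_BITS + FP4_BITS  # 758

DEFAULT_FREQ_CUT = 95.0 / 5.0
DEFAULT_UNIQUE_CUT = 10.0


@lru_cache(maxsize=1)
def fp4_patterns() -> tuple[tuple[str, Chem.Mol], ...]:
    """Compiled (name, query) pairs for the FP4-style block, in file order."""
    text = (
        importlib.resources.files("gpcrtracer.data")
        .joinpath("fp4_patterns.smarts")
        .read_text()
    )
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        query = Chem.MolFromSmarts(smarts)
        if query is None:  # pragma: no cover - vendored file is validated
            raise ValueError(f"invalid vendored SMARTS {name}: {smarts}")
        out.append((name, query))
    if len(out) > FP4_BITS:  # pragma: no cover
        raise ValueError("more FP4 patterns than block positions")
    return tuple(out)


def column_labels() -> list[str]:
    """Stable labels for all 758 positions."""
    labels = [f"MACCS{i}" for i in range(MACCS_BITS)]
    labels += [f"ESTATE{i + 1}" for i in range(ESTATE_BITS)]
    names = [name for name, _ in fp4_patterns()]
    labels += [f"FP4_{names[i]}" if i < len(names) else f"FP4_pad{i}" for i in range(FP4_BITS)]
    return labels


def compute_fingerprint(smiles: str) -> np.ndarray:
    """Encode one SMILES as the 758-position concatenated vector."""
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        raise EncodingError(str(smiles))
    vec = np.zeros(TOTAL_BITS, dtype=np.int64)

    maccs = MACCSkeys.GenMACCSKeys(mol)
    for bit in maccs.GetOnBits():
        vec[bit] = 1

    counts, _sums = EStateFingerprinter.FingerprintMol(mol)
    vec[MACCS_BITS : MACCS_BITS + ESTATE_BITS] = counts.astype(np.int64)

    offset = MACCS_BITS + ESTATE_BITS
    for i, (_name, query) in enumerate(fp4_patterns()):
        if mol.HasSubstructMatch(query):
            vec[offset + i] = 1
    return vec


def fingerprint_matrix(smiles: Iterable[str]) -> pd.DataFrame:
    """Encode many SMILES; rows follow input order, columns are labelled."""
    rows = [compute_fingerprint(s) for s in smiles]
    data = np.vstack(rows) if rows else np.empty((0, TOTAL_BITS), dtype=np.int64)
    return pd.DataFrame(data, columns=column_labels())


def maccs_block(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Extract the binary MACCS block (first 167 columns) as an array."""
    arr = np.asarray(matrix)
    if arr.shape[1] < MACCS_BITS:
        raise SchemaError("matrix narrower than the MACCS block")
    return arr[:, :MACCS_BITS]


@dataclass(frozen=True)
class FeatureMask:
    """Columns retained by near-zero-variance filtering (training data only)."""

    retained_indices: tuple[int, ...]
    freq_cut: float = DEFAULT_FREQ_CUT
    unique_cut: float = DEFAULT_UNIQUE_CUT
    source_width: int = TOTAL_BITS

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.retained_indices)
        if any(i < 0 or i >= self.source_width for i in idx):
            raise SchemaError("mask indices out of range")
        object.__setattr__(self, "retained_indices", idx)

    def __len__(self) -> int:
        return len(self.retained_indices)


def _nzv_flags(column: np.ndarray, freq_cut: float, unique_cut: float) -> bool:
    """True if the column should be removed under the near-zero-variance rule."""
    values, counts = np.unique(column, return_counts=True)
    if len(values) <= 1:
        return True
    counts = np.sort(counts)[::-1]
    freq_ratio = counts[0] / counts[1]
    percent_unique = 100.0 * len(values) / len(column)
    return bool(freq_ratio > freq_cut and percent_unique < unique_cut)


def fit_nzv_mask(
    training_matrix: pd.DataFrame | np.ndarray,
    freq_cut: float = DEFAULT_FREQ_CUT,
    unique_cut: float = DEFAULT_UNIQUE_CUT,
) -> FeatureMask:
    """Fit the near-zero-variance mask on training rows only.

    A column is removed iff it is constant, or its frequency ratio (count of
    the most common value over the second most common) exceeds ``freq_cut``
    while its percent-unique (100 x distinct values / rows) is below
    ``unique_cut``.
    """
    arr = np.asarray(training_matrix)
    if arr.ndim != 2 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise SchemaError("training matrix must be non-empty and 2-D")
    retained = [
        j for j in range(arr.shape[1])
        if not _nzv_flags(arr[:, j], freq_cut, unique_cut)
    ]
    return FeatureMask(
        retained_indices=tuple(retained),
        freq_cut=freq_cut,
        unique_cut=unique_cut,
        source_width=arr.shape[1],
    )


def apply_mask(
    matrix: pd.DataFrame | np.ndarray, mask: FeatureMask
) -> pd.DataFrame | np.ndarray:
    """Subset columns to the mask, preserving mask order."""
    ncol = matrix.shape[1]
    if ncol != mask.source_width:
        raise SchemaError(
            f"matrix has {ncol} columns but mask was fit on {mask.source_width}"
        )
    idx = list(mask.retained_indices)
    if isinstance(matrix, pd.DataFrame):
        return matrix.iloc[:, idx]
    return np.asarray(matrix)[:, idx]
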