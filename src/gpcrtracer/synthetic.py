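"""Synthetic data generators for interaction tables and BRET plates.

The ligand generator builds family-clustered chemistry by decorating a
family-specific scaffold core with small substituents, so that compounds
within a family are structurally more similar to each other than to
compounds of other families. The plate generator produces donor/acceptor
emission pairs whose ratio carries a configurable specific signal over a
background BRET level.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from gpcrtracer.errors import ConfigurationError

RDLogger.DisableLog("rdApp.*")

#: Small substituent fragments attached to scaffold cores (first atom bonds).
SUBSTITUENTS: tuple[str, ...] = (
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "O", "OC", "N", "N(C)C",
    "C#N", "C(F)(F)F", "CO", "S(=O)(=O)N", "C(=O)OC", "C(=O)N", "OCC",
)

#: Species labels used for the non-human raw-table artifact records.
NONHUMAN_SPECIES: tuple[str, ...] = ("mouse", "rat")

#: Receptors simulated per family.
RECEPTORS_PER_FAMILY = 4

INTERACTION_COLUMNS = ["compound_id", "smiles", "receptor", "species", "family"]
PLATE_COLUMNS = [
    "plate", "well", "construct", "tracer", "concentration_nM",
    "condition", "donor_em", "acceptor_em",
]

#: Fixed donor emission (counts); acceptor = BRET x donor (+ noise).
DONOR_COUNTS = 1.0e6

TRACER_ALONE = "tracer_alone"
TRACER_PLUS_COMPETITOR = "tracer_plus_competitor"


def load_scaffold_library() -> dict[str, str]:
    """Return the vendored scaffold library as ``{name: smiles}``."""
    text = (
        importlib.resources.files("gpcrtracer.data")
        .joinpath("scaffolds.txt")
        .read_text()
    )
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smiles = line.split("\t")
        out[name] = smiles
    return out


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SyntheticChemConfig:
    """Configuration for the family-clustered interaction-table generator."""

    n_families: int = 4
    compounds_per_family: int = 50
    scaffolds_per_family: int = 1
    substituent_pool_size: int = len(SUBSTITUENTS)
    promiscuous_fraction: float = 0.0
    duplicate_rate: float = 0.0
    nonhuman_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ConfigurationError("n_families must be >= 2")
        if self.compounds_per_family < 1:
            raise ConfigurationError("compounds_per_family must be >= 1")
        if self.scaffolds_per_family < 1:
            raise ConfigurationError("scaffolds_per_family must be >= 1")
        if not 1 <= self.substituent_pool_size <= len(SUBSTITUENTS):
            raise ConfigurationError(
                f"substituent_pool_size must be in [1, {len(SUBSTITUENTS)}]"
            )
        _check_fraction("promiscuous_fraction", self.promiscuous_fraction)
        _check_fraction("duplicate_rate", self.duplicate_rate)
        _check_fraction("nonhuman_rate", self.nonhuman_rate)


@dataclass(frozen=True)
class SyntheticBretConfig:
    """Configuration for plate and saturation-series generators."""

    true_fold_response: float = 2.0
    background_bret: float = 0.1
    noise_sd: float = 0.0
    n_replicates: int = 2
    bmax: float = 0.2
    ec50: float = 50.0
    concentrations: tuple[float, ...] = (1000.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fold_response <= 0:
            raise ConfigurationError("true_fold_response must be positive")
        if self.background_bret <= 0:
            raise ConfigurationError("background_bret must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.bmax <= 0 or self.ec50 <= 0:
            raise ConfigurationError("bmax and ec50 must be positive")
        concs = tuple(float(c) for c in self.concentrations)
        if any(c <= 0 for c in concs):
            raise ConfigurationError("concentrations must be strictly positive")
        if list(concs) != sorted(concs) and list(concs) != sorted(concs, reverse=True):
            raise ConfigurationError("concentrations must be sorted")
        object.__setattr__(self, "concentrations", concs)


def family_names(n_families: int) -> list[str]:
    return [f"FAM{i + 1:02d}" for i in range(n_families)]


def receptor_names(family: str) -> list[str]:
    return [f"{family}_R{j + 1}" for j in range(RECEPTORS_PER_FAMILY)]


def family_map_table(n_families: int) -> pd.DataFrame:
    """Receptor -> family mapping covering every simulated receptor."""
    rows = [
        {"receptor": r, "family": fam}
        for fam in family_names(n_families)
        for r in receptor_names(fam)
    ]
    return pd.DataFrame(rows)


def _attach(mol: Chem.Mol, substituent: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Bond a substituent fragment to a random C-H carbon of ``mol``."""
    sub = Chem.MolFromSmiles(substituent)
    candidates = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    ]
    if not candidates:
        return None
    idx = int(rng.choice(candidates))
    combo = Chem.RWMol(Chem.CombineMols(mol, sub))
    combo.AddBond(idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _decorate(
    scaffold: Chem.Mol,
    pool: Sequence[str],
    rng: np.random.Generator,
    n_substituents: int,
) -> Chem.Mol:
    mol = scaffold
    for _ in range(n_substituents):
        nxt = _attach(mol, pool[int(rng.integers(len(pool)))], rng)
        if nxt is not None:
            mol = nxt
    return mol


def _unique_compound(
    scaffold: Chem.Mol,
    pool: Sequence[str],
    rng: np.random.Generator,
    seen: set[str],
    max_attempts: int = 50,
) -> str:
    """Generate a decorated canonical SMILES not yet in ``seen``."""
    for _ in range(max_attempts):
        n_subs = int(rng.integers(1, 4))
        smi = Chem.MolToSmiles(_decorate(scaffold, pool, rng, n_subs))
        if smi not in seen:
            return smi
    # fallback: grow a methyl chain until novel (guaranteed to terminate)
    mol = _decorate(scaffold, pool, rng, 3)
    smi = Chem.MolToSmiles(mol)
    while smi in seen:
        grown = _attach(mol, "C", rng)
        if grown is None:  # pragma: no cover - scaffolds always carry C-H
            raise RuntimeError("cannot extend scaffold")
        mol = grown
        smi = Chem.MolToSmiles(mol)
    return smi


def generate_interaction_table(config: SyntheticChemConfig) -> pd.DataFrame:
    """Generate a raw GLASS-like interaction table.

    Each family draws its compounds from family-specific scaffold cores with
    randomized substituents; canonical-structure uniqueness is enforced
    within a family. A ``promiscuous_fraction`` of compounds receives an
    extra record in a second family; ``duplicate_rate`` appends exact
    duplicate rows and ``nonhuman_rate`` appends extra rows with a non-human
    species tag (the redundancy artifacts removed by downstream filtering).
    Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    library = list(load_scaffold_library().values())
    pool = SUBSTITUENTS[: config.substituent_pool_size]
    families = family_names(config.n_families)

    # Assign scaffold cores to families; distinct across families while
    # the library lasts, cycling afterwards.
    order = rng.permutation(len(library))
    assignments: dict[str, list[Chem.Mol]] = {}
    cursor = 0
    for fam in families:
        mols = []
        for _ in range(config.scaffolds_per_family):
            smi = library[order[cursor % len(library)]]
            cursor += 1
            mols.append(Chem.MolFromSmiles(smi))
        assignments[fam] = mols

    rows: list[dict] = []
    counter = 0
    for fam in families:
        seen: set[str] = set()
        receptors = receptor_names(fam)
        for _ in range(config.compounds_per_family):
            scaffold = assignments[fam][int(rng.integers(len(assignments[fam])))]
            smi = _unique_compound(scaffold, pool, rng, seen)
            seen.add(smi)
            counter += 1
            cid = f"CPD{counter:06d}"
            receptor = receptors[int(rng.integers(len(receptors)))]
            rows.append(
                {
                    "compound_id": cid,
                    "smiles": smi,
                    "receptor": receptor,
                    "species": "human",
                    "family": fam,
                }
            )
            if rng.random() < config.promiscuous_fraction:
                other = families[int(rng.integers(config.n_families - 1))]
                if other == fam:
                    other = families[-1]
                rows.append(
                    {
                        "compound_id": cid,
                        "smiles": smi,
                        "receptor": receptor_names(other)[
                            int(rng.integers(RECEPTORS_PER_FAMILY))
                        ],
                        "species": "human",
                        "family": other,
                    }
                )

    base = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)

    extras: list[pd.DataFrame] = [base]
    if config.duplicate_rate > 0:
        take = rng.random(len(base)) < config.duplicate_rate
        extras.append(base.loc[take])
    if config.nonhuman_rate > 0:
        take = rng.random(len(base)) < config.nonhuman_rate
        nonhuman = base.loc[take].copy()
        nonhuman["species"] = [
            NONHUMAN_SPECIES[int(rng.integers(len(NONHUMAN_SPECIES)))]
            for _ in range(len(nonhuman))
        ]
        extras.append(nonhuman)
    return pd.concat(extras, ignore_index=True)


def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    return [f"{rows[(i // 24) % len(rows)]}{i % 24 + 1:02d}" for i in range(n)]


def generate_bret_plate(
    config: SyntheticBretConfig,
    truth: Mapping[tuple[str, str], bool],
) -> pd.DataFrame:
    """Simulate a competitive-displacement plate.

    For bound (construct, tracer) pairs, tracer-alone wells carry an expected
    BRET of ``true_fold_response x background_bret`` while competitor wells
    carry ``background_bret``; unbound pairs sit at background in both
    conditions. Gaussian noise with sd ``noise_sd`` (in BRET units) acts on
    the acceptor channel; the donor channel is fixed at ``DONOR_COUNTS``.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    widx = 0
    for (construct, tracer), bound in truth.items():
        for conc in config.concentrations:
            for condition in (TRACER_ALONE, TRACER_PLUS_COMPETITOR):
                expected = config.background_bret
                if bound and condition == TRACER_ALONE:
                    expected = config.true_fold_response * config.background_bret
                for _ in range(config.n_replicates):
                    bret = expected + rng.normal(0.0, config.noise_sd)
                    rows.append(
                        {
                            "plate": 1,
                            "well": None,
                            "construct": construct,
                            "tracer": tracer,
                            "concentration_nM": conc,
                            "condition": condition,
                            "donor_em": DONOR_COUNTS,
                            "acceptor_em": bret * DONOR_COUNTS,
                        }
                    )
                    widx += 1
    plate = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    plate["well"] = _well_ids(len(plate))
    return plate


def generate_saturation_series(
    config: SyntheticBretConfig,
    construct: str = "CONSTRUCT",
    tracer: str = "TRACER",
) -> pd.DataFrame:
    """Simulate a saturation-binding dose series with paired background wells.

    Tracer-alone wells follow ``background + bmax*c/(ec50 + c)`` and paired
    competitor wells carry background only, both with Gaussian noise.
    """
    if len(config.concentrations) < 4:
        raise ConfigurationError("saturation series needs >= 4 concentrations")
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for conc in config.concentrations:
        specific = config.bmax * conc / (config.ec50 + conc)
        for condition, expected in (
            (TRACER_ALONE, config.background_bret + specific),
            (TRACER_PLUS_COMPETITOR, config.background_bret),
        ):
            for _ in range(config.n_replicates):
                bret = expected + rng.normal(0.0, config.noise_sd)
                rows.append(
                    {
                        "plate": 1,
                        "well": None,
                        "construct": construct,
                        "tracer": tracer,
                        "concentration_nM": conc,
                        "condition": condition,
                        "donor_em": DONOR_COUNTS,
                        "acceptor_em": bret * DONOR_COUNTS,
                    }
                )
    table = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    table["well"] = _well_ids(len(table))
    return table
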