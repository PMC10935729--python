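"""Molecular primitives.

SMILES canonicalization, Bemis–Murcko scaffolds, circular (ECFP-style)
fingerprints with Tanimoto similarity, physicochemical descriptor
featurization, and z-score feature scaling. Everything downstream (scoring,
the surrogate, the synthetic oracles) is built on these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "ScaffoldKey",
    "Fingerprint",
    "DescriptorVector",
    "FeatureScaler",
    "canonicalize",
    "murcko_scaffold",
    "ecfp",
    "tanimoto",
    "mean_pairwise_similarity",
    "featurize",
    "descriptor_matrix",
    "fit_scaler",
    "apply_scaler",
    "read_smi",
    "write_smi",
    "read_smiles_csv",
    "FAST_DESCRIPTORS",
    "ORACLE_DESCRIPTORS",
]


@dataclass
class Molecule:
    """A generated or loaded compound.

    ``valid`` is False when the SMILES cannot be parsed; in that case
    ``canonical_smiles`` is None and the record is retained so downstream
    scoring can assign it a zero reward rather than dropping it silently.
    ``gen_index`` is the position in generation order and is used as the
    stable tie-break during acquisition.
    """

    raw_smiles: str
    canonical_smiles: str | None
    valid: bool
    gen_index: int = 0
    _mol: object = field(default=None, repr=False, compare=False)

    def rdkit_mol(self) -> Chem.Mol:
        if not self.valid:
            raise ValueError(f"invalid molecule: {self.raw_smiles!r}")
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.canonical_smiles)
        return self._mol


@dataclass(frozen=True)
class ScaffoldKey:
    """Canonical Murcko scaffold; the empty string is the acyclic sentinel."""

    scaffold_smiles: str


@dataclass
class Fingerprint:
    bits: np.ndarray  # uint8 vector of length nbits
    radius: int
    nbits: int


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: tuple[str, ...]


@dataclass
class FeatureScaler:
    """Per-column z-scaler that drops invariant (zero-sd) columns."""

    mean: np.ndarray
    sd: np.ndarray
    kept_columns: np.ndarray


def canonicalize(smiles: str, gen_index: int = 0) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Never raises: unparseable input yields ``valid=False``.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        return Molecule(raw_smiles=smiles, canonical_smiles=None, valid=False,
                        gen_index=gen_index)
    return Molecule(raw_smiles=smiles, canonical_smiles=Chem.MolToSmiles(mol),
                    valid=True, gen_index=gen_index, _mol=mol)


def murcko_scaffold(mol: Molecule) -> ScaffoldKey:
    """Canonical Bemis–Murcko framework (ring systems plus linkers).

    Acyclic molecules map to the empty-string sentinel; all of them count as
    a single scaffold key.
    """
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol.rdkit_mol())
    if scaffold:
        scaffold = Chem.MolToSmiles(Chem.MolFromSmiles(scaffold))
    return ScaffoldKey(scaffold)


def ecfp(mol: Molecule, radius: int = 2, nbits: int = 1024) -> Fingerprint:
    """Hashed circular fingerprint (radius 2 / 1024 bits = the common ECFP4)."""
    if nbits <= 0 or nbits & (nbits - 1):
        raise ValueError(f"nbits must be a power of two, got {nbits}")
    gen = _morgan_generator(radius, nbits)
    bits = gen.GetFingerprintAsNumPy(mol.rdkit_mol()).astype(np.uint8)
    return Fingerprint(bits=bits, radius=radius, nbits=nbits)


_MORGAN_CACHE: dict[tuple[int, int], object] = {}


def _morgan_generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _MORGAN_CACHE:
        _MORGAN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits)
    return _MORGAN_CACHE[key]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard coefficient |a∩b|/|a∪b|.

    Convention: 1.0 for two empty fingerprints (identical ⇒ 1), 0.0 when
    exactly one is empty.
    """
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} != {b.nbits}")
    inter = int(np.sum((a.bits > 0) & (b.bits > 0)))
    union = int(np.sum((a.bits > 0) | (b.bits > 0)))
    if union == 0:
        return 1.0
    return inter / union


def mean_pairwise_similarity(mols: Sequence[Molecule], radius: int = 2,
                             nbits: int = 1024) -> float:
    """Mean Tanimoto similarity over all unordered pairs (ECFP4 by default)."""
    if len(mols) < 2:
        raise ValueError("mean pairwise similarity needs at least 2 molecules")
    bits = np.stack([ecfp(m, radius, nbits).bits for m in mols]).astype(np.float64)
    pop = bits.sum(axis=1)
    inter = bits @ bits.T
    union = pop[:, None] + pop[None, :] - inter
    iu = np.triu_indices(len(mols), k=1)
    inter, union = inter[iu], union[iu]
    sims = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return float(sims.mean())


# Descriptor sets. "full" is the complete RDKit physchem suite (~210 values);
# "fast" is a compact subset of cheap descriptors adequate for desk-scale runs;
# "oracle" is the fixed six-descriptor profile the synthetic oracles are
# defined on (MW, logP, ring count, HBD, HBA, TPSA).
FAST_DESCRIPTORS: tuple[tuple[str, object], ...] = (
    ("MolWt", Descriptors.MolWt),
    ("MolLogP", Crippen.MolLogP),
    ("RingCount", rdMolDescriptors.CalcNumRings),
    ("NumHDonors", rdMolDescriptors.CalcNumHBD),
    ("NumHAcceptors", rdMolDescriptors.CalcNumHBA),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("NumRotatableBonds", rdMolDescriptors.CalcNumRotatableBonds),
    ("NumAromaticRings", rdMolDescriptors.CalcNumAromaticRings),
    ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
    ("HeavyAtomCount", lambda m: float(m.GetNumHeavyAtoms())),
    ("NumHeteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
)

ORACLE_DESCRIPTORS: tuple[str, ...] = (
    "MolWt", "MolLogP", "RingCount", "NumHDonors", "NumHAcceptors", "TPSA",
)

_FULL_NAMES: tuple[str, ...] | None = None


def _full_descriptor_names() -> tuple[str, ...]:
    global _FULL_NAMES
    if _FULL_NAMES is None:
        _FULL_NAMES = tuple(name for name, _ in Descriptors.descList)
    return _FULL_NAMES


def _descriptor_row(mol: Chem.Mol, descriptor_set: str) -> tuple[np.ndarray, tuple[str, ...]]:
    if descriptor_set == "full":
        values = Descriptors.CalcMolDescriptors(mol)
        names = _full_descriptor_names()
        row = np.array([values[n] for n in names], dtype=np.float64)
    elif descriptor_set in ("fast", "oracle"):
        funcs = FAST_DESCRIPTORS
        if descriptor_set == "oracle":
            funcs = tuple(f for f in FAST_DESCRIPTORS if f[0] in ORACLE_DESCRIPTORS)
        names = tuple(n for n, _ in funcs)
        row = np.array([f(mol) for _, f in funcs], dtype=np.float64)
    else:
        raise ValueError(f"unknown descriptor set {descriptor_set!r}")
    # A handful of RDKit descriptors can be NaN/inf on exotic structures
    # (e.g. partial-charge descriptors); zero them so the invariant holds.
    row[~np.isfinite(row)] = 0.0
    return row, names


def featurize(mols: Sequence[Molecule], descriptor_set: str = "full") -> list[DescriptorVector]:
    """Deterministic, fixed-order physicochemical descriptor vectors."""
    out = []
    for m in mols:
        row, names = _descriptor_row(m.rdkit_mol(), descriptor_set)
        out.append(DescriptorVector(values=row, names=names))
    return out


def descriptor_matrix(mols: Sequence[Molecule], descriptor_set: str = "fast") -> np.ndarray:
    """Stacked descriptor rows (n_molecules × n_descriptors)."""
    return np.stack([_descriptor_row(m.rdkit_mol(), descriptor_set)[0] for m in mols])


def fit_scaler(matrix: np.ndarray) -> FeatureScaler:
    """Fit per-column mean/sd; columns with zero spread are dropped."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("scaler fitting needs a 2-D matrix with >= 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    kept = np.flatnonzero(sd > 1e-12)
    return FeatureScaler(mean=mean[kept], sd=sd[kept], kept_columns=kept)


def apply_scaler(scaler: FeatureScaler, matrix: np.ndarray) -> np.ndarray:
    if scaler is None:
        raise ValueError("scaler has not been fitted")
    matrix = np.asarray(matrix, dtype=np.float64)
    return (matrix[:, scaler.kept_columns] - scaler.mean) / scaler.sd


# ---------------------------------------------------------------------------
# I/O: .smi (one SMILES per line, optional tab-separated name) and CSV with a
# "smiles" column.

def read_smi(path: str | Path) -> list[Molecule]:
    mols = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            smiles = line.split("\t")[0].split()[0]
            mols.append(canonicalize(smiles, gen_index=i))
    return mols


def write_smi(path: str | Path, mols: Iterable[Molecule]) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write((m.canonical_smiles if m.valid else m.raw_smiles) + "\n")


def read_smiles_csv(path: str | Path, column: str = "smiles") -> list[Molecule]:
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"CSV {path} has no {column!r} column")
    return [canonicalize(s, gen_index=i) for i, s in enumerate(df[column])]
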