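"""SMILES handling, circular fingerprints with bit-to-environment tracking, and
Tanimoto similarity.

The fingerprint of record is the binary circular (Morgan) fingerprint: every
atom-centered environment up to a topological ``radius`` is hashed into a
fixed-width bit vector, and ``bit_info`` retains, for each on-bit, every
``(center_atom, radius)`` environment that set it.  That traceability is what
makes linear-model coefficients explainable as molecular substructures.
A layered fingerprint backend is available behind the same contract, but it
carries no ``bit_info`` and is therefore not traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import ConfigError, SmilesParseError

# RDKit logs every parse failure to stderr; errors are raised as exceptions here.
RDLogger.DisableLog("rdApp.error")

FINGERPRINT_KINDS = ("circular", "layered")


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`SmilesParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty or non-string input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical SMILES of ``smiles``.

    Any two SMILES of the same molecule (under RDKit's default sanitization
    and aromaticity model) map to the same output string, and the map is
    idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.
    """
    return Chem.MolToSmiles(mol_from_smiles(smiles))


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, canonical SMILES, optional natural-product class."""

    id: str
    smiles: str
    np_class: str | None = None

    @classmethod
    def from_smiles(cls, id: str, smiles: str, np_class: str | None = None) -> "MoleculeRecord":
        """Build a record, canonicalizing ``smiles`` (raises on parse failure)."""
        return cls(id=id, smiles=canonicalize_smiles(smiles), np_class=np_class)

    def to_mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


@dataclass(frozen=True)
class FingerprintConfig:
    """Fingerprint settings: kind, environment radius and bit-vector width.

    Defaults (circular, radius 2, 2048 bits) are the community-standard Morgan
    parameters for molecular machine learning.
    """

    kind: str = "circular"
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self):
        if self.kind not in FINGERPRINT_KINDS:
            raise ConfigError(f"unknown fingerprint kind {self.kind!r}; choose from {FINGERPRINT_KINDS}")
        if self.n_bits < 1:
            raise ConfigError(f"n_bits must be >= 1, got {self.n_bits}")
        if self.radius < 0:
            raise ConfigError(f"radius must be >= 0, got {self.radius}")


@dataclass(frozen=True)
class Fingerprint:
    """A sparse binary fingerprint.

    ``bits`` holds the on-bit indices in ``[0, n_bits)``.  For circular
    fingerprints ``bit_info`` maps each on-bit to every ``(center_atom,
    radius)`` environment hashing to it; for layered fingerprints it is
    ``None`` (not traceable).
    """

    bits: frozenset[int]
    n_bits: int
    bit_info: Mapping[int, tuple[tuple[int, int], ...]] | None = None
    config: FingerprintConfig | None = None

    def dense(self) -> np.ndarray:
        x = np.zeros(self.n_bits, dtype=np.uint8)
        if self.bits:
            x[sorted(self.bits)] = 1
        return x

    def to_bitstring(self) -> str:
        return "".join("1" if i in self.bits else "0" for i in range(self.n_bits))

    def to_hex(self) -> str:
        return "%0*x" % ((self.n_bits + 3) // 4, int(self.to_bitstring() or "0", 2))


def _as_mol(mol: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        return mol.to_mol()
    if isinstance(mol, str):
        return mol_from_smiles(mol)
    return mol


def circular_fingerprint(mol: MoleculeRecord | Chem.Mol | str, config: FingerprintConfig = FingerprintConfig()) -> Fingerprint:
    """Circular (Morgan) fingerprint with full bit-to-environment tracking.

    Deterministic: the same molecule and config always yield identical bits
    and ``bit_info``.
    """
    if config.kind != "circular":
        raise ConfigError(f"circular_fingerprint requires kind='circular', got {config.kind!r}")
    m = _as_mol(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=config.radius, fpSize=config.n_bits)
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    bv = gen.GetFingerprint(m, additionalOutput=out)
    info = {int(b): tuple((int(a), int(r)) for a, r in envs) for b, envs in out.GetBitInfoMap().items()}
    return Fingerprint(
        bits=frozenset(int(i) for i in bv.GetOnBits()),
        n_bits=config.n_bits,
        bit_info=info,
        config=config,
    )


def layered_fingerprint(mol: MoleculeRecord | Chem.Mol | str, config: FingerprintConfig) -> Fingerprint:
    """Layered fingerprint backend (multi-attribute subgraph hashes).

    No ``bit_info`` is available: explanations must use the circular backend.
    """
    if config.kind != "layered":
        raise ConfigError(f"layered_fingerprint requires kind='layered', got {config.kind!r}")
    m = _as_mol(mol)
    bv = Chem.LayeredFingerprint(m, fpSize=config.n_bits)
    return Fingerprint(
        bits=frozenset(int(i) for i in bv.GetOnBits()),
        n_bits=config.n_bits,
        bit_info=None,
        config=config,
    )


def fingerprint(mol: MoleculeRecord | Chem.Mol | str, config: FingerprintConfig = FingerprintConfig()) -> Fingerprint:
    """Dispatch on ``config.kind``."""
    if config.kind == "circular":
        return circular_fingerprint(mol, config)
    return layered_fingerprint(mol, config)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two bit sets.

    Convention: two empty fingerprints are identical, so the similarity is 1.
    """
    if a.n_bits != b.n_bits:
        raise ConfigError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def feature_matrix(
    records: Sequence[MoleculeRecord], config: FingerprintConfig = FingerprintConfig()
) -> np.ndarray:
    """Dense ``n x n_bits`` 0/1 matrix, row-aligned with ``records``."""
    X = np.zeros((len(records), config.n_bits), dtype=np.uint8)
    for i, rec in enumerate(records):
        X[i] = fingerprint(rec, config).dense()
    return X


def similarity_matrix(
    records: Sequence[MoleculeRecord] | Sequence[Fingerprint],
    config: FingerprintConfig = FingerprintConfig(),
) -> np.ndarray:
    """Symmetric n×n Tanimoto similarity matrix (diagonal 1 by convention)."""
    fps = [r if isinstance(r, Fingerprint) else fingerprint(r, config) for r in records]
    n = len(fps)
    X = np.zeros((n, config.n_bits), dtype=np.int64)
    for i, fp in enumerate(fps):
        X[i] = fp.dense()
    inter = X @ X.T
    sizes = inter.diagonal()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(S, 1.0)
    return S
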