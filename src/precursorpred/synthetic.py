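"""Seeded generator of planted-substructure molecule datasets and toy pathway
graphs.

Real precursor datasets are built from curated literature and pathway
databases; this module emulates their statistical shape — multi-label,
imbalanced, with label-defining substructures — without any download.  Each
synthetic molecule is a saturated scaffold optionally decorated with one
marker fragment per label (chemically distinctive moieties such as indole,
quinoline, catechol, a prenyl chain), attached by a single C–C/C–heteroatom
bond at an sp³ carbon so every product is valence-valid.  Label j is 1 iff
marker j was attached, then flipped with a configurable noise rate.  Because
labels are determined by planted substructures, a fingerprint pipeline can in
principle recover them perfectly at zero noise — which is exactly what the
parameter-recovery and attribution-recovery tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .dataset import LabeledDataset
from .errors import ConfigError, DataError
from .featurize import MoleculeRecord, canonicalize_smiles, mol_from_smiles
from .pathway import PathwayGraph, PrecursorVocabulary, build_graph


@dataclass(frozen=True)
class LabelRule:
    """One synthetic label: a marker substructure planted at a target frequency.

    ``marker_smarts`` doubles as the attachable fragment (it must parse as
    SMILES) and as the query used to verify planting.  ``attach_index`` names
    the marker atom that bonds to the scaffold.  ``noise_rate`` flips the
    final label with the given probability, emulating curation errors.
    """

    label: str
    marker_smarts: str
    target_frequency: float
    noise_rate: float = 0.0
    attach_index: int = 0

    def __post_init__(self):
        if not (0 < self.target_frequency < 1):
            raise ConfigError(f"target_frequency must be in (0,1), got {self.target_frequency}")
        if not (0 <= self.noise_rate < 0.5):
            raise ConfigError(f"noise_rate must be in [0, 0.5), got {self.noise_rate}")
        if Chem.MolFromSmiles(self.marker_smarts) is None:
            raise ConfigError(f"marker is not a valid fragment SMILES: {self.marker_smarts!r}")

    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.marker_smarts)


#: Marker fragments echo substructures that drive real precursor predictions
#: (indole for tryptophan-derived alkaloids, quinoline ring systems, catechol
#: for hydroxylated phenylpropanoids, an isoprenoid chain for terpenoids).
#: Frequencies deliberately span a wide range to emulate label imbalance.
DEFAULT_RULES = (
    LabelRule("tryptophan_like", "c1ccc2[nH]ccc2c1", 0.45, attach_index=0),
    LabelRule("quinoline_like", "c1ccc2ncccc2c1", 0.32, attach_index=0),
    LabelRule("catechol_like", "Oc1ccccc1O", 0.22, attach_index=3),
    LabelRule("prenyl_like", "CC(C)=CC", 0.15, attach_index=4),
    LabelRule("furan_like", "c1ccoc1", 0.10, attach_index=0),
)

DEFAULT_SCAFFOLDS = (
    "C1CCCCC1",      # cyclohexane
    "C1CCOCC1",      # tetrahydropyran
    "C1CCNCC1",      # piperidine
    "CCCCCCC",       # heptane
    "C1CCC(CC1)C2CCCCC2",  # bicyclohexyl
)


def _sp3_carbons_with_h(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C"
        and a.GetHybridization() == Chem.HybridizationType.SP3
        and a.GetTotalNumHs() > 0
    ]


def _attach(scaffold: Chem.Mol, marker: Chem.Mol, scaffold_atom: int, marker_atom: int) -> Chem.Mol:
    combined = Chem.RWMol(Chem.CombineMols(scaffold, marker))
    offset = scaffold.GetNumAtoms()
    combined.AddBond(scaffold_atom, offset + marker_atom, Chem.BondType.SINGLE)
    mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def generate_dataset(
    n: int,
    rules: Sequence[LabelRule] = DEFAULT_RULES,
    scaffold_pool: Sequence[str] = DEFAULT_SCAFFOLDS,
    seed: int = 0,
) -> LabeledDataset:
    """Generate ``n`` molecules with planted marker substructures.

    Deterministic given the seed: the same call yields byte-identical CSV
    output.  At zero noise every positive of label j contains marker j as a
    substructure match; np_class records the first planted marker (or
    "scaffold" for undecorated molecules).
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    if not rules:
        raise ConfigError("at least one label rule is required")
    scaffolds = [mol_from_smiles(s) for s in scaffold_pool]  # validates
    markers = [mol_from_smiles(r.marker_smarts) for r in rules]
    for r, m in zip(rules, markers):
        if not (0 <= r.attach_index < m.GetNumAtoms()):
            raise ConfigError(f"attach_index {r.attach_index} out of range for {r.marker_smarts!r}")
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    labels = np.zeros((n, len(rules)), dtype=np.int8)
    for i in range(n):
        scaffold = scaffolds[rng.integers(len(scaffolds))]
        mol = Chem.Mol(scaffold)
        attached = []
        for j, rule in enumerate(rules):
            if rng.random() < rule.target_frequency:
                sites = _sp3_carbons_with_h(mol)
                if not sites:
                    continue
                site = int(sites[rng.integers(len(sites))])
                mol = _attach(mol, markers[j], site, rule.attach_index)
                attached.append(j)
        for j, rule in enumerate(rules):
            y = 1 if j in attached else 0
            if rule.noise_rate > 0 and rng.random() < rule.noise_rate:
                y = 1 - y
            labels[i, j] = y
        np_class = rules[attached[0]].label if attached else "scaffold"
        records.append(
            MoleculeRecord(id=f"syn{i:05d}", smiles=Chem.MolToSmiles(mol), np_class=np_class)
        )
    return LabeledDataset(
        records=records,
        labels=labels,
        vocab=PrecursorVocabulary(tuple(r.label for r in rules)),
    )


def with_noise(rules: Sequence[LabelRule], noise_rate: float) -> tuple[LabelRule, ...]:
    """Copy of ``rules`` with every noise_rate replaced."""
    return tuple(
        LabelRule(r.label, r.marker_smarts, r.target_frequency, noise_rate, r.attach_index)
        for r in rules
    )


def marker_atoms(record: MoleculeRecord, rule: LabelRule) -> set[int]:
    """Atom indices of every match of the rule's marker in the record.

    Empty when the marker is absent (e.g. a noise-flipped positive).
    """
    mol = record.to_mol()
    matches = mol.GetSubstructMatches(rule.query())
    return {idx for match in matches for idx in match}


# --------------------------------------------------------------------------
# Toy pathway fixtures
# --------------------------------------------------------------------------

def toy_pathway(spec: str) -> tuple[PathwayGraph, PrecursorVocabulary, dict[str, set[str]]]:
    """Hand-verifiable pathway fixtures for the DFS labeler.

    * ``chain``: P → A → B with vocabulary {P}.
    * ``diamond``: S → X, S → Y, X → Z, Y → Z with vocabulary {X, Y}.
    * ``terpenoid_demo``: the prenyl-diphosphate nesting case — GPP sits
      upstream of GGPP, and the nearest-precursor rule assigns a diterpenoid
      only GGPP, while an all-ancestors rule would also assign GPP.

    Returns (graph, vocabulary, expected labels for every non-source node).
    """
    if spec == "chain":
        g = build_graph([("P", "A", "r1"), ("A", "B", "r2")])
        vocab = PrecursorVocabulary(("P",))
        expected = {"A": {"P"}, "B": {"P"}}
    elif spec == "diamond":
        g = build_graph(
            [("S", "X", "r1"), ("S", "Y", "r2"), ("X", "Z", "r3"), ("Y", "Z", "r4")]
        )
        vocab = PrecursorVocabulary(("X", "Y"))
        expected = {"X": set(), "Y": set(), "Z": {"X", "Y"}}
    elif spec == "terpenoid_demo":
        g = build_graph(
            [
                ("GPP", "monoterpenoid", "r1"),
                ("GPP", "X", "r2"),
                ("X", "GGPP", "r3"),
                ("GGPP", "diterpenoid", "r4"),
            ]
        )
        vocab = PrecursorVocabulary(("GPP", "GGPP"))
        # nearest-precursor: the diterpenoid stops at GGPP and does NOT inherit GPP
        expected = {
            "monoterpenoid": {"GPP"},
            "X": {"GPP"},
            "GGPP": {"GPP"},
            "diterpenoid": {"GGPP"},
        }
    else:
        raise ConfigError(f"unknown toy pathway spec {spec!r}")
    return g, vocab, expected
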