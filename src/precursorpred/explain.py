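"""Map ridge coefficients back to fingerprint bits and molecular substructures.

Because the classifier is linear in the fingerprint, each label's decision
score decomposes exactly as Σ_bit coefficient·bit_value + intercept, and each
circular-fingerprint bit traces back to concrete atom environments.  An
attribution classifies every reported bit as active/inactive (on or off in
the molecule) × positive/negative (coefficient sign); for active bits the
atoms and bonds of the hashed environments are returned so they can be
highlighted on the structure.  Layered-fingerprint models carry no bit-to-
environment map and are reported as not traceable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .errors import ConfigError, DataError
from .featurize import Fingerprint, MoleculeRecord, circular_fingerprint
from .model import RidgeOvRModel


class NotTraceableError(ConfigError):
    """The fingerprint backend has no bit-to-environment map (layered FPs)."""


@dataclass(frozen=True)
class BitAttribution:
    """One (label, bit) explanation entry.

    ``status`` is one of active_positive / active_negative / inactive_positive
    / inactive_negative: "active" means the bit is on in the molecule,
    the suffix is the coefficient sign (zero counts as positive).
    ``atoms``/``bonds`` are populated only for active bits; ``environments``
    keeps one (atoms, bonds) pair per hashed environment, so hash collisions
    remain visible instead of being merged away.
    """

    label: str
    bit: int
    coefficient: float
    status: str
    atoms: frozenset[int] = frozenset()
    bonds: frozenset[int] = frozenset()
    environments: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = ()

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "bit": self.bit,
            "coefficient": self.coefficient,
            "status": self.status,
            "atoms": sorted(self.atoms),
            "bonds": sorted(self.bonds),
            "environments": [
                {"atoms": list(a), "bonds": list(b)} for a, b in self.environments
            ],
        }


def _single_environment(mol: Chem.Mol, center: int, radius: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    if radius == 0:
        return (center,), ()
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return tuple(sorted(atoms)), tuple(sorted(int(b) for b in bond_ids))


def bit_environment(
    mol: MoleculeRecord | Chem.Mol, fp: Fingerprint, bit: int
) -> tuple[set[int], set[int]]:
    """Atoms and bonds covered by every environment hashing to ``bit``.

    The union over all (center, radius) entries recorded for the bit.  A bit
    that is off in this molecule raises a distinct error from a bit outside
    the fingerprint width.
    """
    if not (0 <= bit < fp.n_bits):
        raise ConfigError(f"unknown bit {bit}: outside [0, {fp.n_bits})")
    if bit not in fp.bits:
        raise DataError(f"bit {bit} is not set in this molecule's fingerprint (off-bit)")
    if fp.bit_info is None:
        raise NotTraceableError(
            "fingerprint has no bit-to-environment map (layered backend); "
            "use a circular fingerprint for explanations"
        )
    m = mol.to_mol() if isinstance(mol, MoleculeRecord) else mol
    atoms: set[int] = set()
    bonds: set[int] = set()
    for center, radius in fp.bit_info[bit]:
        a, b = _single_environment(m, center, radius)
        atoms.update(a)
        bonds.update(b)
    return atoms, bonds


def attribution_report(
    model: RidgeOvRModel,
    mol: MoleculeRecord,
    label: str,
    top_k: int = 10,
) -> list[BitAttribution]:
    """Top-k coefficient attributions for one molecule and one label.

    Coefficients of the label's weight vector are ranked by |coefficient|
    descending (ties by bit index ascending); each is classified by whether
    its bit is on in the molecule and by the coefficient's sign.  Atom/bond
    environments are resolved for active bits only.
    """
    if top_k < 1:
        raise ConfigError(f"top_k must be >= 1, got {top_k}")
    if label not in model.vocab:
        raise DataError(f"label {label!r} not in model vocabulary {list(model.vocab.names)}")
    if model.fp_config.kind != "circular":
        raise NotTraceableError(
            "model was trained on a non-traceable fingerprint backend "
            f"({model.fp_config.kind!r}); explanations require circular fingerprints"
        )
    j = model.vocab.index(label)
    fp = circular_fingerprint(mol, model.fp_config)
    rdmol = mol.to_mol()
    coefs = model.W[:, j]
    order = sorted(
        range(len(coefs)), key=lambda k: (-abs(coefs[k]), model.filter.kept_indices[k])
    )[:top_k]
    out: list[BitAttribution] = []
    for k in order:
        bit = model.filter.kept_indices[k]
        coef = float(coefs[k])
        active = bit in fp.bits
        sign = "positive" if coef >= 0 else "negative"
        status = f"{'active' if active else 'inactive'}_{sign}"
        atoms: set[int] = set()
        bonds: set[int] = set()
        envs: tuple = ()
        if active:
            atoms, bonds = bit_environment(rdmol, fp, bit)
            envs = tuple(
                _single_environment(rdmol, c, r) for c, r in fp.bit_info[bit]
            )
        out.append(
            BitAttribution(
                label=label, bit=bit, coefficient=coef, status=status,
                atoms=frozenset(atoms), bonds=frozenset(bonds), environments=envs,
            )
        )
    return out


def explanation_report(
    model: RidgeOvRModel,
    mol: MoleculeRecord,
    labels: Sequence[str] | None = None,
    top_k: int = 10,
) -> dict:
    """JSON-ready explanation for one molecule across labels.

    Per label: predicted flag, decision score, and the top-k attributions.
    """
    labels = list(labels) if labels is not None else list(model.vocab.names)
    scores = model.decision_scores([mol])[0]
    report = {"id": mol.id, "smiles": mol.smiles, "labels": {}}
    for name in labels:
        j = model.vocab.index(name)
        report["labels"][name] = {
            "predicted": bool(scores[j] > 0),
            "score": float(scores[j]),
            "attributions": [a.to_dict() for a in attribution_report(model, mol, name, top_k)],
        }
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def render_molecule_svg(
    mol: MoleculeRecord, atoms: Sequence[int] = (), bonds: Sequence[int] = ()
) -> str:
    """Optional SVG depiction with the given atoms/bonds highlighted."""
    from rdkit.Chem.Draw import rdMolDraw2D

    m = mol.to_mol()
    drawer = rdMolDraw2D.MolDraw2DSVG(400, 300)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, m, highlightAtoms=list(atoms), highlightBonds=list(bonds)
    )
    drawer.FinishDrawing()
    return drawer.GetDrawingText()
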