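"""Charge post-processing for MD-ready output.

Predicted atom-centered charges are made force-field usable in two
steps: nonpolar hydrogens (those bonded to carbon, GROMOS united-atom
convention) can be merged into their parent carbon with their charge,
and any excess of the net charge over the intended integer total is
removed by an equal per-atom shift.  Results are written as PQR
(coordinates + charge + radius) and as a plain charge CSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molgraph import Atom, Bond, COVALENT_RADII, Molecule, MoleculeError

__all__ = [
    "ChargeAssignment",
    "merge_nonpolar_hydrogens",
    "redistribute_excess",
    "write_pqr",
    "parse_pqr_charges",
    "charges_csv",
]


@dataclass
class ChargeAssignment:
    """Per-atom partial charges (e), aligned to a molecule's atom order."""

    charges: np.ndarray
    target_net: float = 0.0

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.ndim != 1:
            raise ValueError("charges must be a flat vector")

    @property
    def net(self) -> float:
        return float(self.charges.sum())

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


def merge_nonpolar_hydrogens(mol: Molecule, ca: ChargeAssignment) -> tuple[Molecule, ChargeAssignment]:
    """Remove every hydrogen bonded to a carbon, adding its charge to
    that carbon; hydrogens on N/O/S (polar) are kept.  Total charge is
    conserved exactly."""
    if ca.n_atoms != mol.n_atoms:
        raise ValueError("charge vector not aligned to molecule")
    adj = mol.adjacency()
    remove: dict[int, int] = {}  # H index -> parent carbon index
    for a in mol.atoms:
        if a.element != "H":
            continue
        if len(adj[a.index]) != 1:
            raise MoleculeError(
                f"hydrogen {a.index} has {len(adj[a.index])} bonds; expected exactly 1"
            )
        parent = adj[a.index][0]
        if mol.atoms[parent].element == "C":
            remove[a.index] = parent
    if not remove:
        return mol, ChargeAssignment(ca.charges.copy(), ca.target_net)

    new_charges = ca.charges.copy()
    for h, parent in remove.items():
        new_charges[parent] += new_charges[h]

    keep = [a.index for a in mol.atoms if a.index not in remove]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [
        Atom(remap[a.index], a.element, None if a.coords is None else a.coords.copy(),
             name=a.name, formal_charge=a.formal_charge)
        for a in mol.atoms if a.index in remap
    ]
    bonds = [
        Bond(min(remap[b.i], remap[b.j]), max(remap[b.i], remap[b.j]), b.order, b.aromatic)
        for b in mol.bonds if b.i in remap and b.j in remap
    ]
    merged = Molecule(mol.id, atoms, bonds, source_format=mol.source_format,
                      orders_reliable=mol.orders_reliable,
                      coords_approximate=mol.coords_approximate)
    return merged, ChargeAssignment(new_charges[keep], ca.target_net)


def redistribute_excess(ca: ChargeAssignment) -> ChargeAssignment:
    """Remove the net-charge excess by shifting every atom equally:
    each charge is decremented by (net - target)/n.  Idempotent and
    difference-preserving."""
    if ca.n_atoms == 0:
        raise ValueError("cannot redistribute over an empty assignment")
    shift = (ca.net - ca.target_net) / ca.n_atoms
    return ChargeAssignment(ca.charges - shift, ca.target_net)


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_pqr(mol: Molecule, ca: ChargeAssignment,
              radius_table: dict[str, float] = COVALENT_RADII) -> str:
    """Whitespace-dialect PQR: ATOM records carrying charge then radius
    after the coordinates.  Charges are written with 12 decimals so the
    net total survives serialization at far better than 1e-9."""
    if ca.n_atoms != mol.n_atoms:
        raise ValueError("charge vector not aligned to molecule")
    if not mol.has_coords:
        raise MoleculeError("PQR output requires coordinates")
    lines = []
    for a, q in zip(mol.atoms, ca.charges):
        x, y, z = a.coords
        lines.append(
            f"ATOM {a.index + 1:>6} {a.name:<4} LIG {1:>5} "
            f"{x:>10.3f} {y:>10.3f} {z:>10.3f} {q:>16.12f} {radius_table[a.element]:>7.4f}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def parse_pqr_charges(text: str) -> np.ndarray:
    """Charges from the PQR charge column (second-to-last field)."""
    charges = []
    for line in text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            fields = line.split()
            charges.append(float(fields[-2]))
    return np.array(charges)


def charges_csv(mol: Molecule, ca: ChargeAssignment) -> str:
    """Plain charge table: atom index, name, element, charge (e)."""
    if ca.n_atoms != mol.n_atoms:
        raise ValueError("charge vector not aligned to molecule")
    frame = pd.DataFrame({
        "index": [a.index for a in mol.atoms],
        "name": [a.name for a in mol.atoms],
        "element": [a.element for a in mol.atoms],
        "charge": ca.charges,
    })
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    return buf.getvalue()
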