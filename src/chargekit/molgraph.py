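"""Molecular graphs: file parsing, bond perception, and ring detection.

A molecule is held as a cyclic undirected graph — atoms are vertices,
bonds are edges — plus optional 3D coordinates in Å.  Supported inputs
are PDB (ATOM/HETATM with optional CONECT), SDF V2000, and a SMILES
subset covering organic chemistry without stereochemistry.  Ring
perception returns the fundamental cycle basis of a depth-first-search
spanning tree, so the number of rings always equals |E| - |V| + C.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SUPPORTED_ELEMENTS",
    "COVALENT_RADII",
    "ELECTRONEGATIVITY",
    "MAX_VALENCE",
    "DEFAULT_VALENCE",
    "Atom",
    "Bond",
    "Molecule",
    "RingInfo",
    "RingSystem",
    "ParseError",
    "MoleculeError",
    "parse_pdb",
    "parse_sdf",
    "parse_smiles",
    "write_pdb",
    "write_sdf",
    "perceive_bonds",
    "find_rings",
    "embed_coordinates",
]

#: Elements the pipeline supports (organic subset).
SUPPORTED_ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I")

#: Single-bond covalent radii in Å (Cordero-style consensus values).
COVALENT_RADII: dict[str, float] = {
    "C": 0.76, "H": 0.31, "N": 0.71, "O": 0.66, "P": 1.07,
    "S": 1.05, "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

#: Pauling electronegativities.
ELECTRONEGATIVITY: dict[str, float] = {
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "P": 2.19,
    "S": 2.58, "F": 3.98, "Cl": 3.16, "Br": 2.96, "I": 2.66,
}

#: Hard valence caps (sum of bond orders) used for graph validation.
MAX_VALENCE: dict[str, int] = {
    "C": 4, "H": 1, "N": 4, "O": 2, "P": 5,
    "S": 6, "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

#: Default valences used to fill implicit hydrogens (neutral atoms).
DEFAULT_VALENCE: dict[str, int] = {
    "C": 4, "H": 1, "N": 3, "O": 2, "P": 3,
    "S": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

# Geometric bond perception: d <= r_i + r_j + BOND_TOLERANCE, d >= CLASH_FLOOR.
BOND_TOLERANCE = 0.45  # Å
CLASH_FLOOR = 0.4      # Å


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


class MoleculeError(ValueError):
    """Raised when a molecular graph violates a structural invariant."""


@dataclass
class Atom:
    """One vertex of the molecular graph."""

    index: int
    element: str
    coords: np.ndarray | None = None
    name: str = ""
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise MoleculeError(f"unsupported element {self.element!r}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
                raise MoleculeError(f"atom {self.index}: coords must be a finite 3-vector")
        if not self.name:
            self.name = self.element


@dataclass(frozen=True)
class Bond:
    """Undirected edge; ``i < j`` by construction."""

    i: int
    j: int
    order: int = 1
    aromatic: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise MoleculeError(f"self-loop bond at atom {self.i}")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)
        if not 1 <= self.order <= 3:
            raise MoleculeError(f"bond order {self.order} outside 1-3")

    def other(self, k: int) -> int:
        return self.j if k == self.i else self.i


@dataclass
class Molecule:
    """Atoms plus an undirected bond graph.

    ``orders_reliable`` is False when bonds were perceived purely from
    geometry, in which case bond orders are all 1 and hybridization
    falls back to geometric rules.
    """

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    source_format: str = "synthetic"
    orders_reliable: bool = True
    coords_approximate: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        order_sum = [0] * n
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise MoleculeError(f"bond ({b.i},{b.j}) references a missing atom")
            if (b.i, b.j) in seen:
                raise MoleculeError(f"duplicate bond ({b.i},{b.j})")
            seen.add((b.i, b.j))
            order_sum[b.i] += b.order
            order_sum[b.j] += b.order
        for a in self.atoms:
            if order_sum[a.index] > MAX_VALENCE[a.element]:
                raise MoleculeError(
                    f"atom {a.index} ({a.element}) exceeds max valence "
                    f"{MAX_VALENCE[a.element]} with bond-order sum {order_sum[a.index]}"
                )

    # -- conveniences -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def has_coords(self) -> bool:
        return all(a.coords is not None for a in self.atoms)

    def coords_array(self) -> np.ndarray:
        if not self.has_coords:
            raise MoleculeError("molecule has atoms without coordinates")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        for nbrs in adj:
            nbrs.sort()
        return adj

    def bonds_of(self, k: int) -> list[Bond]:
        return [b for b in self.bonds if k in (b.i, b.j)]

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")


# ---------------------------------------------------------------------------
# Geometric bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(atoms: Sequence[Atom]) -> list[Bond]:
    """Infer single bonds from interatomic distances.

    Two atoms are bonded when their distance lies between the 0.4 Å
    clash floor and the sum of covalent radii plus 0.45 Å.  When the
    raw assignment would push an atom past its valence cap, candidate
    bonds are dropped longest-first until every cap is respected.
    """
    for a in atoms:
        if a.coords is None:
            raise MoleculeError(f"atom {a.index} has no coordinates; cannot perceive bonds")
    if len(atoms) < 2:
        return []
    xyz = np.array([a.coords for a in atoms], dtype=float)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    candidates: list[tuple[float, int, int]] = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            cutoff = COVALENT_RADII[atoms[i].element] + COVALENT_RADII[atoms[j].element] + BOND_TOLERANCE
            if CLASH_FLOOR <= dist[i, j] <= cutoff:
                candidates.append((dist[i, j], i, j))
    # shortest bonds are most trustworthy; greedily keep them under the caps
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used = [0] * len(atoms)
    bonds: list[Bond] = []
    for d, i, j in candidates:
        if used[i] < MAX_VALENCE[atoms[i].element] and used[j] < MAX_VALENCE[atoms[j].element]:
            bonds.append(Bond(i, j, 1))
            used[i] += 1
            used[j] += 1
    bonds.sort(key=lambda b: (b.i, b.j))
    return bonds


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_TWO_LETTER = {"CL": "Cl", "BR": "Br"}


def _element_from_pdb(record: str, lineno: int) -> str:
    sym = record[76:78].strip() if len(record) >= 78 else ""
    if not sym:
        # fall back to the atom-name field (columns 13-16)
        name = record[12:16].strip().lstrip("0123456789")
        if name[:2].upper() in _TWO_LETTER:
            sym = name[:2]
        elif name:
            sym = name[0]
    sym = sym.capitalize()
    if sym.upper() in _TWO_LETTER:
        sym = _TWO_LETTER[sym.upper()]
    if sym not in SUPPORTED_ELEMENTS:
        raise ParseError(f"line {lineno}: unsupported element {sym!r}")
    return sym


def parse_pdb(text: str, mol_id: str = "pdb") -> Molecule:
    """Read ATOM/HETATM records; use CONECT bonds when present,
    otherwise perceive bonds from geometry."""
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    conect_pairs: set[tuple[int, int]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed {rec} record") from exc
            element = _element_from_pdb(line, lineno)
            idx = len(atoms)
            atoms.append(Atom(idx, element, np.array([x, y, z]), name=line[12:16].strip()))
            serial_to_index[serial] = idx
        elif rec == "CONECT":
            fields = line[6:].split()
            if not fields:
                raise ParseError(f"line {lineno}: empty CONECT record")
            try:
                serials = [int(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed CONECT record") from exc
            base = serials[0]
            for other in serials[1:]:
                conect_pairs.add((min(base, other), max(base, other)))
    if not atoms:
        raise ParseError("no ATOM/HETATM records found")
    if conect_pairs:
        bonds = []
        for si, sj in sorted(conect_pairs):
            if si not in serial_to_index or sj not in serial_to_index:
                raise ParseError(f"CONECT references unknown serial {si if si not in serial_to_index else sj}")
            i, j = serial_to_index[si], serial_to_index[sj]
            bonds.append(Bond(min(i, j), max(i, j), 1))
        bonds.sort(key=lambda b: (b.i, b.j))
        orders_reliable = False  # CONECT carries connectivity, not orders
    else:
        bonds = perceive_bonds(atoms)
        orders_reliable = False
    return Molecule(mol_id, atoms, bonds, source_format="pdb", orders_reliable=orders_reliable)


def write_pdb(mol: Molecule) -> str:
    """Emit HETATM records (1-based serials) plus CONECT connectivity."""
    if not mol.has_coords:
        raise MoleculeError("cannot write PDB without coordinates")
    lines = []
    for a in mol.atoms:
        x, y, z = a.coords
        lines.append(
            f"HETATM{a.index + 1:>5} {a.name:<4} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {a.element:>2}"
        )
    adj = mol.adjacency()
    for i, nbrs in enumerate(adj):
        if nbrs:
            lines.append("CONECT" + f"{i + 1:>5}" + "".join(f"{j + 1:>5}" for j in nbrs))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SDF (V2000)
# ---------------------------------------------------------------------------

def parse_sdf(text: str, mol_id: str | None = None) -> Molecule:
    """Read a single V2000 molfile (the leading record of an SDF)."""
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("SDF too short: missing counts line")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise ParseError("malformed V2000 counts line") from exc
    if n_atoms == 0:
        raise ParseError("SDF declares zero atoms")
    if len(lines) < 4 + n_atoms + n_bonds:
        raise ParseError("SDF truncated: atom/bond blocks shorter than counts line")
    atoms: list[Atom] = []
    for k in range(n_atoms):
        line = lines[4 + k]
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
            sym = line[30:34].strip()
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed atom line {4 + k + 1}") from exc
        if sym not in SUPPORTED_ELEMENTS:
            raise ParseError(f"line {4 + k + 1}: unsupported element {sym!r}")
        atoms.append(Atom(k, sym, np.array([x, y, z])))
    bonds: list[Bond] = []
    for k in range(n_bonds):
        line = lines[4 + n_atoms + k]
        try:
            i = int(line[0:3]) - 1
            j = int(line[3:6]) - 1
            order = int(line[6:9])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed bond line {4 + n_atoms + k + 1}") from exc
        if order == 4:  # V2000 aromatic convention
            bonds.append(Bond(min(i, j), max(i, j), 1, aromatic=True))
        else:
            bonds.append(Bond(min(i, j), max(i, j), order))
    name = (lines[0].strip() or "sdf") if mol_id is None else mol_id
    return Molecule(name, atoms, bonds, source_format="sdf")


def write_sdf(mol: Molecule) -> str:
    """Emit a V2000 molfile; ``parse_sdf`` round-trips it exactly."""
    if not mol.has_coords:
        raise MoleculeError("cannot write SDF without coordinates")
    lines = [mol.id, "  chargekit", ""]
    lines.append(f"{mol.n_atoms:>3}{len(mol.bonds):>3}  0  0  0  0  0  0  0  0999 V2000")
    for a in mol.atoms:
        x, y, z = a.coords
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in sorted(mol.bonds, key=lambda b: (b.i, b.j)):
        order = 4 if b.aromatic else b.order
        lines.append(f"{b.i + 1:>3}{b.j + 1:>3}{order:>3}  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SMILES subset
# ---------------------------------------------------------------------------

_ORGANIC = {"C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_AROMATIC_LOWER = {"c": "C", "n": "N", "o": "O", "s": "S", "p": "P"}
_BOND_ORDER = {"-": 1, "=": 2, "#": 3, ":": 1}
_BRACKET_RE = re.compile(
    r"\[(?P<sym>[A-Z][a-z]?|[cnosp])(?P<hcount>H\d*)?(?P<charge>[+-]\d*|[+]+|[-]+)?\]"
)


def parse_smiles(text: str, mol_id: str | None = None) -> Molecule:
    """Parse a connectivity-only SMILES subset.

    Supports organic-subset and bracket atoms, aromatic lowercase
    c/n/o/s/p, explicit bonds ``- = # :``, branches, and ring closures
    (digits and %nn).  Stereochemistry is rejected as unsupported;
    implicit hydrogens are added to satisfy default valences.
    The result has no coordinates (see :func:`embed_coordinates`).
    """
    text = text.strip()
    if not text:
        raise ParseError("empty SMILES string")
    if any(ch in text for ch in "/\\@"):
        raise ParseError("stereochemistry marks are unsupported")

    atoms: list[dict] = []      # element, aromatic, charge, explicit_h
    bonds: dict[tuple[int, int], tuple[int, bool]] = {}
    stack: list[int] = []
    prev: int | None = None
    pending_bond: str | None = None
    ring_open: dict[int, tuple[int, str | None]] = {}

    def add_atom(element: str, aromatic: bool, charge: int = 0, explicit_h: int | None = None) -> int:
        if element not in SUPPORTED_ELEMENTS:
            raise ParseError(f"unsupported element {element!r} in SMILES")
        atoms.append({"element": element, "aromatic": aromatic, "charge": charge, "explicit_h": explicit_h})
        return len(atoms) - 1

    def add_bond(i: int, j: int, symbol: str | None, both_aromatic: bool) -> None:
        if i == j:
            raise ParseError("ring closure bonds an atom to itself")
        key = (min(i, j), max(i, j))
        if key in bonds:
            raise ParseError("duplicate bond in SMILES")
        if symbol is None:
            bonds[key] = (1, both_aromatic)
        else:
            bonds[key] = (_BOND_ORDER[symbol], symbol == ":")

    def connect(idx: int) -> None:
        nonlocal prev, pending_bond
        if prev is not None:
            add_bond(prev, idx, pending_bond,
                     atoms[prev]["aromatic"] and atoms[idx]["aromatic"])
        prev = idx
        pending_bond = None

    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "(":
            if prev is None:
                raise ParseError("branch before any atom")
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise ParseError("unmatched ')'")
            prev = stack.pop()
            i += 1
        elif ch in _BOND_ORDER:
            pending_bond = ch
            i += 1
        elif ch == "[":
            m = _BRACKET_RE.match(text, i)
            if not m:
                raise ParseError(f"malformed bracket atom at position {i}")
            sym = m.group("sym")
            aromatic = sym in _AROMATIC_LOWER
            element = _AROMATIC_LOWER.get(sym, sym)
            hcount = m.group("hcount")
            explicit_h = 0
            if hcount:
                explicit_h = int(hcount[1:]) if len(hcount) > 1 else 1
            charge_s = m.group("charge") or ""
            if charge_s in ("+", "-"):
                charge = 1 if charge_s == "+" else -1
            elif charge_s and charge_s[0] in "+-" and charge_s[1:].isdigit():
                charge = int(charge_s[1:]) * (1 if charge_s[0] == "+" else -1)
            elif charge_s:
                charge = len(charge_s) * (1 if charge_s[0] == "+" else -1)
            else:
                charge = 0
            idx = add_atom(element, aromatic, charge, explicit_h)
            connect(idx)
            i = m.end()
        elif ch.isdigit() or ch == "%":
            if prev is None:
                raise ParseError("ring closure before any atom")
            if ch == "%":
                if i + 2 >= n or not text[i + 1:i + 3].isdigit():
                    raise ParseError("malformed %nn ring closure")
                num = int(text[i + 1:i + 3])
                i += 3
            else:
                num = int(ch)
                i += 1
            if num in ring_open:
                j, open_bond = ring_open.pop(num)
                symbol = pending_bond or open_bond
                add_bond(prev, j, symbol, atoms[prev]["aromatic"] and atoms[j]["aromatic"])
                pending_bond = None
            else:
                ring_open[num] = (prev, pending_bond)
                pending_bond = None
        elif ch.isalpha():
            two = text[i:i + 2]
            if two in ("Cl", "Br"):
                idx = add_atom(two, False)
                i += 2
            elif ch in _ORGANIC:
                idx = add_atom(ch, False)
                i += 1
            elif ch in _AROMATIC_LOWER:
                idx = add_atom(_AROMATIC_LOWER[ch], True)
                i += 1
            else:
                raise ParseError(f"unsupported SMILES symbol {ch!r} at position {i}")
            connect(idx)
        else:
            raise ParseError(f"unsupported SMILES symbol {ch!r} at position {i}")
    if stack:
        raise ParseError("unmatched '('")
    if ring_open:
        raise ParseError(f"unclosed ring closure digit(s): {sorted(ring_open)}")
    if not atoms:
        raise ParseError("SMILES contains no atoms")

    # implicit-hydrogen fill: aromatic bonds count 1.5 toward valence
    valence_used = [0.0] * len(atoms)
    bond_list: list[Bond] = []
    for (a, b), (order, aromatic) in sorted(bonds.items()):
        bond_list.append(Bond(a, b, order, aromatic=aromatic))
        used = 1.5 if aromatic else float(order)
        valence_used[a] += used
        valence_used[b] += used

    out_atoms = [
        Atom(k, spec["element"], None, formal_charge=spec["charge"])
        for k, spec in enumerate(atoms)
    ]
    h_bonds: list[Bond] = []
    for k, spec in enumerate(atoms):
        if spec["explicit_h"] is not None:
            n_h = spec["explicit_h"]
        else:
            target = DEFAULT_VALENCE[spec["element"]]
            if spec["element"] == "N" and spec["charge"] > 0:
                target += spec["charge"]
            elif spec["element"] == "O" and spec["charge"] < 0:
                target += spec["charge"]
            n_h = max(0, target - math.ceil(valence_used[k]))
        for _ in range(n_h):
            h = Atom(len(out_atoms), "H", None)
            out_atoms.append(h)
            h_bonds.append(Bond(k, h.index, 1))
    name = text if mol_id is None else mol_id
    return Molecule(name, out_atoms, bond_list + h_bonds, source_format="smiles")


# ---------------------------------------------------------------------------
# Deterministic 3D embedding (approximate coordinates for SMILES input)
# ---------------------------------------------------------------------------

_TET = np.array([
    (1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1),
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
    (1, 1, -1), (1, -1, 1), (-1, 1, 1), (-1, -1, -1),
], dtype=float)
_TET /= np.linalg.norm(_TET, axis=1, keepdims=True)

_EMBED_BOND_LENGTH = 1.5  # Å


def embed_coordinates(mol: Molecule) -> Molecule:
    """Assign deterministic approximate 3D coordinates by breadth-first
    placement: every bond gets length 1.5 Å and each new neighbor takes
    the template direction farthest from directions already used at its
    parent (tetrahedral-first template set).

    The geometry is a stand-in sufficient for radial environment
    features, not a physical conformer; the molecule is flagged
    ``coords_approximate``.
    """
    n = mol.n_atoms
    adj = mol.adjacency()
    pos = np.full((n, 3), np.nan)
    used_dirs: list[list[np.ndarray]] = [[] for _ in range(n)]
    placed = np.zeros(n, dtype=bool)
    for root in range(n):
        if placed[root]:
            continue
        offset = np.array([10.0 * root, 0.0, 0.0])  # separate components
        pos[root] = offset
        placed[root] = True
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if placed[v]:
                    continue
                best, best_score = None, -np.inf
                for d in _TET:
                    # prefer directions far from those already used (low max dot)
                    score = -max((float(np.dot(d, ud)) for ud in used_dirs[u]), default=-1.0)
                    if score > best_score:
                        best, best_score = d, score
                assert best is not None
                pos[v] = pos[u] + _EMBED_BOND_LENGTH * best
                used_dirs[u].append(best)
                used_dirs[v].append(-best)
                placed[v] = True
                queue.append(v)
    atoms = [
        Atom(a.index, a.element, pos[a.index], name=a.name, formal_charge=a.formal_charge)
        for a in mol.atoms
    ]
    return Molecule(mol.id, atoms, list(mol.bonds), source_format=mol.source_format,
                    orders_reliable=mol.orders_reliable, coords_approximate=True)


# ---------------------------------------------------------------------------
# Ring perception (DFS fundamental cycle basis)
# ---------------------------------------------------------------------------

@dataclass
class RingSystem:
    """Maximal set of rings fused through shared atoms."""

    ring_indices: list[int]
    atoms: frozenset[int]

    @property
    def n_rings(self) -> int:
        return len(self.ring_indices)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class RingInfo:
    """Cycle-basis rings and derived per-atom statistics."""

    rings: list[tuple[int, ...]]
    atom_ring_count: np.ndarray
    atom_min_ring_size: np.ndarray
    atom_max_ring_size: np.ndarray
    ring_systems: list[RingSystem] = field(default_factory=list)

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    def system_of(self, atom: int) -> RingSystem | None:
        for rs in self.ring_systems:
            if atom in rs.atoms:
                return rs
        return None


def find_rings(mol: Molecule) -> RingInfo:
    """Detect rings as the fundamental cycle basis of a DFS spanning tree.

    The DFS starts at atom 0 (then at the lowest-index atom of each
    remaining component) and visits children in index order, so the
    basis is deterministic for a fixed atom ordering.  Every non-tree
    edge closes exactly one ring: the tree path between its endpoints.
    The basis size therefore equals |E| - |V| + C.
    """
    n = mol.n_atoms
    adj = mol.adjacency()
    parent = [-1] * n
    depth = [-1] * n
    rings: list[tuple[int, ...]] = []
    visited = [False] * n
    for root in range(n):
        if visited[root]:
            continue
        visited[root] = True
        depth[root] = 0
        # iterative DFS, children in index order
        stack: list[tuple[int, Iterable[int]]] = [(root, iter(adj[root]))]
        while stack:
            u, it = stack[-1]
            advanced = False
            for v in it:
                if not visited[v]:
                    visited[v] = True
                    parent[v] = u
                    depth[v] = depth[u] + 1
                    stack.append((v, iter(adj[v])))
                    advanced = True
                    break
                elif v != parent[u] and depth[v] < depth[u]:
                    # back edge u->v: fundamental cycle is tree path u..v
                    path = [u]
                    w = u
                    while w != v:
                        w = parent[w]
                        path.append(w)
                    rings.append(tuple(path))
            if not advanced:
                stack.pop()

    ring_count = np.zeros(n, dtype=int)
    min_size = np.zeros(n, dtype=int)
    max_size = np.zeros(n, dtype=int)
    for ring in rings:
        for a in ring:
            ring_count[a] += 1
            size = len(ring)
            if min_size[a] == 0 or size < min_size[a]:
                min_size[a] = size
            if size > max_size[a]:
                max_size[a] = size

    # merge rings sharing >=1 atom into fused ring systems (union-find)
    parent_rs = list(range(len(rings)))

    def find(x: int) -> int:
        while parent_rs[x] != x:
            parent_rs[x] = parent_rs[parent_rs[x]]
            x = parent_rs[x]
        return x

    atom_to_ring: dict[int, int] = {}
    for ri, ring in enumerate(rings):
        for a in ring:
            if a in atom_to_ring:
                ra, rb = find(atom_to_ring[a]), find(ri)
                if ra != rb:
                    parent_rs[rb] = ra
            else:
                atom_to_ring[a] = ri
    groups: dict[int, list[int]] = {}
    for ri in range(len(rings)):
        groups.setdefault(find(ri), []).append(ri)
    ring_systems = [
        RingSystem(sorted(members), frozenset(a for ri in members for a in rings[ri]))
        for members in (groups[g] for g in sorted(groups))
    ]
    return RingInfo(rings, ring_count, min_size, max_size, ring_systems)
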