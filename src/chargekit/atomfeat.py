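"""Per-atom feature encoding.

Every atom is described by a fixed 61-slot numeric vector covering five
feature families: element identity, carbon hybridization, ring
membership statistics from DFS ring perception, bonded-neighbor element
counts at graph distance one and two, and radial element counts inside
three Euclidean search radii, plus bond-order/charge/size descriptors.

The schema (names and order) is immutable; two runs on the same
molecule produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molgraph import (
    SUPPORTED_ELEMENTS,
    Molecule,
    MoleculeError,
    RingInfo,
    embed_coordinates,
    find_rings,
)

__all__ = [
    "DEFAULT_RADII",
    "FEATURE_SCHEMA",
    "N_FEATURES",
    "schema_hash",
    "FeatureTable",
    "hybridization",
    "radial_counts",
    "neighbor_trace",
    "encode_atom",
    "encode_molecule",
]

#: Radii (Å) of the three concentric distance searches: bonded shell,
#: second shell, and through-space environment at organic geometry.
DEFAULT_RADII: tuple[float, float, float] = (2.0, 4.0, 6.0)

_RADIAL_BINS = ("C", "N", "O", "X", "H")  # X = other heavy atoms

# Slack on the distance-vs-radius comparison: keeps counts stable under
# rigid-body transforms when an interatomic distance sits exactly on a
# search radius (far larger than float rotation error, far smaller than
# any chemically meaningful distance difference).
_BOUNDARY_EPS = 1e-9


def _build_schema() -> tuple[str, ...]:
    names: list[str] = []
    names += [f"elem_{e}" for e in SUPPORTED_ELEMENTS]            # 1-10
    names += ["hyb_sp", "hyb_sp2", "hyb_sp3"]                      # 11-13
    names += ["in_ring", "ring_count", "min_ring_size",            # 14-19
              "max_ring_size", "ring_system_rings", "ring_system_atoms"]
    names += [f"n1_{e}" for e in SUPPORTED_ELEMENTS]               # 20-29
    names += ["degree"]                                            # 30
    names += [f"n2_{e}" for e in SUPPORTED_ELEMENTS]               # 31-40
    names += [f"r{k}_{b}" for k in (1, 2, 3) for b in _RADIAL_BINS]  # 41-55
    names += ["n_single", "n_double", "n_triple"]                  # 56-58
    names += ["aromatic_flag", "formal_charge", "heavy_atom_count"]  # 59-61
    return tuple(names)


FEATURE_SCHEMA: tuple[str, ...] = _build_schema()
N_FEATURES: int = len(FEATURE_SCHEMA)
assert N_FEATURES == 61

_ELEMENT_INDEX = {e: k for k, e in enumerate(SUPPORTED_ELEMENTS)}


def schema_hash(schema: tuple[str, ...] = FEATURE_SCHEMA) -> str:
    """Digest of the ordered feature names; models refuse tables encoded
    under a different schema."""
    return hashlib.sha256("\n".join(schema).encode()).hexdigest()[:16]


@dataclass
class FeatureTable:
    """Per-atom feature matrix with element tags and optional labels."""

    frame: pd.DataFrame
    schema: tuple[str, ...] = FEATURE_SCHEMA

    def __post_init__(self) -> None:
        expected = list(self.schema) + ["element"]
        cols = list(self.frame.columns)
        if cols[: len(expected)] != expected:
            raise ValueError("feature table columns do not match the schema")
        if self.has_labels and not np.all(np.isfinite(self.frame["label"].to_numpy())):
            raise ValueError("non-finite label values")

    @property
    def has_labels(self) -> bool:
        return "label" in self.frame.columns

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def elements(self) -> np.ndarray:
        return self.frame["element"].to_numpy()

    def features(self) -> np.ndarray:
        return self.frame[list(self.schema)].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        if not self.has_labels:
            raise ValueError("table has no label column")
        return self.frame["label"].to_numpy(dtype=float)

    def rows_for(self, element: str) -> "FeatureTable":
        return FeatureTable(self.frame[self.frame["element"] == element].reset_index(drop=True),
                            self.schema)

    def subset(self, indices) -> "FeatureTable":
        return FeatureTable(self.frame.iloc[np.asarray(indices)].reset_index(drop=True),
                            self.schema)

    def to_csv(self, path_or_buf=None):
        return self.frame.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "FeatureTable":
        frame = pd.read_csv(path_or_buf)
        return cls(frame)

    @classmethod
    def concat(cls, tables: list["FeatureTable"]) -> "FeatureTable":
        if not tables:
            raise ValueError("no tables to concatenate")
        return cls(pd.concat([t.frame for t in tables], ignore_index=True), tables[0].schema)


# ---------------------------------------------------------------------------
# Individual feature families
# ---------------------------------------------------------------------------

def hybridization(mol: Molecule, rings: RingInfo, atom: int) -> str:
    """Hybridization class of a carbon atom: ``sp``, ``sp2`` or ``sp3``
    (``n/a`` for non-carbon).

    With reliable bond orders the decision is order-based (any triple
    bond → sp; any double or aromatic bond → sp2; else sp3).  When
    orders were perceived from geometry the rule falls back to degree
    and bond angles: near-linear two-connected carbon → sp, degree-3 →
    sp2, else sp3.
    """
    a = mol.atoms[atom]
    if a.element != "C":
        return "n/a"
    incident = mol.bonds_of(atom)
    if mol.orders_reliable:
        if any(b.order == 3 for b in incident):
            return "sp"
        if any(b.order == 2 or b.aromatic for b in incident):
            return "sp2"
        return "sp3"
    degree = len(incident)
    if degree <= 2 and degree == 2 and mol.has_coords:
        n1, n2 = (b.other(atom) for b in incident)
        v1 = mol.atoms[n1].coords - a.coords
        v2 = mol.atoms[n2].coords - a.coords
        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= 155.0:
            return "sp"
    if degree == 3:
        return "sp2"
    return "sp3"


def radial_counts(mol: Molecule, atom: int,
                  radii: tuple[float, float, float] = DEFAULT_RADII) -> np.ndarray:
    """Counts of atoms within each search radius, binned by element
    class {C, N, O, other-heavy, H}; 3 radii × 5 bins = 15 numbers,
    cumulative (non-decreasing) across the radius triple."""
    if not mol.has_coords:
        raise MoleculeError("radial counts require coordinates (embed SMILES input first)")
    xyz = mol.coords_array()
    d = np.linalg.norm(xyz - xyz[atom], axis=1)
    bins = _bin_ids(mol)
    out = np.zeros(15)
    for k, r in enumerate(radii):
        inside = (d <= r + _BOUNDARY_EPS)
        inside[atom] = False
        out[5 * k: 5 * k + 5] = np.bincount(bins[inside], minlength=5)
    return out


def _bin_ids(mol: Molecule) -> np.ndarray:
    mapping = {"C": 0, "N": 1, "O": 2, "H": 4}
    return np.array([mapping.get(e, 3) for e in mol.elements], dtype=int)


def neighbor_trace(mol: Molecule, atom: int) -> np.ndarray:
    """Element counts of neighbors at graph distance exactly 1 and
    exactly 2 (shortest-path semantics: a level-1 atom never recounts
    at level 2); 10 + 10 numbers in the supported-element order."""
    adj = mol.adjacency()
    level1 = set(adj[atom])
    level2: set[int] = set()
    for v in level1:
        for w in adj[v]:
            if w != atom and w not in level1:
                level2.add(w)
    out = np.zeros(20)
    for v in level1:
        out[_ELEMENT_INDEX[mol.atoms[v].element]] += 1
    for v in level2:
        out[10 + _ELEMENT_INDEX[mol.atoms[v].element]] += 1
    return out


# ---------------------------------------------------------------------------
# Full encoding
# ---------------------------------------------------------------------------

def encode_atom(mol: Molecule, rings: RingInfo, atom: int,
                radii: tuple[float, float, float] = DEFAULT_RADII) -> np.ndarray:
    """Assemble the 61-slot feature vector for one atom."""
    v = np.zeros(N_FEATURES)
    a = mol.atoms[atom]
    v[_ELEMENT_INDEX[a.element]] = 1.0
    hyb = hybridization(mol, rings, atom)
    if hyb != "n/a":
        v[10 + ("sp", "sp2", "sp3").index(hyb)] = 1.0
    rc = int(rings.atom_ring_count[atom])
    v[13] = 1.0 if rc > 0 else 0.0
    v[14] = rc
    v[15] = rings.atom_min_ring_size[atom]
    v[16] = rings.atom_max_ring_size[atom]
    if rc > 0:
        system = rings.system_of(atom)
        assert system is not None
        v[17] = system.n_rings
        v[18] = system.n_atoms
    trace = neighbor_trace(mol, atom)
    v[19:29] = trace[:10]
    v[29] = trace[:10].sum()  # heavy+H degree
    v[30:40] = trace[10:]
    v[40:55] = radial_counts(mol, atom, radii)
    n_orders = np.zeros(3)
    aromatic = 0.0
    for b in mol.bonds_of(atom):
        if b.aromatic:
            aromatic = 1.0
        n_orders[b.order - 1] += 1
    v[55:58] = n_orders
    v[58] = aromatic
    v[59] = a.formal_charge
    v[60] = mol.heavy_atom_count()
    return v


def encode_molecule(mol: Molecule,
                    radii: tuple[float, float, float] = DEFAULT_RADII,
                    labels: np.ndarray | None = None) -> FeatureTable:
    """Encode every atom of a molecule into a :class:`FeatureTable`
    (one row per atom, in atom order).  SMILES-derived molecules
    without coordinates get the deterministic approximate embedding.
    Rings are perceived once and shared across atoms."""
    if mol.n_atoms == 0:
        raise MoleculeError("cannot encode an empty molecule")
    if not mol.has_coords:
        mol = embed_coordinates(mol)
    rings = find_rings(mol)
    rows = _encode_all(mol, rings, radii)
    frame = pd.DataFrame(rows, columns=list(FEATURE_SCHEMA))
    frame["element"] = mol.elements
    if labels is not None:
        if len(labels) != mol.n_atoms:
            raise ValueError("label vector length does not match atom count")
        frame["label"] = np.asarray(labels, dtype=float)
    return FeatureTable(frame)


def _encode_all(mol: Molecule, rings: RingInfo,
                radii: tuple[float, float, float]) -> np.ndarray:
    # Vectorized whole-molecule encoding; agrees exactly with
    # encode_atom row by row (shared intermediates computed once).
    n = mol.n_atoms
    rows = np.zeros((n, N_FEATURES))
    elem_ids = np.array([_ELEMENT_INDEX[e] for e in mol.elements])
    rows[np.arange(n), elem_ids] = 1.0

    adj = mol.adjacency()
    incident: list[list] = [[] for _ in range(n)]
    for b in mol.bonds:
        incident[b.i].append(b)
        incident[b.j].append(b)

    # ring block
    rc = rings.atom_ring_count
    rows[:, 13] = (rc > 0).astype(float)
    rows[:, 14] = rc
    rows[:, 15] = rings.atom_min_ring_size
    rows[:, 16] = rings.atom_max_ring_size
    system_rings = np.zeros(n)
    system_atoms = np.zeros(n)
    for rs in rings.ring_systems:
        for a in rs.atoms:
            system_rings[a] = rs.n_rings
            system_atoms[a] = rs.n_atoms
    rows[:, 17] = system_rings
    rows[:, 18] = system_atoms

    # neighbor trace + degree
    for k in range(n):
        level1 = adj[k]
        l1set = set(level1)
        for v in level1:
            rows[k, 19 + elem_ids[v]] += 1
        level2 = {w for v in level1 for w in adj[v] if w != k and w not in l1set}
        for w in level2:
            rows[k, 30 + elem_ids[w]] += 1
        rows[k, 29] = len(level1)

    # radial counts: 3 masked distance matrices against element-bin one-hots
    xyz = mol.coords_array()
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    bins = _bin_ids(mol)
    onehot = np.zeros((n, 5))
    onehot[np.arange(n), bins] = 1.0
    for kr, r in enumerate(radii):
        mask = (dist <= r + _BOUNDARY_EPS).astype(float)
        np.fill_diagonal(mask, 0.0)
        rows[:, 40 + 5 * kr: 45 + 5 * kr] = mask @ onehot

    # bond-order counts, aromatic flag, hybridization
    for k in range(n):
        aromatic = 0.0
        for b in incident[k]:
            if b.aromatic:
                aromatic = 1.0
            rows[k, 55 + b.order - 1] += 1
        rows[k, 58] = aromatic
        hyb = hybridization(mol, rings, k)
        if hyb != "n/a":
            rows[k, 10 + ("sp", "sp2", "sp3").index(hyb)] = 1.0

    rows[:, 59] = [a.formal_charge for a in mol.atoms]
    rows[:, 60] = mol.heavy_atom_count()
    return rows
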