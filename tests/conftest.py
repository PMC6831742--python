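"""Shared fixtures: small reference molecules and random-graph builders."""

from __future__ import annotations

import numpy as np
import pytest

from chargekit import Atom, Bond, Molecule, SyntheticSpec, generate_molecule, parse_smiles


def pdb_atom_line(serial: int, name: str, x: float, y: float, z: float, element: str) -> str:
    return (
        f"ATOM  {serial:>5} {name:<4} LIG A   1    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
    )


@pytest.fixture
def methane() -> Molecule:
    return parse_smiles("C")


@pytest.fixture
def ethanol() -> Molecule:
    return parse_smiles("CCO")


@pytest.fixture
def benzene_sdf() -> str:
    """Benzene ring (heavy atoms + hydrogens) with order-4 ring bonds."""
    coords = []
    for k in range(6):
        ang = np.pi / 3 * k
        coords.append((1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0))
    for k in range(6):
        ang = np.pi / 3 * k
        coords.append((2.48 * np.cos(ang), 2.48 * np.sin(ang), 0.0))
    lines = ["benzene", "  test", "", " 12 12  0  0  0  0  0  0  0  0999 V2000"]
    for k, (x, y, z) in enumerate(coords):
        elem = "C" if k < 6 else "H"
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {elem:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for k in range(6):
        lines.append(f"{k + 1:>3}{(k + 1) % 6 + 1:>3}  4  0")
    for k in range(6):
        lines.append(f"{k + 1:>3}{k + 7:>3}  1  0")
    lines += ["M  END", "$$$$"]
    return "\n".join(lines) + "\n"


def carbon_skeleton(n: int, edges: list[tuple[int, int]]) -> Molecule:
    """Bare all-carbon graph (no hydrogens, no coordinates needed for
    ring perception); degree must stay <= 4."""
    atoms = [Atom(k, "C", np.zeros(3)) for k in range(n)]
    bonds = [Bond(min(i, j), max(i, j), 1) for i, j in edges]
    return Molecule(f"skel-{n}", atoms, bonds, orders_reliable=False)


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 12):
    """Random connected degree-<=4 graph: spanning tree + extra edges."""
    n = int(rng.integers(3, max_nodes + 1))
    degree = [0] * n
    edges: list[tuple[int, int]] = []
    for v in range(1, n):
        candidates = [u for u in range(v) if degree[u] < 4]
        if not candidates:
            break
        u = int(rng.choice(candidates))
        edges.append((u, v))
        degree[u] += 1
        degree[v] += 1
    n_extra = int(rng.integers(0, 4))
    for _ in range(n_extra):
        pairs = [
            (i, j) for i in range(n) for j in range(i + 1, n)
            if degree[i] < 4 and degree[j] < 4 and (i, j) not in edges
        ]
        if not pairs:
            break
        i, j = pairs[int(rng.integers(len(pairs)))]
        edges.append((i, j))
        degree[i] += 1
        degree[j] += 1
    return n, edges


@pytest.fixture(scope="session")
def synthetic_corpus_small() -> list[Molecule]:
    """200 molecules under default study conditions, for unit-level sweeps."""
    spec = SyntheticSpec(seed=7)
    return [generate_molecule(spec, k) for k in range(200)]
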