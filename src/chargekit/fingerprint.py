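"""Linear path-fragment fingerprints and Tanimoto similarity.

A molecule's fingerprint is the exact set of its linear heavy-atom
fragments: every simple path of 2–7 heavy atoms, rendered as element
symbols joined by bond-order marks and canonicalized by taking the
lexicographically smaller reading direction.  Similarity between two
molecules is the Tanimoto coefficient |A∩B| / |A∪B| over these sets.
Unlike hashed bitvector fingerprints there are no collisions, so the
coefficient is an exact set statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import Molecule

__all__ = ["Fingerprint", "path_fragments", "tanimoto", "pairwise_tanimoto"]

_BOND_MARK = {1: "-", 2: "=", 3: "#"}


@dataclass(frozen=True)
class Fingerprint:
    """Set of canonical linear heavy-atom fragment strings."""

    fragments: frozenset[str]

    def __len__(self) -> int:
        return len(self.fragments)


def _render(elements: list[str], marks: list[str]) -> str:
    parts = [elements[0]]
    for e, m in zip(elements[1:], marks):
        parts.append(m)
        parts.append(e)
    forward = "".join(parts)
    parts_r = [elements[-1]]
    for e, m in zip(reversed(elements[:-1]), reversed(marks)):
        parts_r.append(m)
        parts_r.append(e)
    backward = "".join(parts_r)
    return min(forward, backward)


def path_fragments(mol: Molecule, max_len: int = 7) -> Fingerprint:
    """Enumerate all simple heavy-atom paths of 2..max_len atoms by DFS
    and collect their canonical renderings; hydrogens are excluded."""
    heavy = [a.index for a in mol.atoms if a.element != "H"]
    heavy_set = set(heavy)
    adj: dict[int, list[tuple[int, str]]] = {k: [] for k in heavy}
    for b in mol.bonds:
        if b.i in heavy_set and b.j in heavy_set:
            mark = ":" if b.aromatic else _BOND_MARK[b.order]
            adj[b.i].append((b.j, mark))
            adj[b.j].append((b.i, mark))
    fragments: set[str] = set()
    elements = {a.index: a.element for a in mol.atoms}

    def extend(path: list[int], marks: list[str], on_path: set[int]) -> None:
        if len(path) >= 2:
            fragments.add(_render([elements[k] for k in path], marks))
        if len(path) == max_len:
            return
        for nxt, mark in adj[path[-1]]:
            if nxt not in on_path:
                path.append(nxt)
                marks.append(mark)
                on_path.add(nxt)
                extend(path, marks, on_path)
                on_path.discard(nxt)
                marks.pop()
                path.pop()

    for start in heavy:
        extend([start], [], {start})
    return Fingerprint(frozenset(fragments))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Set Tanimoto coefficient |A∩B| / |A∪B| in [0, 1]."""
    if not a.fragments and not b.fragments:
        raise ValueError("Tanimoto undefined: both fragment sets empty")
    inter = len(a.fragments & b.fragments)
    union = len(a.fragments | b.fragments)
    return inter / union


def pairwise_tanimoto(mols: list[Molecule], max_len: int = 7) -> tuple[np.ndarray, dict]:
    """All-against-all similarity matrix plus a summary over the strict
    upper triangle (median and quartiles) for dataset-diversity checks."""
    if len(mols) < 2:
        raise ValueError("need at least 2 molecules for pairwise similarity")
    fps = [path_fragments(m, max_len) for m in mols]
    n = len(fps)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = tanimoto(fps[i], fps[j])
    upper = mat[np.triu_indices(n, k=1)]
    summary = {
        "median": float(np.median(upper)),
        "q1": float(np.percentile(upper, 25)),
        "q3": float(np.percentile(upper, 75)),
        "n_pairs": int(upper.size),
    }
    return mat, summary
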