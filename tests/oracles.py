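"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: linear paths are
enumerated by exhaustive permutation of atom-index subsets, Tanimoto is
computed on raw canonical-path string sets (no hashing), and single
linkage is the textbook O(n^3) loop over cluster pairs.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from rdkit import Chem


def brute_force_paths(smiles: str, max_atoms: int = 7) -> set[str]:
    """All linear heavy-atom paths of 1..max_atoms atoms, by exhaustion.

    Every permutation of every atom-index subset is checked for being a
    bonded chain; only feasible for small molecules (<= ~9 heavy atoms).
    """
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    n = mol.GetNumAtoms()
    assert n <= 9, "brute-force oracle is exponential; keep molecules small"

    def token(i):
        a = mol.GetAtomWithIdx(i)
        return a.GetSymbol().lower() if a.GetIsAromatic() else a.GetSymbol()

    bond_sym = {Chem.BondType.SINGLE: "-", Chem.BondType.DOUBLE: "=",
                Chem.BondType.TRIPLE: "#", Chem.BondType.AROMATIC: ":"}

    out: set[str] = set()
    for size in range(1, min(max_atoms, n) + 1):
        for subset in combinations(range(n), size):
            for perm in permutations(subset):
                ok = True
                parts = [token(perm[0])]
                for a, b in zip(perm, perm[1:]):
                    bond = mol.GetBondBetweenAtoms(a, b)
                    if bond is None:
                        ok = False
                        break
                    parts.append(bond_sym[bond.GetBondType()])
                    parts.append(token(b))
                if ok:
                    s = "".join(parts)
                    out.add(min(s, s[::-1]))
    return out


def set_tanimoto(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def naive_single_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of single-linkage clustering, textbook O(n^3)."""
    n = len(dist)
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a, b in combinations(range(len(clusters)), 2):
            d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
            if d < best[0]:
                best = (d, (a, b))
        d, (a, b) = best
        heights.append(float(d))
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


def naive_components_below(dist: np.ndarray, threshold: float) -> list[frozenset]:
    """Connected components of the graph with edges dist < threshold."""
    n = len(dist)
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], set()
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in range(n):
                if not seen[v] and dist[u, v] < threshold:
                    seen[v] = True
                    stack.append(v)
        comps.append(frozenset(comp))
    return comps
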