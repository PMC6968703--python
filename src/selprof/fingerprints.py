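"""Molecular fingerprints and Tanimoto similarity/distance matrices.

Two fingerprint schemes are provided:

``path``
    A hashed path-based fingerprint in the spirit of the classic FP2
    design: every simple linear path of 1-7 heavy atoms is written as a
    canonical string over (element, aromaticity, bond order), taking the
    lexicographically smaller of the two reading directions, and hashed
    to one of 1024 bits with 64-bit FNV-1a followed by XOR-folding. The
    hash is fixed and versioned (:data:`HASH_VERSION`) so fingerprints
    are reproducible across platforms. Unlike the original FP2, lone
    single-atom paths are indexed for all elements.

``keys``
    The public 166-key structural-key set (MACCS), evaluated by this
    module's own SMARTS matching loop: bit k is set when the molecule
    matches key k's pattern (with the key's minimum-match-count
    semantics); key 125 (more than one aromatic ring) and key 166 (more
    than one fragment) are evaluated structurally. Key definitions are
    the public set shipped with RDKit.

Similarity between fingerprints A and B is the Tanimoto index
Ti = |A∩B| / |A∪B| on the set bits, and Td = 1 - Ti the corresponding
distance.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.MACCSkeys import smartsPatts as _MACCS_SMARTS

from .datamodel import Fingerprint, LigandEntry, PairwiseMatrix

__all__ = [
    "HASH_VERSION",
    "PATH_NBITS",
    "KEYS_NBITS",
    "MAX_PATH_ATOMS",
    "path_fingerprint",
    "key_fingerprint",
    "make_fingerprint",
    "tanimoto",
    "tanimoto_distance",
    "build_matrices",
]

PATH_NBITS = 1024
KEYS_NBITS = 166
MAX_PATH_ATOMS = 7

#: Identifier of the path-hashing function, recorded in matrix sidecars.
HASH_VERSION = "fnv1a64-xorfold10-v1"

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol


# ---------------------------------------------------------------------------
# path-based scheme
# ---------------------------------------------------------------------------

def _fnv1a64(data: bytes) -> int:
    h = _FNV_OFFSET
    for byte in data:
        h = ((h ^ byte) * _FNV_PRIME) & _MASK64
    return h


def _fold_to_bits(h: int, nbits_pow2: int = PATH_NBITS) -> int:
    # XOR-fold 64 -> 32 -> 16 -> 10 bits
    h = (h >> 32) ^ (h & 0xFFFFFFFF)
    h = (h >> 16) ^ (h & 0xFFFF)
    h = (h >> 10) ^ (h & 0x3FF)
    return h % nbits_pow2


_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _atom_token(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def canonical_paths(mol: Chem.Mol, max_atoms: int = MAX_PATH_ATOMS) -> set[str]:
    """All simple linear heavy-atom paths of 1..max_atoms atoms.

    Each path is rendered as ``atom (bond atom)*`` tokens and
    canonicalized to the lexicographically smaller of its two reading
    directions, so a path and its reverse index the same feature.
    """
    atoms = [_atom_token(a) for a in mol.GetAtoms()]
    bonds: dict[tuple[int, int], str] = {}
    adjacency: list[list[int]] = [[] for _ in atoms]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        sym = _BOND_SYMBOL.get(bond.GetBondType(), "~")
        bonds[(i, j)] = bonds[(j, i)] = sym
        adjacency[i].append(j)
        adjacency[j].append(i)

    paths: set[str] = set()

    def render(idx_path: list[int]) -> str:
        tokens = [atoms[idx_path[0]]]
        for a, b in zip(idx_path, idx_path[1:]):
            tokens.append(bonds[(a, b)])
            tokens.append(atoms[b])
        forward = "".join(tokens)
        backward = "".join(reversed(tokens))
        return min(forward, backward)

    def extend(idx_path: list[int]) -> None:
        paths.add(render(idx_path))
        if len(idx_path) == max_atoms:
            return
        tail = idx_path[-1]
        for nxt in adjacency[tail]:
            if nxt not in idx_path:  # simple (non-self-intersecting) paths
                idx_path.append(nxt)
                extend(idx_path)
                idx_path.pop()

    for start in range(len(atoms)):
        extend([start])
    return paths


def path_fingerprint(smiles: str) -> Fingerprint:
    """Hashed path fingerprint (1024 bits) of a SMILES string."""
    mol = _parse(smiles)
    bits = frozenset(
        _fold_to_bits(_fnv1a64(p.encode("utf-8")))
        for p in canonical_paths(mol)
    )
    return Fingerprint(scheme="path", nbits=PATH_NBITS, bits=bits)


# ---------------------------------------------------------------------------
# structural-key scheme
# ---------------------------------------------------------------------------

_compiled_keys: Optional[list[tuple[Optional[Chem.Mol], int]]] = None


def _maccs_keys() -> list[tuple[Optional[Chem.Mol], int]]:
    global _compiled_keys
    if _compiled_keys is None:
        compiled = []
        for k in range(1, KEYS_NBITS + 1):
            patt, count = _MACCS_SMARTS[k]
            if patt == "?":
                compiled.append((None, count))
            else:
                q = Chem.MolFromSmarts(patt)
                if q is None:  # pragma: no cover - definitions are fixed
                    raise RuntimeError(f"structural key {k} failed to compile")
                compiled.append((q, count))
        _compiled_keys = compiled
    return _compiled_keys


def _n_aromatic_rings(mol: Chem.Mol) -> int:
    n = 0
    for ring in mol.GetRingInfo().BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n += 1
    return n


def key_fingerprint(smiles: str) -> Fingerprint:
    """166-bit structural-key fingerprint of a SMILES string.

    Bit k (0-based index k-1) is set when the molecule matches key k's
    SMARTS pattern; keys carrying a minimum count require strictly more
    than that many substructure matches. Keys that cannot be expressed
    as SMARTS are evaluated structurally: key 125 fires on molecules
    with more than one aromatic ring, key 166 on disconnected
    structures.
    """
    mol = _parse(smiles)
    bits = set()
    for k, (query, count) in enumerate(_maccs_keys(), start=1):
        if query is not None:
            if count == 0:
                hit = mol.HasSubstructMatch(query)
            else:
                hit = len(mol.GetSubstructMatches(query)) > count
        elif k == 125:
            hit = _n_aromatic_rings(mol) > 1
        elif k == 166:
            hit = len(Chem.GetMolFrags(mol)) > 1
        else:
            hit = False
        if hit:
            bits.add(k - 1)
    return Fingerprint(scheme="keys", nbits=KEYS_NBITS, bits=frozenset(bits))


def make_fingerprint(smiles: str, scheme: str) -> Fingerprint:
    """Dispatch to :func:`path_fingerprint` or :func:`key_fingerprint`."""
    if scheme == "path":
        return path_fingerprint(smiles)
    if scheme == "keys":
        return key_fingerprint(smiles)
    raise ValueError(f"unknown fingerprint scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Tanimoto similarity
# ---------------------------------------------------------------------------

def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Ti = |A∩B| / |A∪B|; a pair of all-zero fingerprints scores 0."""
    if a.scheme != b.scheme:
        raise ValueError(f"fingerprint scheme mismatch: {a.scheme} vs {b.scheme}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Td = 1 - Ti."""
    return 1.0 - tanimoto(a, b)


def build_matrices(
    entries: Sequence[LigandEntry],
    scheme: str = "keys",
) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Ti and Td matrices over a curated ligand set.

    Both matrices share the ligand order of ``entries``; the distance
    matrix is exactly ``1 - similarity`` elementwise with a unit/zero
    diagonal. Any unparsable SMILES aborts with the offending CIDs.
    """
    if len(entries) < 2:
        raise ValueError("need at least 2 ligands to build pairwise matrices")
    fps = []
    bad: list[str] = []
    for e in entries:
        try:
            fps.append(make_fingerprint(e.smiles, scheme))
        except ValueError:
            bad.append(e.cid)
    if bad:
        raise ValueError("unparsable SMILES for CID(s): " + ", ".join(bad))

    nbits = fps[0].nbits
    bitmat = np.zeros((len(fps), nbits), dtype=np.int64)
    for i, fp in enumerate(fps):
        if fp.bits:
            bitmat[i, sorted(fp.bits)] = 1
    inter = bitmat @ bitmat.T
    pop = bitmat.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        ti = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(ti, 1.0)
    order = [e.cid for e in entries]
    sim = PairwiseMatrix(kind="similarity", values=ti, ligand_order=order)
    td = 1.0 - ti
    np.fill_diagonal(td, 0.0)
    dist = PairwiseMatrix(kind="distance", values=td, ligand_order=order)
    return sim, dist
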