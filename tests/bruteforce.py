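"""Brute-force substructure enumerators used as fingerprint oracles.

Each function counts the *distinct substructural features* of a small
molecule by explicit graph enumeration — linear bond paths, typed atom
pairs, typed 4-atom torsions and circular atom environments — without
touching the hashing/folding pipeline under test.  On molecules small
enough that hash collisions are absent, the set-bit count of the
corresponding fingerprint must equal the enumerated feature count.

"""

from __future__ import annotations

from rdkit import Chem


def NumPiElectrons(atom: Chem.Atom) -> int:
    """Pi electrons an atom contributes: 1 if aromatic, otherwise one per
    extra bond order (double bond -> 1, triple -> 2)."""
    if atom.GetIsAromatic():
        return 1
    return sum(int(b.GetBondTypeAsDouble()) - 1 for b in atom.GetBonds())


def _adjacency(mol: Chem.Mol) -> dict[int, list[tuple[int, int]]]:
    """atom index -> list of (neighbor atom index, bond index)."""
    adj: dict[int, list[tuple[int, int]]] = {a.GetIdx(): [] for a in mol.GetAtoms()}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i].append((j, bond.GetIdx()))
        adj[j].append((i, bond.GetIdx()))
    return adj


def _bond_type(mol: Chem.Mol, bond_idx: int) -> str:
    return str(mol.GetBondWithIdx(bond_idx).GetBondType())


# --------------------------------------------------------------------------
# linear paths (daylight-type)


def count_linear_paths(smiles: str, max_path: int = 7) -> int:
    """Number of distinct linear heavy-atom bond paths of 1..max_path bonds.

    Paths are bond-distinct walks: no bond is traversed twice, and a
    walk may close a cycle (revisit an atom) — but a cycle-containing
    walk only counts when its length is exactly ``max_path`` (shorter
    cyclic walks are excluded; acyclic walks of every length count).
    A path feature is identified by its sequence of (element, aromatic)
    atom labels and bond types, read in the canonical (lexicographically
    smaller) direction; each set of bonds is counted once.
    """
    mol = Chem.MolFromSmiles(smiles)
    adj = _adjacency(mol)

    def atom_label(i: int):
        a = mol.GetAtomWithIdx(i)
        return (a.GetAtomicNum(), a.GetIsAromatic())

    features: set[tuple] = set()
    seen_bond_sets: set[frozenset] = set()

    def extend(atoms: list[int], bonds: list[int]) -> None:
        if bonds:
            key = frozenset(bonds)
            acyclic = len(set(atoms)) == len(bonds) + 1
            if key not in seen_bond_sets and (acyclic or len(bonds) == max_path):
                seen_bond_sets.add(key)
                labels = tuple(atom_label(i) for i in atoms)
                bt = tuple(_bond_type(mol, b) for b in bonds)
                forward = (labels, bt)
                backward = (labels[::-1], bt[::-1])
                features.add(min(forward, backward))
            if len(bonds) == max_path:
                return
        tail = atoms[-1]
        for nbr, bond in adj[tail]:
            if bond in bonds:
                continue
            extend(atoms + [nbr], bonds + [bond])

    for start in adj:
        extend([start], [])
    return len(features)


# --------------------------------------------------------------------------
# atom pairs


def _pair_code(mol: Chem.Mol, i: int) -> tuple:
    a = mol.GetAtomWithIdx(i)
    return (a.GetAtomicNum(), a.GetDegree(), NumPiElectrons(a))


def _distance_matrix(mol: Chem.Mol) -> list[list[int]]:
    """All-pairs shortest path lengths by BFS (heavy-atom graph)."""
    n = mol.GetNumAtoms()
    adj = _adjacency(mol)
    dist = [[-1] * n for _ in range(n)]
    for s in range(n):
        dist[s][s] = 0
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                for v, _ in adj[u]:
                    if dist[s][v] == -1:
                        dist[s][v] = dist[s][u] + 1
                        nxt.append(v)
            queue = nxt
    return dist


def count_atom_pairs(smiles: str) -> int:
    """Number of distinct (typed atom, typed atom, topological distance)
    triples over all heavy-atom pairs."""
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    dist = _distance_matrix(mol)
    features = set()
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = _pair_code(mol, i), _pair_code(mol, j)
            features.add((min(ci, cj), max(ci, cj), dist[i][j]))
    return len(features)


# --------------------------------------------------------------------------
# topological torsions


def count_torsions(smiles: str) -> int:
    """Number of distinct typed linear 4-heavy-atom bonded paths.

    Atom types are the atom-pair codes with the degree reduced by the
    number of in-path bonds at that atom (so path-internal bonds do not
    count toward branching).
    """
    mol = Chem.MolFromSmiles(smiles)
    adj = _adjacency(mol)
    features = set()

    def code(i: int, in_path_bonds: int) -> tuple:
        a = mol.GetAtomWithIdx(i)
        return (a.GetAtomicNum(), a.GetDegree() - in_path_bonds, NumPiElectrons(a))

    for a in adj:
        for b, _ in adj[a]:
            for c, _ in adj[b]:
                if c == a:
                    continue
                for d, _ in adj[c]:
                    if d in (a, b):
                        continue
                    if a > d or (a == d):  # canonical direction; a==d impossible on a path
                        continue
                    path = (code(a, 1), code(b, 2), code(c, 2), code(d, 1))
                    features.add(min(path, path[::-1]))
    return len(features)


# --------------------------------------------------------------------------
# circular environments (Morgan)


def count_morgan_environments(smiles: str, radius: int = 2) -> int:
    """Number of distinct circular atom environments up to ``radius``.

    Implements the iterative environment construction directly: the
    radius-0 identifier is the atom's (element, degree, H count, charge,
    ring membership) tuple; the radius-r identifier combines the
    radius-(r-1) identifier with the sorted (bond type, neighbor
    identifier) list.  An environment is dropped when it stops growing
    (its bond set equals the previous radius) or when its bond set was
    already contributed by another atom at an earlier-or-equal radius.
    """
    mol = Chem.MolFromSmiles(smiles)
    adj = _adjacency(mol)
    n = mol.GetNumAtoms()

    def init_code(i: int) -> tuple:
        a = mol.GetAtomWithIdx(i)
        return (
            a.GetAtomicNum(),
            a.GetDegree(),
            a.GetTotalNumHs(),
            a.GetFormalCharge(),
            a.IsInRing(),
        )

    codes: dict[int, tuple] = {i: init_code(i) for i in range(n)}
    # bonds within radius r of each atom
    bond_sets: dict[int, frozenset] = {i: frozenset() for i in range(n)}
    features: set[tuple] = set()
    emitted_bond_sets: set[frozenset] = set()

    for i in range(n):
        features.add(codes[i])
        emitted_bond_sets.add(frozenset({("atom", i)}))  # radius-0 envs never clash

    for _ in range(radius):
        new_codes = {}
        new_bond_sets = {}
        for i in range(n):
            nbrs = sorted((_bond_type(mol, b), codes[j]) for j, b in adj[i])
            new_codes[i] = (codes[i], tuple(nbrs))
            grown = set(bond_sets[i])
            for j, b in adj[i]:
                grown.add(b)
                grown |= bond_sets[j]
            new_bond_sets[i] = frozenset(grown)
        for i in range(n):
            if new_bond_sets[i] == bond_sets[i]:
                continue  # environment no longer grows
            if new_bond_sets[i] in emitted_bond_sets:
                continue  # same bond set already contributed
            emitted_bond_sets.add(new_bond_sets[i])
            features.add(new_codes[i])
        codes = new_codes
        bond_sets = new_bond_sets
    return len(features)
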