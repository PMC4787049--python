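"""Ligand classification and per-protein ligand diversity.

Ligands co-crystallized with enzyme structures are represented as small
molecular graphs (element, formal charge, chirality on atoms; order on
bonds). Crystallization additives (water, glycerol, cryoprotectants,
detergents, buffer ions) are filtered out; the remaining ligands are
deduplicated with a Morgan-style canonical key and compared with a path
fingerprint under the Tanimoto coefficient, yielding a per-protein ligand
diversity profile (a protein binding more than six distinct ligands is
flagged as promiscuous).
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field

FINGERPRINT_BITS = 1024
MAX_PATH_LENGTH = 7
PROMISCUITY_THRESHOLD = 6  # strictly more than this many distinct ligands

# Crystallization additives and ions excluded from the metabolic-ligand set.
# Metal cofactors are retained by default (keep_metals flag).
NONMETABOLIC_CODES = frozenset({
    "HOH", "DOD", "GOL", "EDO", "PEG", "PGE", "PG4", "MPD", "BOG", "LDA",
    "SDS", "DMS", "ACT", "ACY", "FMT", "EOH", "MOH", "IPA", "TRS", "EPE",
    "MES", "BME", "DTT", "IMD", "SO4", "PO4", "NO3", "CO3", "AZI", "CL",
    "BR", "IOD", "F", "NA", "K", "CS", "LI", "NH4",
})
METAL_CODES = frozenset({"MG", "MN", "ZN", "FE", "FE2", "CA", "CU", "CO", "NI", "MO", "W"})


@dataclass(frozen=True)
class LigandAtom:
    element: str
    charge: int = 0
    chirality: str = ""  # "", "R", "S"


@dataclass
class LigandGraph:
    code: str
    atoms: list[LigandAtom]
    bonds: list[tuple[int, int, str]]  # (i, j, order in {"1","2","3","ar"})

    def __post_init__(self):
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < len(self.atoms) and 0 <= j < len(self.atoms)) or i == j:
                raise ValueError(f"{self.code}: invalid bond ({i}, {j})")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"{self.code}: duplicate bond ({i}, {j})")
            seen.add(key)

    def neighbors(self) -> list[list[tuple[int, str]]]:
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj

    def components(self) -> list[list[int]]:
        adj = self.neighbors()
        seen: set[int] = set()
        comps = []
        for start in range(len(self.atoms)):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                v = stack.pop()
                comp.append(v)
                for w, _ in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            comps.append(sorted(comp))
        return comps


def _initial_invariants(g: LigandGraph) -> list[str]:
    adj = g.neighbors()
    inv = []
    for idx, atom in enumerate(g.atoms):
        degree = len(adj[idx])
        valence = sum({"1": 1, "2": 2, "3": 3, "ar": 1.5}[o] for _, o in adj[idx])
        inv.append(f"{atom.element}|{atom.charge}|{degree}|{valence}|{atom.chirality}")
    return inv


def canonical_key(g: LigandGraph) -> str:
    """Relabeling-invariant structural key by iterative neighborhood refinement.

    Atom invariants start from (element, charge, degree, valence, chirality)
    and are refined by the sorted multiset of (bond order, neighbor invariant)
    until the partition stabilizes; the key combines the final invariant
    multiset with the bond-class multiset. Heuristic: isomorphic graphs always
    collide, highly symmetric non-isomorphic pairs may too.
    """
    comps = g.components()
    if len(comps) > 1:
        keys = []
        for comp in comps:
            remap = {old: new for new, old in enumerate(comp)}
            sub = LigandGraph(g.code, [g.atoms[i] for i in comp],
                              [(remap[i], remap[j], o) for i, j, o in g.bonds
                               if i in remap and j in remap])
            keys.append(canonical_key(sub))
        return ".".join(sorted(keys))
    adj = g.neighbors()
    base = _initial_invariants(g)
    inv = list(base)
    for _ in range(len(g.atoms) + 1):
        refined = [inv[i] + "#" + ";".join(sorted(f"{o}:{inv[w]}" for w, o in adj[i]))
                   for i in range(len(g.atoms))]
        # re-rank to keep labels short; ranks are relabeling-invariant
        ranks = {s: str(r) for r, s in enumerate(sorted(set(refined)))}
        new_inv = [ranks[refined[i]] + "|" + base[i] for i in range(len(g.atoms))]
        stable = _partition(new_inv) == _partition(inv)
        inv = new_inv
        if stable:
            break
    final = sorted(Counter(inv).items())
    bonds = sorted(Counter(
        "-".join(sorted((inv[i], inv[j]))) + f"~{o}" for i, j, o in g.bonds).items())
    return repr(final) + "||" + repr(bonds)


def _partition(labels: list[str]) -> list[tuple[int, ...]]:
    groups: dict[str, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    return sorted(tuple(v) for v in groups.values())


def _hash_bit(s: str, n_bits: int) -> int:
    h = hashlib.blake2b(s.encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % n_bits


@dataclass
class Fingerprint:
    bits: frozenset[int]
    n_bits: int = FINGERPRINT_BITS
    max_path: int = MAX_PATH_LENGTH


def fingerprint(g: LigandGraph, n_bits: int = FINGERPRINT_BITS,
                max_path: int = MAX_PATH_LENGTH) -> Fingerprint:
    """Path fingerprint: hash every simple path of 0..max_path bonds.

    Each path maps to the lexicographically smaller of its two direction
    strings (element and bond-order alternation), so the bitset is invariant
    to atom ordering.
    """
    adj = g.neighbors()
    bits: set[int] = set()

    def grow(path_atoms: list[int], path_str: list[str]):
        forward = "".join(path_str)
        backward = "".join(reversed(path_str))
        bits.add(_hash_bit(min(forward, backward), n_bits))
        if (len(path_str) + 1) // 2 >= max_path + 1:
            return
        last = path_atoms[-1]
        for w, order in adj[last]:
            if w in path_atoms:
                continue
            grow(path_atoms + [w], path_str + [order, g.atoms[w].element])

    for start in range(len(g.atoms)):
        grow([start], [g.atoms[start].element])
    return Fingerprint(frozenset(bits), n_bits, max_path)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets are identical (1.0)."""
    if a.n_bits != b.n_bits or a.max_path != b.max_path:
        raise ValueError("fingerprints generated with different parameters")
    if not a.bits and not b.bits:
        return 1.0
    union = len(a.bits | b.bits)
    return len(a.bits & b.bits) / union


def filter_nonmetabolic(codes: list[str], keep_metals: bool = True) -> list[str]:
    """Drop crystallization additives; optionally drop metal ions too."""
    excluded = NONMETABOLIC_CODES if keep_metals else (NONMETABOLIC_CODES | METAL_CODES)
    return [c for c in codes if c.upper() not in excluded]


def ligand_diversity(protein_ligands: dict[str, list[LigandGraph]]) -> dict:
    """Per-protein distinct-ligand counts and fingerprint diversity.

    Returns per-protein records (n_distinct, max pairwise distance
    = 1 - min Tanimoto, promiscuity flag for > 6 distinct ligands) plus the
    histogram of distinct-ligand counts across proteins.
    """
    records = {}
    for protein, graphs in sorted(protein_ligands.items()):
        distinct: dict[str, LigandGraph] = {}
        for g in graphs:
            distinct.setdefault(canonical_key(g), g)
        fps = [fingerprint(g) for g in distinct.values()]
        max_dist = 0.0
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                max_dist = max(max_dist, 1.0 - tanimoto(fps[i], fps[j]))
        records[protein] = {
            "n_distinct": len(distinct),
            "max_pairwise_distance": max_dist,
            "gt6_flag": len(distinct) > PROMISCUITY_THRESHOLD,
        }
    histogram = Counter(rec["n_distinct"] for rec in records.values())
    return {"per_protein": records, "histogram": dict(sorted(histogram.items()))}


# ---------------------------------------------------------------------------
# TSV ligand-graph format: one block per ligand
#   LIGAND <code>
#   ATOM <idx> <element> <charge> <chirality|->
#   BOND <i> <j> <order>

def read_ligand_tsv(text: str) -> list[LigandGraph]:
    graphs: list[LigandGraph] = []
    code, atoms, bonds = None, [], []

    def flush():
        if code is not None:
            graphs.append(LigandGraph(code, list(atoms), list(bonds)))

    for line in text.splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "LIGAND":
            flush()
            code, atoms, bonds = parts[1], [], []
        elif parts[0] == "ATOM":
            chir = parts[4] if len(parts) > 4 and parts[4] != "-" else ""
            atoms.append(LigandAtom(parts[2], int(parts[3]), chir))
        elif parts[0] == "BOND":
            bonds.append((int(parts[1]), int(parts[2]), parts[3]))
        else:
            raise ValueError(f"unrecognized ligand record: {line!r}")
    flush()
    return graphs


def write_ligand_tsv(graphs: list[LigandGraph]) -> str:
    lines = []
    for g in graphs:
        lines.append(f"LIGAND {g.code}")
        for idx, a in enumerate(g.atoms):
            lines.append(f"ATOM {idx} {a.element} {a.charge} {a.chirality or '-'}")
        for i, j, order in g.bonds:
            lines.append(f"BOND {i} {j} {order}")
    return "\n".join(lines) + "\n"
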