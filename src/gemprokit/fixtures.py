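"""Synthetic test substrates with planted ground truth.

Every stage of the toolkit can be exercised without downloading anything:
ideal-geometry peptides (helix, hairpin, mutants, gapped chains, disulfide
dimers), viable toy metabolic models with known GPR structure, abundance and
melting-temperature tables, ligand graph sets and clustered feature
matrices. Generators are deterministic: the same parameters and seed give
byte-identical output, and each generator also returns the planted truth so
tests can assert against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .ligands import LigandAtom, LigandGraph
from .model_io import MetabolicModel, Reaction, model_to_json
from .props import FEATURE_NAMES
from .refine import graft_sidechain
from .structures import Atom, ChainRecord, Residue, StructureRecord, write_pdb

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0
# Open extended conformation in which the idealized side-chain templates are
# mutually clash-free at the 0.8 contact scale (found by dihedral scan); used
# for mutation/gap fixtures so residual clashes are attributable to grafts.
OPEN_PHI, OPEN_PSI = -170.0, 70.0


def build_backbone(sequence: str, phi: float, psi: float,
                   first_resnum: int = 1, chain_id: str = "A") -> StructureRecord:
    """Peptide backbone (N, CA, C, O) from ideal internal coordinates.

    Uniform (phi, psi) for every residue, omega fixed trans (180 deg).
    """
    n = len(sequence)
    if n < 1:
        raise ValueError("empty sequence")
    from Bio.SeqUtils import seq3

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (geometry.BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(geometry.ANGLE_N_CA_C)
    C[0] = CA[0] + geometry.BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = geometry.place_atom(N[i - 1], CA[i - 1], C[i - 1],
                                   geometry.BOND_C_N, geometry.ANGLE_CA_C_N, psi)
        CA[i] = geometry.place_atom(CA[i - 1], C[i - 1], N[i],
                                    geometry.BOND_N_CA, geometry.ANGLE_C_N_CA,
                                    geometry.OMEGA)
        C[i] = geometry.place_atom(C[i - 1], N[i], CA[i],
                                   geometry.BOND_CA_C, geometry.ANGLE_N_CA_C, phi)
    for i in range(n):
        # carbonyl O opposite the next amide N (psi + 180)
        O[i] = geometry.place_atom(N[i], CA[i], C[i],
                                   geometry.BOND_C_O, geometry.ANGLE_CA_C_O, psi + 180.0)
    residues = []
    for i, aa in enumerate(sequence):
        name3 = seq3(aa).upper()
        residues.append(Residue(first_resnum + i, name3, [
            Atom("N", "N", N[i].copy()),
            Atom("CA", "C", CA[i].copy()),
            Atom("C", "C", C[i].copy()),
            Atom("O", "O", O[i].copy()),
        ]))
    chain = ChainRecord(chain_id, residues)
    return StructureRecord("fixture", chains={chain_id: chain})


def build_peptide(sequence: str, phi: float, psi: float,
                  first_resnum: int = 1, chain_id: str = "A") -> StructureRecord:
    """Backbone plus idealized side chains for every residue."""
    struct = build_backbone(sequence, phi, psi, first_resnum, chain_id)
    for res, aa in zip(struct.chains[chain_id].residues, sequence):
        struct = graft_sidechain(struct, chain_id, res.number, aa)
    return struct


def make_helix_pdb(n_res: int = 12, phi: float = HELIX_PHI, psi: float = HELIX_PSI,
                   sequence: str | None = None, resolution: float | None = 2.0) -> str:
    """Ideal poly-Ala alpha-helix as PDB text."""
    if n_res < 2:
        raise ValueError("n_res >= 2 required")
    seq = sequence or "A" * n_res
    struct = build_peptide(seq, phi, psi)
    struct.structure_id = "HELIX"
    struct.resolution = resolution
    return write_pdb(struct)


def _rigid_transform(struct: StructureRecord, rot: np.ndarray, trans: np.ndarray):
    for _, _, atom in struct.iter_atoms():
        atom.coord = rot @ atom.coord + trans


def make_hairpin_pdb(strand_len: int = 6, resolution: float = 2.0) -> str:
    """Two antiparallel ideal strands with an inter-strand hydrogen-bond register.

    The second strand is the first one flipped 180 degrees and shifted; the
    shift is picked by a deterministic grid search maximizing Kabsch-Sander
    inter-strand hydrogen bonds. Residue numbering leaves a gap (no loop is
    modeled), so the two strands read as one chain with a chain break.
    """
    from .props import _hbond_matrix

    seq = "V" * strand_len
    phi, psi = -135.0, 135.0  # mild pleat; flat enough for a rigid flipped partner
    s1 = build_peptide(seq, phi, psi)
    s2_base = build_peptide(seq, phi, psi, first_resnum=strand_len + 5)
    flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    best = None
    # local search around the known good register for this conformation
    for dy in np.arange(5.5, 7.25, 0.25):
        for dx in np.arange(-1.5, 1.75, 0.25):
            for dz in np.arange(0.0, 2.25, 0.25):
                s2 = s2_base.copy()
                _rigid_transform(s2, flip, np.array([dx, dy, dz]))
                merged = s1.copy()
                merged.chains["A"].residues += s2.chains["A"].residues
                hb = _hbond_matrix(merged.chains["A"])
                sym = sum(1 for i in range(strand_len)
                          for j in range(strand_len, 2 * strand_len)
                          if hb[i, j] and hb[j, i])
                inter = int(hb[:strand_len, strand_len:].sum()
                            + hb[strand_len:, :strand_len].sum())
                if best is None or (sym, inter) > best[:2]:
                    best = (sym, inter, merged)
    struct = best[2]
    struct.structure_id = "HAIRPIN"
    struct.resolution = resolution
    return write_pdb(struct)


@dataclass
class MutantTruth:
    wt_sequence: str
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)


def random_sequence(n: int, seed: int, alphabet: str = "ADEFGHIKLMNQRSTVWY") -> str:
    """Seeded random sequence; no Cys/Pro, and no CD1-bearing residue
    (Ile/Leu/Phe/Trp/Tyr) directly before a CG2-bearing one (Thr/Val/Ile) --
    the one bigram whose idealized extended rotamers collide even in the
    open conformation."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        aa = alphabet[int(rng.integers(0, len(alphabet)))]
        if out and out[-1] in "ILFWY" and aa in "TVI":
            continue
        out.append(aa)
    return "".join(out)


def make_mutant_pdb(n_res: int = 140, seed: int = 0,
                    mutations: list[tuple[int, str]] | None = None,
                    gaps: list[tuple[int, int]] | None = None,
                    resolution: float = 2.0,
                    wt_sequence: str | None = None) -> tuple[str, MutantTruth]:
    """Extended-backbone protein whose structure sequence deviates from the wild type.

    ``mutations`` are (1-based position, observed amino acid); ``gaps`` are
    (start position, length) of unresolved interior stretches. The extended
    conformation keeps the idealized side chains clash-free, so any steric
    strain after refinement is attributable to the grafted atoms. Returns the
    PDB text plus the planted truth (wild-type sequence, expected mutation
    and gap lists).
    """
    wt = wt_sequence or random_sequence(n_res, seed)
    mutations = mutations or []
    gaps = gaps or []
    observed = list(wt)
    truth = MutantTruth(wt_sequence=wt)
    for pos, aa in mutations:
        truth.mutations.append((pos, wt[pos - 1], aa))
        observed[pos - 1] = aa
    struct = build_peptide("".join(observed), OPEN_PHI, OPEN_PSI)
    drop: set[int] = set()
    for start, length in gaps:
        drop |= set(range(start, start + length))
        truth.gaps.append((start, length))
    chain = struct.chains["A"]
    chain.residues = [r for r in chain.residues if r.number not in drop]
    struct.structure_id = "MUTANT"
    struct.resolution = resolution
    return write_pdb(struct), truth


def make_fig_style_two_mutation_pdb(seed: int = 0) -> tuple[str, MutantTruth]:
    """Crystal-vs-wild-type fixture with Glu->His and Glu->Gln point mutations.

    The wild type carries Glu at positions 115 and 131; the 'crystal'
    structure shows His115 and Gln131.
    """
    wt = list(random_sequence(140, seed))
    wt[114], wt[130] = "E", "E"
    return make_mutant_pdb(n_res=140, seed=seed,
                           mutations=[(115, "H"), (131, "Q")],
                           wt_sequence="".join(wt))


def make_gapped_pdb(n_res: int = 40, gap_start: int = 15, gap_len: int = 10,
                    seed: int = 0) -> tuple[str, MutantTruth]:
    """Structure with a long interior deletion (quality group III)."""
    return make_mutant_pdb(n_res=n_res, seed=seed, gaps=[(gap_start, gap_len)])


def make_dimer_ssbond_pdb(sg_distance: float = 4.0) -> str:
    """Two short chains whose cysteines form an inter-chain disulfide."""
    a = build_peptide("ACA", HELIX_PHI, HELIX_PSI, chain_id="A")
    b = build_peptide("ACA", HELIX_PHI, HELIX_PSI, chain_id="B")
    sg_a = a.chains["A"].residues[1].atom("SG").coord
    sg_b = b.chains["B"].residues[1].atom("SG").coord
    # move chain B so the two SG atoms sit at the requested separation
    direction = np.array([0.0, 0.0, 1.0])
    _rigid_transform(b, np.eye(3), sg_a + sg_distance * direction - sg_b)
    merged = StructureRecord("SSDIMER", resolution=2.0,
                             chains={"A": a.chains["A"], "B": b.chains["B"]})
    return write_pdb(merged)


# ---------------------------------------------------------------------------
# Toy metabolic models

_GPR_PATTERNS = ("single", "homomer", "complex", "isozyme_pair", "iso_complex")


def _pattern_complexes(pattern: str, genes: list[str]) -> list[dict[str, int]]:
    """Known complex list per GPR pattern -- the planted ground truth."""
    if pattern == "single":
        return [{genes[0]: 1}]
    if pattern == "homomer":
        return [{genes[0]: 2}]
    if pattern == "complex":
        return [{genes[0]: 1, genes[1]: 1}]
    if pattern == "isozyme_pair":
        return [{genes[0]: 1}, {genes[1]: 1}]
    if pattern == "iso_complex":
        return [{genes[0]: 1, genes[1]: 1}, {genes[2]: 1}]
    raise ValueError(pattern)


def _pattern_gpr(pattern: str, genes: list[str]) -> str:
    if pattern == "single":
        return genes[0]
    if pattern == "homomer":
        return f"{genes[0]} and {genes[0]}"
    if pattern == "complex":
        return f"({genes[0]} and {genes[1]})"
    if pattern == "isozyme_pair":
        return f"{genes[0]} or {genes[1]}"
    if pattern == "iso_complex":
        return f"({genes[0]} and {genes[1]}) or {genes[2]}"
    raise ValueError(pattern)


def make_toy_model(n_rxn: int = 10, seed: int = 0, uptake_ub: float = 10.0
                   ) -> tuple[MetabolicModel, dict]:
    """Viable linear-pathway model with GPRs of known boolean structure.

    Uptake -> chain of conversions -> biomass; each conversion reaction draws
    one GPR pattern (single gene, homodimer, two-subunit complex, isozyme
    pair, complex-plus-isozyme) over a shared gene pool, so isozyme reactions
    and multi-complex genes occur with known identity. The truth dict records
    the planted model statistics, computed from the pattern definitions alone
    (no GPR parsing involved).
    """
    if n_rxn < 3:
        raise ValueError("n_rxn >= 3 required")
    rng = np.random.default_rng(seed)
    n_conv = n_rxn - 2
    pool = [f"g{i:03d}" for i in range(max(3, int(np.ceil(n_conv * 1.2))))]
    reactions = [Reaction("R_UPTAKE", {"M000": 1.0}, 0.0, uptake_ub)]
    genes: set[str] = set()
    census: dict[tuple, dict[str, int]] = {}
    n_isozyme = 0
    for i in range(n_conv):
        pattern = _GPR_PATTERNS[rng.integers(0, len(_GPR_PATTERNS))]
        k_genes = {"single": 1, "homomer": 1, "complex": 2,
                   "isozyme_pair": 2, "iso_complex": 3}[pattern]
        chosen = [pool[j] for j in rng.choice(len(pool), size=k_genes, replace=False)]
        gpr = _pattern_gpr(pattern, chosen)
        complexes = _pattern_complexes(pattern, chosen)
        if len(complexes) >= 2:
            n_isozyme += 1
        for cdef in complexes:
            census.setdefault(tuple(sorted(cdef.items())), cdef)
        genes |= set(chosen)
        reactions.append(Reaction(
            f"R{i + 1:03d}", {f"M{i:03d}": -1.0, f"M{i + 1:03d}": 1.0},
            0.0, 1000.0, gpr, subsystem="pathway"))
    reactions.append(Reaction("R_BIOMASS", {f"M{n_conv:03d}": -1.0}, 0.0, 1000.0))
    metabolites = {f"M{i:03d}" for i in range(n_conv + 1)}
    model = MetabolicModel(f"toy_{seed}", genes, metabolites, reactions, "R_BIOMASS")
    gene_complexes: dict[str, int] = {}
    for cdef in census.values():
        for g in cdef:
            gene_complexes[g] = gene_complexes.get(g, 0) + 1
    multi = sorted(g for g, k in gene_complexes.items() if k >= 2)
    truth = {
        "isozyme_reaction_fraction": n_isozyme / n_conv,
        "multi_complex_gene_count": len(multi),
        "multi_complex_gene_fraction": len(multi) / len(genes) if genes else 0.0,
        "multi_complex_genes": multi,
        "n_complexes": len(census),
        "unconstrained_growth": uptake_ub,
    }
    return model, truth


def make_abundance_set(P, e_true, noise_sd: float = 0.0, seed: int = 0):
    """Measured abundances p = P e_true + |noise|, with the truth attached."""
    import pandas as pd

    e_true = np.asarray(e_true, dtype=float)
    if (e_true < 0).any():
        raise ValueError("e_true must be non-negative")
    rng = np.random.default_rng(seed)
    noise = np.abs(rng.normal(0.0, noise_sd, size=P.shape[0])) if noise_sd > 0 \
        else np.zeros(P.shape[0])
    p = np.asarray(P, dtype=float) @ e_true + noise
    index = P.index if hasattr(P, "index") else range(P.shape[0])
    return pd.Series(p, index=index, name="abundance"), {
        "e_true": e_true, "noise_total": float(noise.sum())}


def make_tm_table(genes, seed: int = 0, lo: float = 40.0, hi: float = 70.0):
    """Uniform random melting temperatures over [lo, hi] for the given genes."""
    from .thermal import PREDICTED, TmTable

    rng = np.random.default_rng(seed)
    genes = sorted(genes)
    values = rng.uniform(lo, hi, size=len(genes))
    return TmTable({g: round(float(t), 2) for g, t in zip(genes, values)},
                   {g: PREDICTED for g in genes})


def make_cluster_blobs(n_per: int = 50, k: int = 4, separation: float = 20.0,
                       seed: int = 0, n_features: int = len(FEATURE_NAMES)):
    """k unit-variance Gaussian blobs in feature space, centers ``separation`` apart.

    Columns carry the canonical 29 property names (truncated/padded if a
    different dimension is requested). Returns (DataFrame, labels Series).
    """
    import pandas as pd

    if k < 1:
        raise ValueError("k >= 1 required")
    rng = np.random.default_rng(seed)
    # centers at distance ~separation*sqrt(2) on random directions, so the
    # displacement spreads over all feature dimensions
    centers = rng.normal(size=(k, n_features))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= separation
    rows, labels = [], []
    for ci in range(k):
        rows.append(rng.normal(0.0, 1.0, size=(n_per, n_features)) + centers[ci])
        labels.extend([ci] * n_per)
    X = np.vstack(rows)
    names = (list(FEATURE_NAMES) + [f"f{i}" for i in range(n_features)])[:n_features]
    index = [f"p{i:04d}" for i in range(len(X))]
    return (pd.DataFrame(X, index=index, columns=names),
            pd.Series(labels, index=index, name="label"))


# ---------------------------------------------------------------------------
# Ligand sets

def _chain_graph(code: str, elements: list[str], orders: list[str] | None = None
                 ) -> LigandGraph:
    orders = orders or ["1"] * (len(elements) - 1)
    return LigandGraph(code, [LigandAtom(e) for e in elements],
                       [(i, i + 1, o) for i, o in enumerate(orders)])


def ligand_library() -> dict[str, LigandGraph]:
    """Small deterministic library of heavy-atom ligand graphs."""
    lib = {
        "MET": _chain_graph("MET", ["C"]),                      # methane
        "ETA": _chain_graph("ETA", ["C", "C"]),                 # ethane
        "EOH": _chain_graph("EOH", ["C", "C", "O"]),            # ethanol
        "DME": LigandGraph("DME", [LigandAtom("C"), LigandAtom("O"), LigandAtom("C")],
                           [(0, 1, "1"), (1, 2, "1")]),         # dimethyl ether
        "GOL": LigandGraph("GOL",
                           [LigandAtom("C"), LigandAtom("C"), LigandAtom("C"),
                            LigandAtom("O"), LigandAtom("O"), LigandAtom("O")],
                           [(0, 1, "1"), (1, 2, "1"), (0, 3, "1"),
                            (1, 4, "1"), (2, 5, "1")]),         # glycerol
        "PYR": LigandGraph("PYR",
                           [LigandAtom("C"), LigandAtom("C"), LigandAtom("C"),
                            LigandAtom("O"), LigandAtom("O"), LigandAtom("O")],
                           [(0, 1, "1"), (1, 2, "1"), (1, 3, "2"),
                            (2, 4, "2"), (2, 5, "1")]),         # pyruvate-like
        "BNZ": LigandGraph("BNZ", [LigandAtom("C") for _ in range(6)],
                           [(i, (i + 1) % 6, "ar") for i in range(6)]),  # benzene
        "ACA": _chain_graph("ACA", ["C", "C", "O"], ["1", "2"]),  # acetaldehyde-ish
        "SER": LigandGraph("SER",
                           [LigandAtom("N"), LigandAtom("C", chirality="S"),
                            LigandAtom("C"), LigandAtom("O"), LigandAtom("O"),
                            LigandAtom("C"), LigandAtom("O")],
                           [(0, 1, "1"), (1, 2, "1"), (2, 3, "2"),
                            (2, 4, "1"), (1, 5, "1"), (5, 6, "1")]),  # serine
        "HOH": LigandGraph("HOH", [LigandAtom("O")], []),
    }
    return lib


def permute_graph(g: LigandGraph, seed: int = 0) -> LigandGraph:
    """Same molecule, atoms relabeled by a seeded permutation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(g.atoms))
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(len(perm))
    atoms = [g.atoms[j] for j in perm]
    bonds = [(int(inverse[i]), int(inverse[j]), o) for i, j, o in g.bonds]
    return LigandGraph(g.code, atoms, bonds)


def make_ligand_set(seed: int = 0) -> tuple[dict[str, list[LigandGraph]], dict]:
    """Protein -> bound-ligand graphs, with planted distinct counts.

    One promiscuous protein binds 7 structurally distinct ligands (some as
    relabeled duplicates), one specialist binds a single ligand twice.
    """
    lib = ligand_library()
    promiscuous = [lib[c] for c in ("MET", "ETA", "EOH", "DME", "GOL", "PYR", "BNZ")]
    promiscuous += [permute_graph(lib["GOL"], seed + 1), permute_graph(lib["EOH"], seed + 2)]
    specialist = [lib["PYR"], permute_graph(lib["PYR"], seed + 3)]
    proteins = {"enzA": promiscuous, "enzB": specialist}
    truth = {"enzA": {"n_distinct": 7, "gt6_flag": True},
             "enzB": {"n_distinct": 1, "gt6_flag": False}}
    return proteins, truth


# ---------------------------------------------------------------------------
# CLI support: write a fixture bundle plus truth.json

def write_fixture(kind: str, out_dir: str, seed: int = 0) -> dict:
    """Materialize one fixture kind into a directory; returns the truth record."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"kind": kind, "seed": seed}
    kind = kind.upper()
    if kind == "HELIX_PDB":
        (out / "helix.pdb").write_text(make_helix_pdb())
        truth["helix_residues"] = list(range(3, 11))
    elif kind == "HAIRPIN_PDB":
        (out / "hairpin.pdb").write_text(make_hairpin_pdb())
    elif kind == "MUTANT_PDB":
        text, t = make_fig_style_two_mutation_pdb(seed)
        (out / "mutant.pdb").write_text(text)
        (out / "wt.fasta").write_text(f">wt\n{t.wt_sequence}\n")
        truth["mutations"] = t.mutations
    elif kind == "GAPPED_PDB":
        text, t = make_gapped_pdb(seed=seed)
        (out / "gapped.pdb").write_text(text)
        (out / "wt.fasta").write_text(f">wt\n{t.wt_sequence}\n")
        truth["gaps"] = t.gaps
    elif kind == "DIMER_SSBOND_PDB":
        (out / "dimer.pdb").write_text(make_dimer_ssbond_pdb())
        truth["n_ss_bonds"] = 1
    elif kind == "TOY_MODEL":
        model, t = make_toy_model(seed=seed)
        (out / "model.json").write_text(model_to_json(model))
        truth.update(t)
    elif kind == "TM_TABLE":
        model, _ = make_toy_model(seed=seed)
        tm = make_tm_table(model.genes, seed=seed)
        lines = ["gene_id\ttm_celsius\tsource"]
        lines += [f"{g}\t{t}\t{s}" for (g, t), s in
                  zip(sorted(tm.tm.items()), [tm.source[g] for g in sorted(tm.tm)])]
        (out / "tm.tsv").write_text("\n".join(lines) + "\n")
    elif kind == "LIGAND_SET":
        from .ligands import write_ligand_tsv

        proteins, t = make_ligand_set(seed)
        for name, graphs in proteins.items():
            (out / f"{name}.ligands.tsv").write_text(write_ligand_tsv(graphs))
        truth["proteins"] = t
    elif kind == "CLUSTER_BLOBS":
        X, labels = make_cluster_blobs(seed=seed)
        X.assign(label=labels).to_csv(out / "blobs.tsv", sep="\t")
        truth["k"] = 4
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return truth
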