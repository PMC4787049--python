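"""Revert mutated residues of a minimally modified structure to the wild type.

Three-stage repair of a group-II structure: (i) strip the mutated residue's
side chain down to the peptide backbone; (ii) graft an idealized wild-type
side chain by internal-coordinate construction; (iii) relieve steric clashes
with a steepest-descent minimization of a purely repulsive harmonic contact
potential. The potential is a deliberate simplification of a molecular-
mechanics force field: its only job is to push grafted atoms out of van der
Waals overlap, and it leaves every backbone atom untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import seq3
from scipy.spatial import cKDTree

from . import geometry
from .qc import AlignmentResult, align_structure_to_wt, classify_group
from .structures import Atom, StructureRecord
from .templates import BACKBONE_ATOMS, DEFAULT_VDW, SIDECHAIN_TEMPLATES, VDW_RADII


@dataclass
class MinimizerConfig:
    clash_scale: float = 0.8       # r0 = scale * (vdw_i + vdw_j)
    force_constant: float = 1.0    # energy units / A^2
    step: float = 0.01             # initial step, A
    max_iter: int = 5000
    grad_tol: float = 1e-4

    def __post_init__(self):
        if min(self.clash_scale, self.force_constant, self.step,
               self.max_iter, self.grad_tol) <= 0:
            raise ValueError("all minimizer parameters must be positive")


@dataclass
class RefinementReport:
    mutations_fixed: list[tuple[int, str, str]] = field(default_factory=list)
    initial_clashes: int = 0
    final_clashes: int = 0
    n_iterations: int = 0


def detect_mutations(aln: AlignmentResult) -> list[tuple[int, str, str]]:
    """Mismatched aligned positions, ordered by wild-type position."""
    return sorted(aln.mutations)


def strip_sidechain(struct: StructureRecord, chain_id: str, resnum: int) -> StructureRecord:
    """Remove all non-backbone atoms of one residue (returns a modified copy)."""
    out = struct.copy()
    res = out.chains[chain_id].residue(resnum)
    if res is None:
        raise KeyError(f"residue {resnum} not in chain {chain_id}")
    missing = BACKBONE_ATOMS - {a.name for a in res.atoms}
    if missing:
        raise ValueError(f"residue {resnum}: missing backbone atoms {sorted(missing)}")
    res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    return out


def graft_sidechain(struct: StructureRecord, chain_id: str, resnum: int,
                    target_aa: str) -> StructureRecord:
    """Build an idealized side chain for ``target_aa`` on a stripped residue.

    CB goes at 1.52 A from CA with a tetrahedral N-CA-CB angle; further atoms
    follow the internal-coordinate template with extended chi angles. The
    residue is renamed to the target amino acid.
    """
    target_aa = target_aa.upper()
    if target_aa not in SIDECHAIN_TEMPLATES:
        raise ValueError(f"unknown amino acid {target_aa!r}")
    out = struct.copy()
    res = out.chains[chain_id].residue(resnum)
    if res is None:
        raise KeyError(f"residue {resnum} not in chain {chain_id}")
    placed = {a.name: a.coord for a in res.atoms}
    for name in ("N", "CA", "C"):
        if name not in placed:
            raise ValueError(f"residue {resnum}: missing backbone atom {name}")
    new_atoms: list[Atom] = []
    if target_aa != "G":
        cb = geometry.place_cb(placed["N"], placed["CA"], placed["C"])
        placed["CB"] = cb
        new_atoms.append(Atom("CB", "C", cb))
    for name, element, (ra, rb, rc), bond, ang, dih in SIDECHAIN_TEMPLATES[target_aa]:
        coord = geometry.place_atom(placed[ra], placed[rb], placed[rc], bond, ang, dih)
        placed[name] = coord
        new_atoms.append(Atom(name, element, coord))
    res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS] + new_atoms
    res.name3 = seq3(target_aa).upper()
    return out


def _atom_table(struct: StructureRecord):
    """Flatten to (chain_id, resnum, atom) with a coordinate matrix."""
    entries = []
    coords = []
    for cid, res, atom in struct.iter_atoms():
        entries.append((cid, res.number, atom))
        coords.append(atom.coord)
    return entries, np.asarray(coords, dtype=float)


def _clash_pairs(entries, coords, scale: float):
    """Candidate pairs below their contact distance r0, with exclusions.

    Excluded: pairs within one residue, and backbone 1-2/1-3 pairs across the
    peptide bond between sequence-adjacent residues.
    """
    radii = np.array([VDW_RADII.get(e[2].element, DEFAULT_VDW) for e in entries])
    rmax = scale * 2 * radii.max()
    tree = cKDTree(coords)
    pairs = []
    for i, j in tree.query_pairs(rmax):
        ci, ri, ai = entries[i]
        cj, rj, aj = entries[j]
        if ci == cj and ri == rj:
            continue
        if ci == cj and abs(ri - rj) == 1:
            lo, hi = (i, j) if ri < rj else (j, i)
            la, ha = entries[lo][2].name, entries[hi][2].name
            # peptide-bond 1-2 and 1-3 neighborhoods
            if (la, ha) in {("C", "N"), ("CA", "N"), ("O", "N"), ("C", "CA")}:
                continue
        r0 = scale * (radii[i] + radii[j])
        if np.linalg.norm(coords[i] - coords[j]) < r0:
            pairs.append((i, j, r0))
    return pairs


def count_clashes(struct: StructureRecord, scale: float = 0.8) -> int:
    entries, coords = _atom_table(struct)
    if len(entries) < 2:
        return 0
    return len(_clash_pairs(entries, coords, scale))


def minimize_steric(struct: StructureRecord, movable: set[tuple[str, int, str]],
                    cfg: MinimizerConfig | None = None) -> tuple[StructureRecord, dict]:
    """Steepest-descent relief of steric clashes.

    Energy E = sum over clashing pairs (r < r0) of k (r0 - r)^2 with
    r0 = scale * (vdw_i + vdw_j). Only atoms in ``movable`` (keys
    (chain, resnum, atom name)) are displaced; a backtracking line search
    makes the energy non-increasing at every iteration.
    """
    cfg = cfg or MinimizerConfig()
    if not movable:
        raise ValueError("movable atom set is empty")
    out = struct.copy()
    entries, coords = _atom_table(out)
    idx_movable = np.array([k for k, (cid, rn, atom) in enumerate(entries)
                            if (cid, rn, atom.name) in movable], dtype=int)

    def energy_grad(x):
        pairs = _clash_pairs(entries, x, cfg.clash_scale)
        e = 0.0
        g = np.zeros_like(x)
        for i, j, r0 in pairs:
            d = x[i] - x[j]
            r = np.linalg.norm(d)
            if r < 1e-9:
                continue
            e += cfg.force_constant * (r0 - r) ** 2
            f = -2.0 * cfg.force_constant * (r0 - r) / r * d
            g[i] += f
            g[j] -= f
        return e, g, len(pairs)

    e, g, _ = energy_grad(coords)
    if not np.isfinite(e):
        raise ValueError("non-finite clash energy")
    history = [e]
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        gm = np.zeros_like(g)
        gm[idx_movable] = g[idx_movable]
        gnorm = np.linalg.norm(gm)
        if gnorm < cfg.grad_tol:
            break
        direction = -gm / gnorm
        alpha = cfg.step
        improved = False
        for _ in range(40):
            trial = coords + alpha * direction
            e_t, g_t, _ = energy_grad(trial)
            if e_t <= e:
                coords, e, g = trial, e_t, g_t
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    for k, (cid, rn, atom) in enumerate(entries):
        atom.coord = coords[k]
    history.append(e)
    info = {"energy_initial": history[0], "energy_final": e, "iterations": n_iter,
            "clashes": energy_grad(coords)[2]}
    return out, info


def revert_to_wildtype(struct: StructureRecord, wt_seq: str, chain_id: str | None = None,
                       cfg: MinimizerConfig | None = None,
                       ) -> tuple[StructureRecord, RefinementReport]:
    """Full repair: detect mutations, strip, graft, minimize grafted atoms.

    Refuses structures that do not classify as group I/II against the given
    wild-type sequence (group III belongs in homology modeling). Group I input
    is a no-op with an empty report.
    """
    cfg = cfg or MinimizerConfig()
    if chain_id is None:
        chain_id = next(iter(struct.chains))
    chain = struct.chains[chain_id]
    aln = align_structure_to_wt(wt_seq, chain.observed_sequence)
    group = classify_group(aln, struct)
    if group == "III":
        raise ValueError(
            "structure is group III (large gaps or long mutation runs); "
            "route to homology modeling instead of sequence refinement")
    mutations = detect_mutations(aln)
    report = RefinementReport(mutations_fixed=mutations)
    if not mutations:
        return struct.copy(), report

    pos_to_resnum = dict((wt, chain.residues[st - 1].number) for wt, st in aln.aligned_pairs)
    out = struct.copy()
    movable: set[tuple[str, int, str]] = set()
    for wt_pos, wt_aa, _obs in mutations:
        resnum = pos_to_resnum[wt_pos]
        out = strip_sidechain(out, chain_id, resnum)
        out = graft_sidechain(out, chain_id, resnum, wt_aa)
        res = out.chains[chain_id].residue(resnum)
        movable |= {(chain_id, resnum, a.name) for a in res.atoms
                    if a.name not in BACKBONE_ATOMS}
    report.initial_clashes = count_clashes(out, cfg.clash_scale)
    if movable:
        out, info = minimize_steric(out, movable, cfg)
        report.n_iterations = info["iterations"]
    report.final_clashes = count_clashes(out, cfg.clash_scale)
    for wt_pos, wt_aa, obs in mutations:
        out.remarks.append(
            f"REMARK  99 REVERTED {obs}{pos_to_resnum[wt_pos]}{wt_aa}")
    if out.chains[chain_id].seqres is not None:
        out.chains[chain_id].seqres = None  # sequence now read from rebuilt residues
    return out, report
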