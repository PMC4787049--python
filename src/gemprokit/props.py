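"""Per-protein structural property profile.

The profile is a 29-feature vector per protein: total and per-residue
solvent-accessible surface area (SASA), contact and disulfide counts,
surface/buried split, 8-class secondary-structure composition, ovality
(SASA / N_res^(2/3)), mean residue depth, and residue chemical-class
percentages over all, surface and buried residues.

SASA follows the probe-sphere (rolling ball) definition with a deterministic
golden-spiral point lattice on each atom sphere; secondary structure follows
the Kabsch-Sander hydrogen-bond energy criterion with DSSP-style turn,
bridge and bend patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import ChainRecord, StructureRecord
from .templates import DEFAULT_VDW, VDW_RADII

PROBE_RADIUS = 1.4  # A
SASA_POINTS = 960
SURFACE_SASA_THRESHOLD = 3.0  # A^2, strictly greater than -> surface
SS_BOND_CUTOFF = 5.0  # A, SG-SG
CONTACT_CUTOFF = 4.5  # A, heavy-atom pairs
CONTACT_MIN_SEPARATION = 3  # residues

NONPOLAR = "NONPOLAR"
POLAR = "POLAR"
POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"

RESIDUE_CLASSES = {
    **{aa: NONPOLAR for aa in "AVLIMFWPG"},
    **{aa: POLAR for aa in "STNQYC"},
    **{aa: POSITIVE for aa in "KRH"},
    **{aa: NEGATIVE for aa in "DE"},
}

FEATURE_NAMES = (
    "sasa_total", "mean_residue_sasa", "n_res", "n_contacts", "n_ss_bonds",
    "pct_buried", "pct_surface",
    "pct_helix_H", "pct_strand_E", "pct_310_G", "pct_pi_I", "pct_turn_T",
    "pct_bend_S", "pct_bridge_B", "pct_disordered",
    "ovality", "mean_residue_depth",
    "pct_nonpolar", "pct_polar", "pct_positive", "pct_negative",
    "pct_surface_nonpolar", "pct_surface_polar", "pct_surface_positive",
    "pct_surface_negative",
    "pct_buried_nonpolar", "pct_buried_polar", "pct_buried_positive",
    "pct_buried_negative",
)


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere lattice (Fibonacci spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _heavy_atoms(chain: ChainRecord):
    entries, coords, radii = [], [], []
    for ridx, res in enumerate(chain.residues):
        for atom in res.atoms:
            if atom.element == "H":
                continue
            entries.append((ridx, atom))
            coords.append(atom.coord)
            radii.append(VDW_RADII.get(atom.element, DEFAULT_VDW))
    return entries, np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


@dataclass
class SasaResult:
    per_atom: np.ndarray             # A^2, aligned with heavy-atom order
    per_residue: np.ndarray          # A^2, per chain residue
    surface_points: np.ndarray       # exposed sample points, (m, 3)
    total: float


def compute_sasa(chain: ChainRecord, probe: float = PROBE_RADIUS,
                 n_points: int = SASA_POINTS) -> SasaResult:
    """Probe-accessible surface area via a fixed point lattice per atom.

    A lattice point on the expanded sphere (r_vdw + probe) counts as exposed
    when it lies outside every neighboring atom's expanded sphere; the atom's
    SASA is the exposed fraction of its sphere area. Exposed points are kept
    for the residue-depth calculation.
    """
    if n_points < 60:
        raise ValueError("n_points < 60 gives unusably coarse SASA")
    entries, coords, radii = _heavy_atoms(chain)
    if len(entries) == 0:
        raise ValueError("chain has no heavy atoms")
    sphere = _golden_spiral(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    per_atom = np.zeros(len(entries))
    exposed_points = []
    rmax = expanded.max()
    for i in range(len(entries)):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + rmax)
                     if j != i]
        mask = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            mask &= d2 > expanded[j] ** 2
        frac = mask.sum() / n_points
        per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
        if mask.any():
            exposed_points.append(pts[mask])
    per_residue = np.zeros(len(chain.residues))
    for (ridx, _), a in zip(entries, per_atom):
        per_residue[ridx] += a
    surface = np.vstack(exposed_points) if exposed_points else np.empty((0, 3))
    return SasaResult(per_atom, per_residue, surface, float(per_atom.sum()))


def assign_surface_buried(per_residue_sasa: np.ndarray,
                          threshold: float = SURFACE_SASA_THRESHOLD) -> list[str]:
    """SURFACE iff residue SASA strictly exceeds the threshold (3 A^2)."""
    return ["SURFACE" if s > threshold else "BURIED" for s in per_residue_sasa]


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander)

_KS_Q = 27.888  # kcal/mol * A; 332 * 0.42 * 0.20
_KS_CUTOFF = -0.5


def _backbone(chain: ChainRecord):
    """Backbone coordinate arrays and an amide-H reconstruction.

    H_i sits 1.0 A from N_i along the C(i-1)=O(i-1) bond direction, the DSSP
    convention; residues without a sequence-contiguous predecessor (chain
    start, gap) have no amide H and cannot donate.
    """
    n = len(chain.residues)
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    for i, res in enumerate(chain.residues):
        for name, arr in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            a = res.atom(name)
            if a is not None:
                arr[i] = a.coord
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        contiguous = chain.residues[i].number == chain.residues[i - 1].number + 1
        if contiguous and np.isfinite(C[i - 1]).all() and np.isfinite(O[i - 1]).all() \
                and np.isfinite(N[i]).all():
            d = C[i - 1] - O[i - 1]
            H[i] = N[i] + d / np.linalg.norm(d)
    return N, CA, C, O, H


def _hbond_matrix(chain: ChainRecord) -> np.ndarray:
    """hb[i, j] true when CO(i) accepts an H-bond from NH(j) (E < -0.5)."""
    n = len(chain.residues)
    N, CA, C, O, H = _backbone(chain)
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if not (np.isfinite(C[i]).all() and np.isfinite(O[i]).all()):
            continue
        for j in range(n):
            if abs(i - j) < 2:  # no bond with self or direct neighbor
                continue
            if not (np.isfinite(N[j]).all() and np.isfinite(H[j]).all()):
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                e = -9.9
            else:
                e = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _KS_CUTOFF:
                hb[i, j] = True
    return hb


def assign_secondary_structure(chain: ChainRecord) -> list[str]:
    """Kabsch-Sander 8-class assignment: H, G, I, E, B, T, S or '-'.

    Helix classes require two consecutive n-turns (CO(k) to NH(k+n)); a
    residue is labeled when it is interior to both turns of such a pair.
    Bridges follow the parallel/antiparallel hydrogen-bond patterns; ladders
    of consecutive bridges are extended strand E, isolated bridges B. A
    hydrogen-bonded turn marks interior residues T, and a CA-trace kink above
    70 degrees marks a bend S. Priority: H > E > B > G > I > T > S.
    """
    n = len(chain.residues)
    if n < 3:
        return ["-"] * n
    hb = _hbond_matrix(chain)
    _, CA, _, _, _ = _backbone(chain)

    def turn(k, length):
        return k + length < n and hb[k, k + length]

    helix_sets = {"H": set(), "G": set(), "I": set()}
    for code, length in (("G", 3), ("H", 4), ("I", 5)):
        for k in range(n):
            if turn(k, length) and turn(k + 1, length):
                interior1 = set(range(k + 1, k + length))
                interior2 = set(range(k + 2, k + 1 + length))
                helix_sets[code] |= interior1 & interior2

    # Bridges (Kabsch-Sander patterns), |i - j| >= 3
    bridge = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                bridge[i, j] = bridge[j, i] = True
    bridged = {i for i in range(n) if bridge[i].any()}
    strand = set()
    for i in range(n):
        for j in range(n):
            if not bridge[i, j]:
                continue
            # ladder: an adjacent residue pair also bridges
            for di in (-1, 1):
                for dj in (-1, 1):
                    if 0 <= i + di < n and 0 <= j + dj < n and bridge[i + di, j + dj]:
                        strand.add(i)
    isolated = bridged - strand

    turn_set = set()
    for code, length in (("G", 3), ("H", 4), ("I", 5)):
        for k in range(n):
            if turn(k, length):
                turn_set |= set(range(k + 1, k + length))

    bend = set()
    for i in range(2, n - 2):
        if np.isfinite(CA[[i - 2, i, i + 2]]).all():
            u = CA[i] - CA[i - 2]
            v = CA[i + 2] - CA[i]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
                bend.add(i)

    out = []
    for i in range(n):
        if i in helix_sets["H"]:
            out.append("H")
        elif i in strand:
            out.append("E")
        elif i in isolated:
            out.append("B")
        elif i in helix_sets["G"]:
            out.append("G")
        elif i in helix_sets["I"]:
            out.append("I")
        elif i in turn_set:
            out.append("T")
        elif i in bend:
            out.append("S")
        else:
            out.append("-")
    return out


def ss_composition(ss: list[str]) -> dict[str, float]:
    """Fractional 8-class composition (sums to 1 for non-empty input)."""
    n = max(len(ss), 1)
    return {c: ss.count(c) / n for c in ("H", "G", "I", "E", "B", "T", "S", "-")}


def count_ss_bonds(chain: ChainRecord, cutoff: float = SS_BOND_CUTOFF) -> int:
    """Disulfide bonds: SG-SG pairs within the cutoff, greedily paired nearest-first."""
    sg = [(res.number, atom.coord) for res in chain.residues for atom in res.atoms
          if atom.name == "SG"]
    pairs = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            d = float(np.linalg.norm(sg[i][1] - sg[j][1]))
            if d <= cutoff:
                pairs.append((d, i, j))
    pairs.sort()
    used: set[int] = set()
    count = 0
    for _, i, j in pairs:
        if i not in used and j not in used:
            used |= {i, j}
            count += 1
    return count


def count_contacts(chain: ChainRecord, cutoff: float = CONTACT_CUTOFF,
                   min_separation: int = CONTACT_MIN_SEPARATION) -> int:
    """Heavy-atom pairs within the cutoff between sequence-distant residues."""
    entries, coords, _ = _heavy_atoms(chain)
    if len(entries) < 2:
        return 0
    tree = cKDTree(coords)
    count = 0
    for i, j in tree.query_pairs(cutoff):
        ri, rj = entries[i][0], entries[j][0]
        if abs(chain.residues[ri].number - chain.residues[rj].number) >= min_separation:
            count += 1
    return count


def compute_residue_depth(chain: ChainRecord, sasa: SasaResult) -> np.ndarray:
    """Mean distance of each residue's heavy atoms to the accessible surface."""
    entries, coords, _ = _heavy_atoms(chain)
    if sasa.surface_points.shape[0] == 0:
        return np.full(len(chain.residues), np.nan)
    tree = cKDTree(sasa.surface_points)
    dmin, _ = tree.query(coords)
    depth = np.zeros(len(chain.residues))
    counts = np.zeros(len(chain.residues))
    for (ridx, _), d in zip(entries, dmin):
        depth[ridx] += d
        counts[ridx] += 1
    with np.errstate(invalid="ignore"):
        return depth / counts


def _class_percentages(residues, mask=None) -> dict[str, float]:
    classes = [RESIDUE_CLASSES.get(r.aa) for r in residues]
    if mask is not None:
        classes = [c for c, m in zip(classes, mask) if m]
    classes = [c for c in classes if c is not None]
    n = len(classes)
    out = {}
    for cls, suffix in ((NONPOLAR, "nonpolar"), (POLAR, "polar"),
                        (POSITIVE, "positive"), (NEGATIVE, "negative")):
        out[suffix] = 100.0 * classes.count(cls) / n if n else 0.0
    return out


def property_vector(chain: ChainRecord, probe: float = PROBE_RADIUS,
                    n_points: int = SASA_POINTS) -> dict[str, float]:
    """Assemble the full 29-feature profile of one protein chain."""
    n_res = len(chain.residues)
    if n_res == 0:
        raise ValueError("empty chain")
    sasa = compute_sasa(chain, probe, n_points)
    ss = assign_secondary_structure(chain)
    comp = ss_composition(ss)
    loc = assign_surface_buried(sasa.per_residue)
    surface_mask = [x == "SURFACE" for x in loc]
    buried_mask = [x == "BURIED" for x in loc]
    depth = compute_residue_depth(chain, sasa)
    vec = {
        "sasa_total": sasa.total,
        "mean_residue_sasa": sasa.total / n_res,
        "n_res": float(n_res),
        "n_contacts": float(count_contacts(chain)),
        "n_ss_bonds": float(count_ss_bonds(chain)),
        "pct_buried": 100.0 * sum(buried_mask) / n_res,
        "pct_surface": 100.0 * sum(surface_mask) / n_res,
        "pct_helix_H": 100.0 * comp["H"],
        "pct_strand_E": 100.0 * comp["E"],
        "pct_310_G": 100.0 * comp["G"],
        "pct_pi_I": 100.0 * comp["I"],
        "pct_turn_T": 100.0 * comp["T"],
        "pct_bend_S": 100.0 * comp["S"],
        "pct_bridge_B": 100.0 * comp["B"],
        "pct_disordered": 100.0 * comp["-"],
        "ovality": sasa.total / n_res ** (2.0 / 3.0),
        "mean_residue_depth": float(np.nanmean(depth)),
    }
    for suffix, val in _class_percentages(chain.residues).items():
        vec[f"pct_{suffix}"] = val
    for suffix, val in _class_percentages(chain.residues, surface_mask).items():
        vec[f"pct_surface_{suffix}"] = val
    for suffix, val in _class_percentages(chain.residues, buried_mask).items():
        vec[f"pct_buried_{suffix}"] = val
    assert set(vec) == set(FEATURE_NAMES)
    return {name: vec[name] for name in FEATURE_NAMES}


def property_table(structures: dict[str, StructureRecord], **kwargs):
    """One property-vector row per gene, as a DataFrame indexed by gene id."""
    import pandas as pd

    rows = {}
    for gene, struct in sorted(structures.items()):
        rows[gene] = property_vector(struct.first_chain(), **kwargs)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "gene"
    return df
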