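"""Parsed protein structures: records, PDB reading and writing.

The in-memory model is deliberately small: chains of residues of heavy atoms
with coordinates, plus the metadata the QC stage ranks on (experimental
method, crystallographic resolution, and a model-accuracy score for homology
models, carried in a ``REMARK  99 TMSCORE`` line).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.SeqUtils import seq1, seq3

XRAY = "XRAY"
NMR = "NMR"
MODEL = "MODEL"


class PdbParseError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy())


@dataclass
class Residue:
    number: int
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa(self) -> str:
        """One-letter code; 'X' for non-standard residues."""
        one = seq1(self.name3.capitalize())
        return one if one != "" else "X"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.number, self.name3, [a.copy() for a in self.atoms])


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    seqres: str | None = None

    @property
    def reported_sequence(self) -> str:
        """SEQRES sequence when present, else the sequence of resolved residues."""
        if self.seqres:
            return self.seqres
        return "".join(r.aa for r in self.residues)

    @property
    def observed_sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue(self, number: int) -> Residue | None:
        for r in self.residues:
            if r.number == number:
                return r
        return None

    def copy(self) -> "ChainRecord":
        return ChainRecord(self.chain_id, [r.copy() for r in self.residues], self.seqres)


@dataclass
class StructureRecord:
    structure_id: str
    method: str = XRAY
    resolution: float | None = None
    tm_score: float | None = None
    chains: dict[str, ChainRecord] = field(default_factory=dict)
    remarks: list[str] = field(default_factory=list)

    def first_chain(self) -> ChainRecord:
        return next(iter(self.chains.values()))

    def copy(self) -> "StructureRecord":
        return replace(self, chains={k: c.copy() for k, c in self.chains.items()},
                       remarks=list(self.remarks))

    def iter_atoms(self):
        """Yield (chain_id, residue, atom) over all chains in order."""
        for cid, chain in self.chains.items():
            for res in chain.residues:
                for atom in res.atoms:
                    yield cid, res, atom


def _scan_header(text: str):
    """Pull resolution, experimental method and TM-score out of header lines."""
    resolution = None
    method = None
    tm_score = None
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "REMARK" and line[7:10].strip() == "2" and "RESOLUTION." in line:
            tail = line.split("RESOLUTION.", 1)[1]
            tok = tail.replace("ANGSTROMS.", "").replace("ANGSTROMS", "").strip()
            if tok and "NOT APPLICABLE" not in tail:
                try:
                    resolution = float(tok.split()[0])
                except ValueError:
                    pass
        elif rec == "EXPDTA":
            body = line[6:].upper()
            if "NMR" in body:
                method = NMR
            elif "X-RAY" in body:
                method = XRAY
            elif "THEORETICAL" in body or "MODEL" in body:
                method = MODEL
        elif rec == "REMARK" and "TMSCORE" in line:
            try:
                tm_score = float(line.split("TMSCORE", 1)[1].strip())
            except ValueError:
                pass
    return resolution, method, tm_score


def _scan_seqres(text: str) -> dict[str, str]:
    """SEQRES sequences per chain, as one-letter strings."""
    seqs: dict[str, list[str]] = {}
    for line in text.splitlines():
        if line.startswith("SEQRES"):
            chain_id = line[11].strip() or "A"
            for tok in line[19:].split():
                one = seq1(tok.capitalize())
                seqs.setdefault(chain_id, []).append(one if one else "X")
    return {c: "".join(v) for c, v in seqs.items()}


def parse_pdb(text: str, structure_id: str = "struct") -> StructureRecord:
    """Parse PDB-format text into a StructureRecord.

    Coordinates are parsed with Biopython's PDBParser; resolution is read from
    the ``REMARK   2 RESOLUTION.`` line, the method from ``EXPDTA`` (absent
    resolution implies NMR unless stated), and homology models may carry a
    ``REMARK  99 TMSCORE`` accuracy annotation.
    """
    if not any(line.startswith(("ATOM  ", "ATOM ")) for line in text.splitlines()):
        raise PdbParseError(f"{structure_id}: no ATOM records")
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith("ATOM"):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise PdbParseError(
                    f"{structure_id}: malformed coordinate field at line {i}: {line!r}")
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(structure_id, io.StringIO(text))
    except PDBConstructionException as exc:  # pragma: no cover - permissive parser
        raise PdbParseError(f"{structure_id}: {exc}") from exc

    resolution, method, tm_score = _scan_header(text)
    if method is None:
        method = MODEL if tm_score is not None else (XRAY if resolution is not None else NMR)
    seqres = _scan_seqres(text)

    chains: dict[str, ChainRecord] = {}
    bio_model = next(iter(bio))
    for bio_chain in bio_model:
        residues = []
        for bio_res in bio_chain:
            if bio_res.id[0].strip():  # skip HETATM/water residues
                continue
            atoms = [Atom(a.get_name(), (a.element or a.get_name()[0]).upper(),
                          np.asarray(a.get_coord(), dtype=float))
                     for a in bio_res]
            residues.append(Residue(bio_res.id[1], bio_res.get_resname(), atoms))
        residues.sort(key=lambda r: r.number)
        cid = bio_chain.id.strip() or "A"
        chains[cid] = ChainRecord(cid, residues, seqres.get(cid))
    if not chains:
        raise PdbParseError(f"{structure_id}: no protein chains")
    return StructureRecord(structure_id, method, resolution, tm_score, chains)


def write_pdb(struct: StructureRecord) -> str:
    """Serialize a StructureRecord back to PDB text (ATOM records, header remarks)."""
    lines: list[str] = []
    if struct.method == NMR:
        lines.append("EXPDTA    SOLUTION NMR")
    elif struct.method == MODEL:
        lines.append("EXPDTA    THEORETICAL MODEL")
    else:
        lines.append("EXPDTA    X-RAY DIFFRACTION")
    if struct.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {struct.resolution:.2f} ANGSTROMS.")
    if struct.tm_score is not None:
        lines.append(f"REMARK  99 TMSCORE {struct.tm_score:.3f}")
    lines.extend(struct.remarks)
    for cid, chain in struct.chains.items():
        if chain.seqres:
            codes = [seq3(a).upper() if a != "X" else "UNK" for a in chain.seqres]
            nres = len(codes)
            for i in range(0, nres, 13):
                row = " ".join(codes[i:i + 13])
                lines.append(f"SEQRES {i // 13 + 1:>3} {cid} {nres:>4}  {row}")
    serial = 1
    for cid, chain in struct.chains.items():
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:>5} {name}{'':1}{res.name3:<3} {cid}{res.number:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2}")
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
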