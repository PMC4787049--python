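"""Structure-to-gene mapping QC: alignment metrics, quality scores, ranking.

Each candidate structure of a gene is aligned to the gene's wild-type
sequence; sequence identity, completeness (fraction of wild-type positions
resolved in the structure, regardless of exact match), mutations and interior
gaps feed a combined quality score in (0, 1] and a three-way quality group:

* group I   - no mutations, no interior gaps: usable as-is;
* group II  - minimally modified (short mutation runs, small interior gaps):
  repairable by the refinement stage;
* group III - anything worse: route to homology modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .structures import MODEL, NMR, XRAY, ChainRecord, StructureRecord

SS_CLASSES = ("H", "G", "I", "E", "B", "T", "S", "-")


@dataclass
class AlignmentResult:
    wt_length: int
    aligned_pairs: list[tuple[int, int]]  # (wt pos 1-based, struct pos 1-based)
    identity_fraction: float
    completeness_fraction: float
    mutations: list[tuple[int, str, str]]  # (wt pos, wt aa, observed aa)
    interior_gaps: list[tuple[int, int]]  # (start wt pos, length)
    terminal_gap_lengths: tuple[int, int] = (0, 0)


@dataclass
class QualityScore:
    s_si: float
    s_res: float
    combined: float
    group: str
    s_comp: float | None = None
    completeness: float = 0.0


@dataclass
class QcConfig:
    """Tunable QC thresholds; defaults are the package's documented choices."""

    weights: tuple[float, float, float] = (0.5, 0.3, 0.2)  # identity/completeness/resolution
    max_resolution: float = 3.0
    max_mutation_run: int = 2
    max_total_mutations: int = 5
    max_interior_gap: int = 3
    max_total_interior_gap: int = 5
    nmr_s_res: float = 0.7


DEFAULT_CONFIG = QcConfig()


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_internal_gap_score = -2.0
    aligner.extend_internal_gap_score = -0.5
    # Terminal overhangs are unpenalized: an unresolved tail is not an
    # alignment error, it just lowers completeness.
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def align_structure_to_wt(wt_seq: str, struct_seq: str) -> AlignmentResult:
    """Global alignment of a structure-resolved sequence to the wild type.

    identity = exact matches / wild-type length; completeness = resolved
    (aligned) wild-type positions / wild-type length, disregarding whether
    the residue matches.
    """
    if not wt_seq or not struct_seq:
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    aln = aligner.align(wt_seq, struct_seq)[0]
    pairs: list[tuple[int, int]] = []
    mutations: list[tuple[int, str, str]] = []
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(int(t1) - int(t0)):
            wt_pos, st_pos = int(t0) + k + 1, int(q0) + k + 1
            pairs.append((wt_pos, st_pos))
            if wt_seq[wt_pos - 1] != struct_seq[st_pos - 1]:
                mutations.append((wt_pos, wt_seq[wt_pos - 1], struct_seq[st_pos - 1]))
    n = len(wt_seq)
    aligned_wt = [p for p, _ in pairs]
    matches = len(pairs) - len(mutations)
    if aligned_wt:
        first, last = aligned_wt[0], aligned_wt[-1]
        covered = set(aligned_wt)
        interior = []
        gap_start = None
        for pos in range(first, last + 1):
            if pos not in covered:
                if gap_start is None:
                    gap_start = pos
            elif gap_start is not None:
                interior.append((gap_start, pos - gap_start))
                gap_start = None
        terminal = (int(first) - 1, n - int(last))
    else:  # pragma: no cover - global alignment always aligns something
        interior, terminal = [], (n, 0)
    return AlignmentResult(
        wt_length=n,
        aligned_pairs=pairs,
        identity_fraction=matches / n,
        completeness_fraction=len(pairs) / n,
        mutations=mutations,
        interior_gaps=interior,
        terminal_gap_lengths=terminal,
    )


def resolution_score(struct: StructureRecord, cfg: QcConfig = DEFAULT_CONFIG) -> float:
    """Map resolution to [0, 1]: 1.0 A -> 1, linearly down to 0 at 5.0 A; NMR 0.7."""
    if struct.method == NMR or struct.resolution is None:
        return cfg.nmr_s_res
    return max(0.0, min(1.0, 1.0 - (struct.resolution - 1.0) / 4.0))


def ss_composition_distance(f_model: dict[str, float], f_ref: dict[str, float]) -> float:
    """Half L1 distance between two secondary-structure class compositions."""
    return 0.5 * sum(abs(f_model.get(c, 0.0) - f_ref.get(c, 0.0)) for c in SS_CLASSES)


def score_structure(
    aln: AlignmentResult,
    struct: StructureRecord,
    ss_ref: dict[str, float] | None = None,
    ss_model: dict[str, float] | None = None,
    cfg: QcConfig = DEFAULT_CONFIG,
) -> QualityScore:
    """Combined quality score in (0, 1].

    Experimental structures: weighted sum of sequence identity, completeness
    and resolution score. Homology models: mean of the model's TM-score and a
    secondary-structure composition agreement term s_comp (1 when the model's
    8-class composition matches the reference's).
    """
    s_si = aln.identity_fraction
    s_res = resolution_score(struct, cfg)
    group = classify_group(aln, struct, cfg)
    if struct.method == MODEL:
        if struct.tm_score is None:
            raise ValueError(f"{struct.structure_id}: homology model without TM-score")
        if ss_ref is not None and ss_model is not None:
            s_comp = 1.0 - ss_composition_distance(ss_model, ss_ref)
        else:
            s_comp = 1.0
        combined = 0.5 * struct.tm_score + 0.5 * s_comp
    else:
        s_comp = None
        w_si, w_comp, w_res = cfg.weights
        combined = w_si * s_si + w_comp * aln.completeness_fraction + w_res * s_res
    combined = min(1.0, max(0.01, combined))
    return QualityScore(s_si=s_si, s_res=s_res, combined=combined, group=group,
                        s_comp=s_comp, completeness=aln.completeness_fraction)


def _mutation_runs(mutations: list[tuple[int, str, str]]) -> list[int]:
    runs = []
    prev = None
    for pos, _, _ in mutations:
        if prev is not None and pos == prev + 1:
            runs[-1] += 1
        else:
            runs.append(1)
        prev = pos
    return runs


def classify_group(aln: AlignmentResult, struct: StructureRecord,
                   cfg: QcConfig = DEFAULT_CONFIG) -> str:
    """Quality group I/II/III. Terminal gaps are deliberately ignored here."""
    res_ok = struct.method != XRAY or struct.resolution is None \
        or struct.resolution <= cfg.max_resolution
    if not aln.mutations and not aln.interior_gaps and res_ok:
        return "I"
    runs = _mutation_runs(aln.mutations)
    gap_lengths = [length for _, length in aln.interior_gaps]
    if (res_ok
            and all(r <= cfg.max_mutation_run for r in runs)
            and len(aln.mutations) <= cfg.max_total_mutations
            and all(g <= cfg.max_interior_gap for g in gap_lengths)
            and sum(gap_lengths) <= cfg.max_total_interior_gap):
        return "II"
    return "III"


def rank_structures(
    gene: str,
    candidates: list[tuple[StructureRecord, QualityScore]],
) -> tuple[list[tuple[StructureRecord, QualityScore]], tuple[StructureRecord, QualityScore]]:
    """Sort candidates best-first and pick the representative structure.

    Order: combined score desc; experimental before homology models at equal
    score; then higher identity, lower resolution, lexicographic id.
    """
    if not candidates:
        raise ValueError(f"{gene}: no candidate structures")

    def key(item):
        struct, score = item
        res = struct.resolution if struct.resolution is not None else float("inf")
        return (-score.combined, 1 if struct.method == MODEL else 0,
                -score.s_si, res, struct.structure_id)

    ordered = sorted(candidates, key=key)
    return ordered, ordered[0]


def best_chain(struct: StructureRecord, wt_seq: str) -> tuple[str, AlignmentResult]:
    """Chain with highest identity to the gene's sequence (multi-chain PDBs)."""
    best: tuple[str, AlignmentResult] | None = None
    for cid, chain in struct.chains.items():
        if not chain.observed_sequence:
            continue
        aln = align_structure_to_wt(wt_seq, chain.observed_sequence)
        if best is None or aln.identity_fraction > best[1].identity_fraction:
            best = (cid, aln)
    if best is None:
        raise ValueError(f"{struct.structure_id}: no chain with residues")
    return best


def rank_report(
    sequences: dict[str, str],
    structures: dict[str, list[StructureRecord]],
    cfg: QcConfig = DEFAULT_CONFIG,
):
    """Per-gene ranking table over candidate structures.

    ``structures`` maps gene id -> candidate StructureRecords. Returns a
    pandas DataFrame with one row per (gene, structure), best first, and a
    representative flag.
    """
    import pandas as pd

    rows = []
    for gene in sorted(structures):
        wt = sequences[gene]
        cands = []
        for struct in structures[gene]:
            _, aln = best_chain(struct, wt)
            cands.append((struct, score_structure(aln, struct, cfg=cfg)))
        ordered, rep = rank_structures(gene, cands)
        for struct, score in ordered:
            rows.append({
                "gene": gene,
                "structure_id": struct.structure_id,
                "method": struct.method,
                "resolution": struct.resolution,
                "s_si": score.s_si,
                "completeness": score.completeness,
                "combined": score.combined,
                "group": score.group,
                "representative": struct.structure_id == rep[0].structure_id,
            })
    return pd.DataFrame(rows)
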