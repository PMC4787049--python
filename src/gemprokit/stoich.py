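"""Protein complex stoichiometry: enzyme abundance prediction by LP.

The protein stoichiometric matrix P has one row per peptide (gene) and one
column per enzyme complex; entry (i, j) is the copy number of peptide i in
complex j. Given measured peptide abundances p, feasible enzyme abundances e
and free (uncomplexed) peptide f satisfy P e + f = p with e, f >= 0. The
point solution minimizes total free peptide; flux variability analysis at
that optimum brackets each enzyme abundance between its minimum and maximum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import ComplexDefinition

FVA_REL_TOL = 1e-6
FVA_ABS_TOL = 1e-9


@dataclass
class AbundanceSolution:
    measured: pd.Series                 # protein -> abundance
    enzyme: pd.Series                   # enzyme -> point estimate
    free: pd.Series                     # protein -> free peptide
    f_total_min: float
    fva: pd.DataFrame | None = None     # enzyme x (min, max)


def build_matrix(complexes: list[ComplexDefinition]) -> pd.DataFrame:
    """Proteins x enzymes integer matrix from deduplicated complex definitions."""
    if not complexes:
        raise ValueError("no complexes")
    enzymes = sorted({c.enzyme_id or c.canonical_id() for c in complexes})
    if len(enzymes) != len(complexes):
        raise ValueError("duplicate enzyme ids in complex list")
    proteins = sorted({g for c in complexes for g in c.subunits})
    P = pd.DataFrame(0, index=proteins, columns=enzymes, dtype=int)
    for c in complexes:
        eid = c.enzyme_id or c.canonical_id()
        for gene, copies in c.subunits.items():
            P.loc[gene, eid] = int(copies)
    P.index.name = "protein"
    P.columns.name = "enzyme"
    return P


def fit_abundances(P: pd.DataFrame, p: pd.Series) -> AbundanceSolution:
    """LP: minimize total free peptide subject to P e + f = p, e, f >= 0.

    Always feasible (e = 0, f = p). The optimal total free peptide is unique;
    the returned (e, f) is one optimal vertex.
    """
    p = p.reindex(P.index)
    if p.isna().any():
        missing = list(p.index[p.isna()])
        raise ValueError(f"missing abundances for proteins {missing}")
    if (p < 0).any():
        raise ValueError("negative abundance")
    n_prot, n_enz = P.shape
    A = np.asarray(P, dtype=float)
    c = np.concatenate([np.zeros(n_enz), np.ones(n_prot)])
    A_eq = np.hstack([A, np.eye(n_prot)])
    res = linprog(c, A_eq=A_eq, b_eq=p.to_numpy(dtype=float),
                  bounds=[(0, None)] * (n_enz + n_prot), method="highs")
    if not res.success:  # pragma: no cover - problem is always feasible
        raise RuntimeError(f"LP failed: {res.message}")
    x = np.maximum(res.x, 0.0)  # scrub LP round-off signed zeros
    e = pd.Series(x[:n_enz], index=P.columns, name="enzyme_abundance")
    f = pd.Series(x[n_enz:], index=P.index, name="free_peptide")
    return AbundanceSolution(measured=p, enzyme=e, free=f, f_total_min=float(res.fun))


def fva_enzymes(P: pd.DataFrame, p: pd.Series, f_total_min: float,
                rel_tol: float = FVA_REL_TOL, abs_tol: float = FVA_ABS_TOL) -> pd.DataFrame:
    """Per-enzyme abundance range with total free peptide held at its minimum.

    The free-peptide optimum is fixed up to a small slack (relative + absolute)
    because exact equality is numerically brittle in LP solvers.
    """
    p = p.reindex(P.index).to_numpy(dtype=float)
    n_prot, n_enz = P.shape
    A = np.asarray(P, dtype=float)
    A_eq = np.hstack([A, np.eye(n_prot)])
    A_ub = np.concatenate([np.zeros(n_enz), np.ones(n_prot)])[None, :]
    b_ub = [f_total_min * (1.0 + rel_tol) + abs_tol]
    bounds = [(0, None)] * (n_enz + n_prot)
    rows = []
    for j in range(n_enz):
        c = np.zeros(n_enz + n_prot)
        c[j] = 1.0
        lo = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=p,
                     bounds=bounds, method="highs")
        hi = linprog(-c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=p,
                     bounds=bounds, method="highs")
        if not (lo.success and hi.success):  # pragma: no cover
            raise RuntimeError("FVA subproblem failed")
        rows.append((lo.fun, -hi.fun))
    return pd.DataFrame(rows, index=P.columns, columns=["min", "max"])


def solve(P: pd.DataFrame, p: pd.Series) -> AbundanceSolution:
    """Point fit plus FVA ranges in one call."""
    sol = fit_abundances(P, p)
    sol.fva = fva_enzymes(P, p, sol.f_total_min)
    return sol


def stoich_stats(complexes: list[ComplexDefinition],
                 solution: AbundanceSolution | None = None) -> dict:
    """Homomer census and (optionally) the free-abundance ranking.

    A homomer has a single distinct subunit gene; even stoichiometry means an
    even copy number. Multi-complex genes occur in >= 2 complexes.
    """
    n = len(complexes)
    homomers = [c for c in complexes if len(c.subunits) == 1]
    even = [c for c in homomers if next(iter(c.subunits.values())) % 2 == 0]
    gene_count: dict[str, int] = {}
    for c in complexes:
        for g in c.subunits:
            gene_count[g] = gene_count.get(g, 0) + 1
    multi = sorted(g for g, k in gene_count.items() if k >= 2)
    out = {
        "homomer_fraction": len(homomers) / n if n else 0.0,
        "even_fraction_among_homomers": len(even) / len(homomers) if homomers else 0.0,
        "multi_complex_genes": multi,
        "multi_complex_gene_count": len(multi),
    }
    if solution is not None:
        out["free_abundance_ranking"] = list(
            solution.free.sort_values(ascending=False).index)
    return out


def solution_to_tsv(sol: AbundanceSolution) -> str:
    """Two-section TSV: per-protein measured/free, per-enzyme point/min/max."""
    buf = io.StringIO()
    prot = pd.DataFrame({"measured": sol.measured, "free": sol.free})
    prot.index.name = "gene"
    buf.write(prot.to_csv(sep="\t"))
    buf.write("#\n")
    enz = pd.DataFrame({"point": sol.enzyme})
    if sol.fva is not None:
        enz["min"] = sol.fva["min"]
        enz["max"] = sol.fva["max"]
    enz.index.name = "enzyme"
    buf.write(enz.to_csv(sep="\t"))
    return buf.getvalue()
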