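"""Temperature-constrained growth prediction.

Each gene carries a melting temperature T_M; at simulation temperature T a
gene is functional iff T <= T_M (binary stability, boundary inclusive).
A reaction stays enabled when its GPR still evaluates true over the
functional genes (isozymes can rescue); disabled reactions get zero flux
bounds, and flux balance analysis (FBA) then gives the growth rate at each
temperature. Because the disabled set grows with temperature, the curve is
monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import MetabolicModel, parse_gpr

EXPERIMENTAL, PREDICTED, MISSING = "EXPERIMENTAL", "PREDICTED", "MISSING"


@dataclass
class TmTable:
    tm: dict[str, float]                       # gene -> melting temperature, Celsius
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for g, t in self.tm.items():
            if not np.isfinite(t):
                raise ValueError(f"{g}: non-finite T_M")

    @classmethod
    def from_tsv(cls, path: str) -> "TmTable":
        df = pd.read_csv(path, sep="\t")
        return cls({r.gene_id: float(r.tm_celsius) for r in df.itertuples(index=False)},
                   {r.gene_id: getattr(r, "source", PREDICTED)
                    for r in df.itertuples(index=False)})


class FbaError(RuntimeError):
    pass


def fba(model: MetabolicModel,
        bounds_overrides: dict[str, tuple[float, float]] | None = None
        ) -> tuple[float, pd.Series]:
    """Flux balance analysis: maximize the objective flux under S v = 0.

    Returns (objective value, one optimal flux vector). Raises FbaError
    distinguishing infeasible from unbounded problems.
    """
    overrides = bounds_overrides or {}
    mets = sorted(model.metabolites)
    met_idx = {m: i for i, m in enumerate(mets)}
    rxns = model.reactions
    S = np.zeros((len(mets), len(rxns)))
    bounds = []
    for j, rxn in enumerate(rxns):
        for met, coef in rxn.stoichiometry.items():
            S[met_idx[met], j] = coef
        lb, ub = overrides.get(rxn.id, (rxn.lower_bound, rxn.upper_bound))
        bounds.append((lb, ub))
    c = np.zeros(len(rxns))
    c[[j for j, r in enumerate(rxns) if r.id == model.objective_reaction][0]] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
    if res.status == 3:
        raise FbaError("FBA problem is unbounded")
    if res.status == 2 or not res.success:
        raise FbaError(f"FBA problem is infeasible: {res.message}")
    flux = pd.Series(res.x, index=[r.id for r in rxns])
    return float(-res.fun), flux


def apply_tm_constraints(model: MetabolicModel, tm: TmTable, temperature: float,
                         strict: bool = False
                         ) -> tuple[dict[str, tuple[float, float]], list[str]]:
    """Zero the bounds of reactions whose GPR fails at the given temperature.

    A gene is functional iff T <= T_M(gene); genes without T_M data default to
    functional (``strict=True`` flips that default). Reactions without a GPR
    are never disabled.
    """
    default = not strict

    def functional(gene: str) -> bool:
        t_m = tm.tm.get(gene)
        if t_m is None:
            return default
        return temperature <= t_m

    overrides: dict[str, tuple[float, float]] = {}
    disabled: list[str] = []
    for rxn in model.reactions:
        if not rxn.gpr.strip():
            continue
        ast = parse_gpr(rxn.gpr)
        if not ast.evaluate({g: functional(g) for g in ast.genes()}):
            overrides[rxn.id] = (0.0, 0.0)
            disabled.append(rxn.id)
    return overrides, disabled


@dataclass
class GrowthCurve:
    temperatures: np.ndarray
    growth: np.ndarray
    disabled: list[list[str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.temperatures,
            "growth": self.growth,
            "n_disabled": [len(d) for d in self.disabled],
            "disabled_ids": [";".join(d) for d in self.disabled],
        })


def growth_curve(model: MetabolicModel, tm: TmTable, grid,
                 strict: bool = False) -> GrowthCurve:
    """FBA growth rate over a strictly increasing temperature grid."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty temperature grid")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    growth, disabled = [], []
    for t in grid:
        overrides, dis = apply_tm_constraints(model, tm, t, strict)
        g, _ = fba(model, overrides)
        growth.append(max(g, 0.0))
        disabled.append(dis)
    growth_arr = np.asarray(growth)
    # nested constraint sets: warmer never grows faster (up to LP tolerance)
    assert np.all(np.diff(growth_arr) <= 1e-7), "growth curve not monotone"
    return GrowthCurve(grid, growth_arr, disabled)
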