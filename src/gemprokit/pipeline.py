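"""Master per-gene table assembly and the end-to-end pipeline driver.

The master table is the central per-gene data frame: one row per model gene
joining sequence length, the representative structure and its QC metrics,
the structural property profile, complex memberships and melting
temperature. Stages that were not run leave their columns null.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time

import pandas as pd

from .model_io import MetabolicModel, reaction_complexes
from .thermal import TmTable

logger = logging.getLogger("gemprokit")


def assemble_master_table(
    model: MetabolicModel,
    sequences: dict[str, str] | None = None,
    ranking: pd.DataFrame | None = None,
    props: pd.DataFrame | None = None,
    tm: TmTable | None = None,
) -> pd.DataFrame:
    """Left-join all per-gene evidence onto the model's gene list."""
    genes = sorted(model.genes)
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    if sequences is not None:
        table["seq_length"] = pd.Series({g: len(s) for g, s in sequences.items()})
    if ranking is not None:
        if ranking["gene"].duplicated().any():
            reps = ranking[ranking["representative"]]
        else:
            reps = ranking
        if reps["gene"].duplicated().any():
            raise ValueError("duplicate gene in ranking input")
        reps = reps.set_index("gene")
        for col in ("structure_id", "method", "resolution", "s_si",
                    "completeness", "combined", "group"):
            table[col] = reps[col]
        table["n_candidate_structures"] = ranking.groupby("gene").size()
    if props is not None:
        if props.index.duplicated().any():
            raise ValueError("duplicate gene in property table")
        table = table.join(props, how="left")
    memberships: dict[str, list[str]] = {g: [] for g in genes}
    for rid, complexes in reaction_complexes(model).items():
        for c in complexes:
            for g in c.subunits:
                if g in memberships:
                    memberships[g].append(c.canonical_id())
    table["complexes"] = pd.Series(
        {g: ";".join(sorted(set(v))) for g, v in memberships.items()})
    if tm is not None:
        table["tm_celsius"] = pd.Series(tm.tm)
    return table


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str) -> pathlib.Path:
    """Run enabled stages in order and write outputs plus a MANIFEST.

    Config keys: ``model`` (path, required), ``sequences`` (FASTA path),
    ``pdb_dir``, ``tm_table``, ``seed``, and per-stage enable flags
    ``compare``/``stoich``/``tm_growth`` with their inputs. Partial outputs
    are kept on failure; the MANIFEST lists what completed.
    """
    from . import model_io, props as props_mod, qc
    from .structures import parse_pdb

    known = {"model", "sequences", "pdb_dir", "tm_table", "seed",
             "tm_grid", "abundances", "compare", "stoich", "tm_growth"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    def record(name: str, path: pathlib.Path, t0: float):
        manifest[name] = {"path": path.name, "sha256": _sha256(path),
                          "seconds": round(time.time() - t0, 3)}
        logger.info("stage %s -> %s", name, path.name)

    model = model_io.read_model(config["model"])
    sequences = model_io.read_fasta(config["sequences"]) if config.get("sequences") else None
    ranking = None
    if config.get("pdb_dir") and sequences:
        t0 = time.time()
        structures: dict[str, list] = {}
        for pdb_path in sorted(pathlib.Path(config["pdb_dir"]).glob("*.pdb")):
            gene = pdb_path.stem.split("__")[0]
            if gene in sequences:
                structures.setdefault(gene, []).append(
                    parse_pdb(pdb_path.read_text(), pdb_path.stem))
        if structures:
            ranking = qc.rank_report(sequences, structures)
            path = out / "ranking.tsv"
            ranking.to_csv(path, sep="\t", index=False)
            record("map_qc", path, t0)
    props_df = None
    if config.get("pdb_dir") and ranking is not None:
        t0 = time.time()
        reps = {}
        for row in ranking[ranking["representative"]].itertuples(index=False):
            pdb_path = pathlib.Path(config["pdb_dir"]) / f"{row.structure_id}.pdb"
            if pdb_path.exists():
                reps[row.gene] = parse_pdb(pdb_path.read_text(), row.structure_id)
        if reps:
            props_df = props_mod.property_table(reps)
            path = out / "props.tsv"
            props_df.to_csv(path, sep="\t")
            record("props", path, t0)
    tm = TmTable.from_tsv(config["tm_table"]) if config.get("tm_table") else None
    if tm is not None and config.get("tm_growth"):
        from .thermal import growth_curve

        t0 = time.time()
        grid = config.get("tm_grid", list(range(20, 81, 5)))
        curve = growth_curve(model, tm, grid)
        path = out / "growth_curve.tsv"
        curve.to_frame().to_csv(path, sep="\t", index=False)
        record("tm_growth", path, t0)
    if config.get("abundances") and config.get("stoich"):
        from .model_io import expand_complexes, parse_gpr
        from .stoich import build_matrix, solution_to_tsv, solve

        t0 = time.time()
        census = {}
        for rxn in model.reactions:
            if rxn.gpr.strip():
                for c in expand_complexes(parse_gpr(rxn.gpr)):
                    census[c.key()] = c
        P = build_matrix(list(census.values()))
        ab = pd.read_csv(config["abundances"], sep="\t", index_col=0).iloc[:, 0]
        sol = solve(P, ab)
        path = out / "stoich_solution.tsv"
        path.write_text(solution_to_tsv(sol))
        record("stoich", path, t0)
    t0 = time.time()
    master = assemble_master_table(model, sequences, ranking, props_df, tm)
    path = out / "master_table.tsv"
    master.to_csv(path, sep="\t")
    record("master_table", path, t0)
    manifest_path = out / "MANIFEST.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
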