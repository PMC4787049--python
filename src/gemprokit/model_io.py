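"""Metabolic model I/O and gene-protein-reaction (GPR) rule handling.

A GPR is a boolean statement over gene locus ids: AND joins subunits of one
enzyme complex, OR joins isozymes (alternative complexes catalyzing the same
reaction). Expanding a GPR to disjunctive normal form therefore yields the
candidate enzyme complexes of the reaction, with subunit copy numbers given
by gene multiplicity within a conjunction (curated stoichiometry tables can
override the default of one copy).
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

GENE, AND, OR = "GENE", "AND", "OR"

_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z0-9_.\-]+")


class GprParseError(ValueError):
    pass


@dataclass(frozen=True)
class GprAst:
    kind: str
    children: tuple["GprAst", ...] = ()
    gene: str | None = None

    def genes(self) -> set[str]:
        if self.kind == GENE:
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, available: set[str] | dict[str, bool]) -> bool:
        """Truth value of the rule under a gene-availability assignment."""
        if self.kind == GENE:
            if isinstance(available, dict):
                return bool(available.get(self.gene, False))
            return self.gene in available
        if self.kind == AND:
            return all(c.evaluate(available) for c in self.children)
        return any(c.evaluate(available) for c in self.children)


@dataclass
class ComplexDefinition:
    """One enzyme complex: subunit gene -> copy number (>= 1)."""

    enzyme_id: str
    subunits: dict[str, int]

    def key(self) -> tuple[tuple[str, int], ...]:
        """Identity of the complex: the multiset of (gene, copies)."""
        return tuple(sorted(self.subunits.items()))

    def canonical_id(self) -> str:
        return "_".join(f"{g}x{n}" for g, n in self.key())


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"{self.id}: lower_bound > upper_bound")


@dataclass
class MetabolicModel:
    model_id: str
    genes: set[str]
    metabolites: set[str]
    reactions: list[Reaction]
    objective_reaction: str

    def __post_init__(self):
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reaction ids")
        if self.objective_reaction not in set(ids):
            raise ValueError(f"objective reaction {self.objective_reaction!r} not in model")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


def tokenize_gpr(text: str) -> list[str]:
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if text[pos:m.start()].strip():
            raise GprParseError(f"unknown token {text[pos:m.start()].strip()!r} in GPR")
        tokens.append(m.group())
        pos = m.end()
    if text[pos:].strip():
        raise GprParseError(f"unknown token {text[pos:].strip()!r} in GPR")
    return tokens


def parse_gpr(text: str) -> GprAst:
    """Parse a GPR rule ('and'/'or', case-insensitive, parentheses) into an AST."""
    tokens = tokenize_gpr(text)
    if not tokens:
        raise GprParseError("empty GPR")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect(tok):
        nonlocal pos
        if peek() != tok:
            raise GprParseError(f"expected {tok!r}, found {peek()!r}")
        pos += 1

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprAst(OR, tuple(terms))

    def parse_and():
        nonlocal pos
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else GprAst(AND, tuple(factors))

    def parse_factor():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of GPR")
        if tok == "(":
            pos += 1
            node = parse_or()
            expect(")")
            return node
        if tok == ")":
            raise GprParseError("unbalanced parentheses")
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"misplaced operator {tok!r}")
        pos += 1
        return GprAst(GENE, gene=tok)

    ast = parse_or()
    if pos != len(tokens):
        raise GprParseError("unbalanced parentheses" if peek() == ")" else
                            f"trailing tokens {tokens[pos:]!r}")
    return ast


def expand_complexes(ast: GprAst) -> list[ComplexDefinition]:
    """Expand a GPR AST to disjunctive normal form: one complex per conjunction.

    Copy number of a subunit equals the gene's multiplicity in the conjunction;
    duplicate complexes (same subunit multiset) are merged; output is sorted by
    the canonical subunit string, so the expansion is deterministic.
    """

    def dnf(node: GprAst) -> list[Counter]:
        if node.kind == GENE:
            return [Counter({node.gene: 1})]
        if node.kind == OR:
            out: list[Counter] = []
            for c in node.children:
                out.extend(dnf(c))
            return out
        # AND: cross product, multiplicities add
        terms = [dnf(c) for c in node.children]
        out = [Counter()]
        for alts in terms:
            out = [prev + alt for prev in out for alt in alts]
        return out

    seen: dict[tuple, Counter] = {}
    for conj in dnf(ast):
        key = tuple(sorted(conj.items()))
        seen.setdefault(key, conj)
    complexes = [ComplexDefinition("", dict(sorted(c.items()))) for c in seen.values()]
    complexes.sort(key=lambda c: c.canonical_id())
    for c in complexes:
        c.enzyme_id = c.canonical_id()
    return complexes


def apply_stoichiometry_table(
    complexes: list[ComplexDefinition],
    table: dict[str, dict[str, int]],
) -> list[ComplexDefinition]:
    """Override default copy numbers with curated complex stoichiometry.

    Table entries are matched to complexes by subunit gene set; entries whose
    gene set matches no complex are skipped with a warning.
    """
    by_geneset = {frozenset(c.subunits): c for c in complexes}
    out = [ComplexDefinition(c.enzyme_id, dict(c.subunits)) for c in complexes]
    out_by_geneset = {frozenset(c.subunits): c for c in out}
    for enzyme_id, subunits in table.items():
        target = out_by_geneset.get(frozenset(subunits))
        if target is None:
            warnings.warn(f"stoichiometry entry {enzyme_id!r} matches no complex; skipped")
            continue
        target.subunits = dict(sorted(subunits.items()))
        target.enzyme_id = enzyme_id
    del by_geneset
    return out


def reaction_complexes(model: MetabolicModel) -> dict[str, list[ComplexDefinition]]:
    """DNF complexes per reaction with a non-empty GPR."""
    out: dict[str, list[ComplexDefinition]] = {}
    for rxn in model.reactions:
        if rxn.gpr.strip():
            out[rxn.id] = expand_complexes(parse_gpr(rxn.gpr))
    return out


def model_stats(model: MetabolicModel) -> dict:
    """Isozyme-reaction fraction and multi-complex gene census of a model.

    An isozyme reaction expands to >= 2 complexes; a multi-complex gene occurs
    in >= 2 distinct complexes, complexes deduplicated globally by (gene,
    copies) multiset. Gene fractions use all model genes as denominator,
    reaction fractions the reactions with non-empty GPRs.
    """
    per_rxn = reaction_complexes(model)
    n_gpr_rxns = len(per_rxn)
    n_isozyme = sum(1 for cs in per_rxn.values() if len(cs) >= 2)
    census: dict[tuple, ComplexDefinition] = {}
    for cs in per_rxn.values():
        for c in cs:
            census.setdefault(c.key(), c)
    gene_complex_count = Counter()
    for c in census.values():
        for g in c.subunits:
            gene_complex_count[g] += 1
    multi = sorted(g for g, n in gene_complex_count.items() if n >= 2)
    n_genes = len(model.genes)
    return {
        "isozyme_reaction_fraction": (n_isozyme / n_gpr_rxns) if n_gpr_rxns else 0.0,
        "multi_complex_gene_count": len(multi),
        "multi_complex_gene_fraction": (len(multi) / n_genes) if n_genes else 0.0,
        "multi_complex_genes": multi,
        "n_complexes": len(census),
    }


# ---------------------------------------------------------------------------
# I/O

def model_to_json(model: MetabolicModel) -> str:
    doc = {
        "id": model.model_id,
        "genes": sorted(model.genes),
        "metabolites": sorted(model.metabolites),
        "reactions": [
            {"id": r.id, "stoich": r.stoichiometry, "lb": r.lower_bound,
             "ub": r.upper_bound, "gpr": r.gpr, "subsystem": r.subsystem}
            for r in model.reactions
        ],
        "objective": model.objective_reaction,
    }
    return json.dumps(doc, indent=1, sort_keys=False)


def model_from_json(text: str) -> MetabolicModel:
    doc = json.loads(text)
    reactions = [
        Reaction(r["id"], {k: float(v) for k, v in r["stoich"].items()},
                 float(r.get("lb", -1000.0)), float(r.get("ub", 1000.0)),
                 r.get("gpr", ""), r.get("subsystem", ""))
        for r in doc["reactions"]
    ]
    model = MetabolicModel(doc["id"], set(doc["genes"]), set(doc["metabolites"]),
                           reactions, doc["objective"])
    _check_gpr_genes(model)
    return model


def _check_gpr_genes(model: MetabolicModel) -> None:
    for rxn in model.reactions:
        if rxn.gpr.strip():
            missing = parse_gpr(rxn.gpr).genes() - model.genes
            if missing:
                raise ValueError(f"{rxn.id}: GPR references unknown genes {sorted(missing)}")


def read_model(path: str) -> MetabolicModel:
    """Read a model from the canonical JSON dialect or from SBML Level 3 (fbc)."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith("{"):
        return model_from_json(text)
    return read_sbml(path)


def read_sbml(path: str) -> MetabolicModel:
    """Read the fbc gene-association subset of SBML Level 3 via cobrapy."""
    import cobra.io

    cm = cobra.io.read_sbml_model(path)
    objective = None
    for rxn in cm.reactions:
        if rxn.objective_coefficient:
            objective = rxn.id
            break
    if objective is None:
        raise ValueError("SBML model has no objective reaction")
    reactions = [
        Reaction(r.id, {m.id: coef for m, coef in r.metabolites.items()},
                 r.lower_bound, r.upper_bound, r.gene_reaction_rule or "",
                 getattr(r, "subsystem", "") or "")
        for r in cm.reactions
    ]
    return MetabolicModel(cm.id or "model", {g.id for g in cm.genes},
                          {m.id for m in cm.metabolites}, reactions, objective)


def read_fasta(path: str) -> dict[str, str]:
    """Gene id -> amino-acid sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_stoichiometry_table(path: str) -> dict[str, dict[str, int]]:
    """TSV with columns enzyme_id, gene_id, copies -> nested mapping."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"enzyme_id": str, "gene_id": str})
    table: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(row.enzyme_id, {})[row.gene_id] = int(row.copies)
    return table
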