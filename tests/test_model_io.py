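"""GPR parsing, DNF expansion and model statistics."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemprokit.model_io import (ComplexDefinition, GprParseError, MetabolicModel,
                                Reaction, apply_stoichiometry_table,
                                expand_complexes, model_from_json, model_stats,
                                model_to_json, parse_gpr)


def brute_force_truth_table(gpr_text, genes):
    """Independent oracle: evaluate the GPR string with Python's eval."""
    expr = gpr_text.replace("(", " ( ").replace(")", " ) ")
    results = {}
    for assignment in itertools.product([False, True], repeat=len(genes)):
        env = dict(zip(genes, assignment))
        tokens = [("env['%s']" % t if t not in ("(", ")", "and", "or", "AND", "OR")
                   else t.lower()) for t in expr.split()]
        results[assignment] = eval(" ".join(tokens), {"env": env})
    return results


def dnf_truth_table(complexes, genes):
    """Evaluate the DNF complex list: true iff some complex is fully available."""
    results = {}
    for assignment in itertools.product([False, True], repeat=len(genes)):
        env = dict(zip(genes, assignment))
        results[assignment] = any(all(env[g] for g in c.subunits) for c in complexes)
    return results


class TestParseGpr:
    def test_or_of_and(self):
        ast = parse_gpr("(b0001 and b0002) or b0003")
        assert ast.kind == "OR"
        kinds = sorted(c.kind for c in ast.children)
        assert kinds == ["AND", "GENE"]

    def test_single_gene_leaf(self):
        ast = parse_gpr("b0001")
        assert ast.kind == "GENE" and ast.gene == "b0001"

    @pytest.mark.parametrize("text", [
        "(a or b) and c",
        "a and (b or c) and d",
        "((a or b) and (c or d)) or e",
        "a AND b OR c",
    ])
    def test_truth_table_equivalence(self, text):
        ast = parse_gpr(text)
        genes = sorted(ast.genes())
        oracle = brute_force_truth_table(text, genes)
        for assignment, expected in oracle.items():
            assert ast.evaluate(dict(zip(genes, assignment))) == expected

    @pytest.mark.parametrize("bad", ["(a and b", "a b", "a and or b", "", "a )"])
    def test_parse_errors(self, bad):
        with pytest.raises(GprParseError):
            parse_gpr(bad)


class TestExpandComplexes:
    def test_isozyme_complex(self):
        complexes = expand_complexes(parse_gpr("(g1 and g2) or g3"))
        assert [c.subunits for c in complexes] == [{"g1": 1, "g2": 1}, {"g3": 1}]

    def test_distribution_over_or(self):
        complexes = expand_complexes(parse_gpr("a and (b or c)"))
        assert [c.subunits for c in complexes] == [{"a": 1, "b": 1}, {"a": 1, "c": 1}]

    def test_single_gene(self):
        assert [c.subunits for c in expand_complexes(parse_gpr("g1"))] == [{"g1": 1}]

    def test_homomer_multiplicity(self):
        assert expand_complexes(parse_gpr("g1 and g1"))[0].subunits == {"g1": 2}

    @given(st.integers(0, 9999))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dnf_equivalent_to_source(self, seed):
        """DNF expansion matches the source GPR on every truth assignment."""
        import numpy as np

        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(rng.integers(2, 7))]

        def random_expr(depth):
            if depth == 0 or rng.random() < 0.4:
                return pool[rng.integers(0, len(pool))]
            op = " and " if rng.random() < 0.5 else " or "
            return "(" + op.join(random_expr(depth - 1)
                                 for _ in range(rng.integers(2, 4))) + ")"

        text = random_expr(3)
        ast = parse_gpr(text)
        genes = sorted(ast.genes())
        assert dnf_truth_table(expand_complexes(ast), genes) == \
            brute_force_truth_table(text, genes)

    def test_idempotent_on_dnf(self):
        text = "(g1 and g2) or g3 or (g4 and g4)"
        once = expand_complexes(parse_gpr(text))
        rebuilt = " or ".join(
            "(" + " and ".join(itertools.chain.from_iterable(
                [g] * k for g, k in c.subunits.items())) + ")"
            for c in once)
        assert [c.subunits for c in expand_complexes(parse_gpr(rebuilt))] == \
            [c.subunits for c in once]


class TestStoichiometryTable:
    def test_curated_override(self):
        complexes = expand_complexes(parse_gpr("atpB"))
        out = apply_stoichiometry_table(complexes, {"ATPSYN": {"atpB": 3}})
        assert out[0].subunits == {"atpB": 3} and out[0].enzyme_id == "ATPSYN"

    def test_empty_table_is_identity(self):
        complexes = expand_complexes(parse_gpr("(a and b) or c"))
        out = apply_stoichiometry_table(complexes, {})
        assert [c.subunits for c in out] == [c.subunits for c in complexes]

    def test_unmatched_entry_warns_and_skips(self):
        complexes = expand_complexes(parse_gpr("a"))
        with pytest.warns(UserWarning, match="matches no complex"):
            out = apply_stoichiometry_table(complexes, {"X": {"zz": 2}})
        assert [c.subunits for c in out] == [{"a": 1}]


def _model(reactions, genes):
    mets = {m for r in reactions for m in r.stoichiometry}
    return MetabolicModel("m", set(genes), mets, reactions, reactions[-1].id)


class TestModelStats:
    def test_hand_enumerated_toy(self):
        rxns = [
            Reaction("R1", {"A": -1, "B": 1}, 0, 10, gpr="(a and b) or c"),
            Reaction("R2", {"B": -1, "C": 1}, 0, 10, gpr="a"),
        ]
        stats = model_stats(_model(rxns, ["a", "b", "c"]))
        assert stats["isozyme_reaction_fraction"] == 0.5
        assert stats["multi_complex_gene_count"] == 1
        assert stats["multi_complex_genes"] == ["a"]

    def test_no_gprs(self):
        rxns = [Reaction("R1", {"A": -1, "B": 1}, 0, 10)]
        stats = model_stats(_model(rxns, []))
        assert stats["isozyme_reaction_fraction"] == 0.0
        assert stats["multi_complex_gene_count"] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_planted_truth(self, seed):
        from gemprokit.fixtures import make_toy_model

        model, truth = make_toy_model(n_rxn=20, seed=seed)
        stats = model_stats(model)
        assert stats["isozyme_reaction_fraction"] == pytest.approx(
            truth["isozyme_reaction_fraction"])
        assert stats["multi_complex_gene_count"] == truth["multi_complex_gene_count"]
        assert sorted(stats["multi_complex_genes"]) == truth["multi_complex_genes"]
        assert stats["n_complexes"] == truth["n_complexes"]

    def test_invariant_to_reaction_order_and_whitespace(self, toy_model):
        model, _ = toy_model
        ref = model_stats(model)
        shuffled = MetabolicModel(model.model_id, model.genes, model.metabolites,
                                  list(reversed(model.reactions)),
                                  model.objective_reaction)
        for rxn in shuffled.reactions:
            rxn.gpr = rxn.gpr.replace(" and ", "  and  ").replace("(", "( ")
        assert model_stats(shuffled) == ref


class TestModelJson:
    def test_round_trip(self, toy_model):
        model, _ = toy_model
        restored = model_from_json(model_to_json(model))
        assert restored.genes == model.genes
        assert restored.objective_reaction == model.objective_reaction
        assert [r.id for r in restored.reactions] == [r.id for r in model.reactions]
        assert model_to_json(restored) == model_to_json(model)

    def test_gpr_with_unknown_gene_rejected(self):
        doc = ('{"id":"m","genes":["a"],"metabolites":["A"],'
               '"reactions":[{"id":"R1","stoich":{"A":1},"lb":0,"ub":10,'
               '"gpr":"a and zz","subsystem":""}],"objective":"R1"}')
        with pytest.raises(ValueError, match="unknown genes"):
            model_from_json(doc)


def test_read_sbml_via_cobra(tmp_path):
    """SBML written by cobrapy round-trips into the package model."""
    import cobra

    m = cobra.Model("toy")
    a = cobra.Metabolite("A", compartment="c")
    b = cobra.Metabolite("B", compartment="c")
    up = cobra.Reaction("UP")
    up.add_metabolites({a: 1})
    up.bounds = (0, 10)
    conv = cobra.Reaction("CONV")
    conv.add_metabolites({a: -1, b: 1})
    conv.bounds = (0, 1000)
    conv.gene_reaction_rule = "(g1 and g2) or g3"
    bio = cobra.Reaction("BIO")
    bio.add_metabolites({b: -1})
    bio.bounds = (0, 1000)
    m.add_reactions([up, conv, bio])
    m.objective = "BIO"
    path = tmp_path / "toy.xml"
    cobra.io.write_sbml_model(m, str(path))

    from gemprokit.model_io import read_model

    mm = read_model(str(path))
    assert mm.genes == {"g1", "g2", "g3"}
    assert mm.objective_reaction == "BIO"
    assert mm.reaction("CONV").gpr == "(g1 and g2) or g3"
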