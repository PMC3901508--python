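"""Classification, completeness checking, sequencing, dependency graphs."""

import pytest

from mmlsim import mml, plan


class TestClassification:
    def test_reaction_chain_plan(self, box1_plan):
        p = box1_plan
        assert p.time_domain == "t" and p.space_domain is None
        assert p.ode_vars == ["H", "U", "X"]
        assert sorted(p.ics) == ["H", "U", "X"]
        # parameters first, then the simultaneous dynamic block
        assert p.order[:7] == sorted(pp.name for pp in p.model.params)
        assert p.order[7:] == ["H", "U", "X"]

    def test_btex_plan(self, box2_plan):
        p = box2_plan
        assert (p.time_domain, p.space_domain) == ("t", "x")
        assert p.pde_vars == ["Ccap", "Cisf"]
        assert sorted(p.ics) == ["Ccap", "Cisf"]
        # total-flux inflow recognized as a Robin form; other edges reflect
        assert p.bcs[("Ccap", "min")].form == "robin"
        assert p.bcs[("Ccap", "max")].form == "neumann"
        assert p.bcs[("Cisf", "min")].form == "neumann"
        assert p.bcs[("Cisf", "max")].form == "neumann"
        # the outflow sampler is a time-only variable defined at x.max
        assert p.aux_boundary["Cout"][0] == "max"

    def test_minimal_single_ode(self):
        m = mml.parse_model(
            "math m { realDomain t; t.min=0; t.max=1; t.delta=0.5; "
            "real a(t); when (t=t.min) { a = 0; } a:t = 1; }")
        p = plan.classify_and_sequence(m)
        assert p.ode_vars == ["a"]
        g = plan.build_dependency_graph(m)
        assert sorted(g.nodes) == ["a", "t"]
        assert list(g.edges) == [("t", "a")]

    def test_plan_serialization_deterministic(self, box2_source):
        a = plan.classify_and_sequence(mml.parse_model(box2_source))
        b = plan.classify_and_sequence(mml.parse_model(box2_source))
        assert a.serialize() == b.serialize()
        assert a.serialize().encode() == b.serialize().encode()

    def test_nonlinear_implicit_rejected(self):
        src = ("math m { realDomain t; t.min=0; t.max=1; t.delta=0.5; "
               "real a(t); real b(t); when (t=t.min) { a = 1; } "
               "a:t = 0 - a; b*b + a = 2; }")
        with pytest.raises(plan.PlanError, match="nonlinear"):
            plan.classify_and_sequence(mml.parse_model(src))

    def test_linear_implicit_solved(self):
        src = ("math m { realDomain t; t.min=0; t.max=1; t.delta=0.5; "
               "real a(t); real b(t); when (t=t.min) { a = 1; } "
               "a:t = 0 - a; 2*b + a = 4; }")
        p = plan.classify_and_sequence(mml.parse_model(src))
        assert p.interior["b"].kind == "algebraic"
        assert not p.interior["b"].explicit

    def test_algebraic_cycle_rejected(self):
        src = ("math m { realDomain t; t.min=0; t.max=1; t.delta=0.5; "
               "real a(t); real b(t); real c(t); "
               "when (t=t.min) { c = 1; } c:t = 0 - c; "
               "a = b + c; b = a - c; }")
        with pytest.raises(plan.PlanError):
            plan.classify_and_sequence(mml.parse_model(src))


class TestCompleteness:
    @pytest.mark.parametrize("which", ["box1", "box2"])
    def test_every_single_deletion_yields_one_underspecified(
            self, which, box1_model, box2_model):
        model = {"box1": box1_model, "box2": box2_model}[which]
        for i in range(len(model.equations)):
            mutant = model.copy()
            del mutant.equations[i]
            diags = plan.validate_model(mutant)
            assert len(diags) == 1, (i, [str(d) for d in diags])
            assert diags[0].kind == "UNDERSPECIFIED"

    @pytest.mark.parametrize("which", ["box1", "box2"])
    def test_every_single_duplication_yields_one_overspecified(
            self, which, box1_model, box2_model):
        model = {"box1": box1_model, "box2": box2_model}[which]
        for i in range(len(model.equations)):
            mutant = model.copy()
            mutant.equations.append(model.copy().equations[i])
            diags = plan.validate_model(mutant)
            assert len(diags) == 1, (i, [str(d) for d in diags])
            assert diags[0].kind == "OVERSPECIFIED"

    def test_deleted_initial_condition_names_the_variable(self, box1_model):
        mutant = box1_model.copy()
        mutant.equations = [e for e in mutant.equations
                            if not (e.guard is not None
                                    and isinstance(e.lhs, mml.Name)
                                    and e.lhs.id == "U")]
        diags = plan.validate_model(mutant)
        assert [str(d) for d in diags] == \
            ["UNDERSPECIFIED(U: missing initial condition)"]

    def test_extra_algebraic_definition_is_overspecified(self, box1_model):
        mutant = box1_model.copy()
        extra = mml.parse_model(
            "math m { realDomain t; t.min=0; t.max=1; t.delta=0.5; "
            "real U(t); real H(t); when (t=t.min){U=0;H=0;} "
            "U:t = 1; H:t = 1; U = H; }")
        mutant.equations.append(extra.equations[-1])  # U = H
        diags = plan.validate_model(mutant)
        assert len(diags) == 1
        assert diags[0].kind == "OVERSPECIFIED" and diags[0].var == "U"


class TestSequencing:
    def test_evaluation_order_respects_dependencies(self):
        src = ("math m { realDomain t; t.min=0; t.max=1; t.delta=0.5; "
               "real y(t); real a(t); real b(t); real c(t); "
               "when (t=t.min) { y = 1; } y:t = 0 - y; "
               "c = b + y; b = 2*a; a = y + 1; }")
        p = plan.classify_and_sequence(mml.parse_model(src))
        # post-hoc: every dependency edge must point forward in the order
        g = plan.build_dependency_graph(p.model, include_params=False)
        pos = {name: i for i, name in enumerate(p.algebraic_order)}
        for u, v in g.edges:
            if u in pos and v in pos:
                assert pos[u] < pos[v], (u, v, p.algebraic_order)

    def test_lexicographic_tie_break(self):
        src = ("math m { realDomain t; t.min=0; t.max=1; t.delta=0.5; "
               "real y(t); real q(t); real p(t); "
               "when (t=t.min) { y = 1; } y:t = 0 - y; "
               "q = y; p = y; }")
        p = plan.classify_and_sequence(mml.parse_model(src))
        assert p.algebraic_order == ["p", "q"]


class TestNetworkGraph:
    def test_reaction_chain_edges(self, box1_model):
        g = plan.build_dependency_graph(box1_model, include_params=True)
        assert g.has_edge("H", "X") and g.has_edge("X", "U")
        assert g.has_edge("Vhmax", "H")
        assert not g.has_edge("U", "H")

    def test_btex_boundary_coupling(self, box2_model):
        g = plan.build_dependency_graph(box2_model, include_params=True)
        assert g.has_edge("Cin", "Ccap")      # via the inflow clause
        assert g.has_edge("Ccap", "Cisf") and g.has_edge("Cisf", "Ccap")
        assert g.has_edge("Ccap", "Cout")

    def test_hidden_parameters_shrink_node_set(self, box1_model):
        g = plan.build_dependency_graph(box1_model, include_params=False)
        assert sorted(g.nodes) == ["H", "U", "X", "t"]

    def test_empty_model_exports_empty_documents(self):
        m = mml.parse_model("math empty { }")
        g = plan.build_dependency_graph(m)
        dot = plan.export_network_graph(g, "dot")
        assert "->" not in dot
        import json
        doc = json.loads(plan.export_network_graph(g, "json"))
        assert doc == {"nodes": [], "edges": []}

    def test_btex_full_graph_matches_hand_enumeration(self, box2_model):
        g = plan.build_dependency_graph(box2_model, include_params=True)
        # enumerated by hand from the model source: per-variable symbol
        # sets of its interior equation, IC and boundary clauses
        expected_in = {
            "Ccap": {"t", "x", "Fcap", "L", "Vcap", "Dcap", "PS", "Cisf",
                     "Cin"},
            "Cisf": {"t", "x", "Gisf", "Visf", "Disf", "PS", "Ccap"},
            "Cout": {"x", "Ccap"},
        }
        for var, preds in expected_in.items():
            assert set(g.predecessors(var)) == preds, var
        assert set(g.predecessors("Cin")) == set()
        dot = plan.export_network_graph(g, "dot")
        assert '"Cin" [shape=diamond' in dot
        lines = [ln for ln in dot.splitlines() if "shape=" in ln]
        assert lines == sorted(lines)  # deterministic lexicographic order
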