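import pytest

from cardiobool.logic import (
    And,
    BooleanNetwork,
    Const,
    Not,
    Or,
    ParseError,
    Perturbation,
    PerturbationConflictError,
    UnknownNodeError,
    Var,
    apply_perturbation,
    async_successors,
    canonical_name,
    evaluate,
    format_expression,
    parse_expression,
    sync_step,
)

from conftest import make_net


class TestCanonicalNames:
    def test_separator_normalisation(self):
        assert canonical_name("GATA4/6") == "GATA4_6"
        assert canonical_name("NKX2-5") == "NKX2_5"
        assert canonical_name("nkx2.5") == "NKX2_5"

    def test_alias_table(self):
        assert canonical_name("COUP-TFII") == "NR2F2"
        assert canonical_name("GATAs") == "GATA4_6"

    def test_custom_aliases(self):
        assert canonical_name("foo", {"FOO": "BAR"}) == "BAR"


class TestParser:
    def test_and_not(self):
        expr = parse_expression("NR2F2 & !HEY2", {"NR2F2", "HEY2"})
        assert expr == And((Var("NR2F2"), Not(Var("HEY2"))))

    def test_alias_literal(self):
        assert parse_expression("COUP-TFII", {"NR2F2"}) == Var("NR2F2")

    def test_unclosed_parenthesis(self):
        with pytest.raises(ParseError):
            parse_expression("A & (B", {"A", "B"})

    def test_unknown_identifier_named(self):
        with pytest.raises(UnknownNodeError) as exc:
            parse_expression("A & MYSTERY", {"A"})
        assert "MYSTERY" in str(exc.value)

    def test_precedence_not_and_or(self):
        # !A & B | C parses as ((!A) & B) | C
        expr = parse_expression("!A & B | C", {"A", "B", "C"})
        assert expr == Or((And((Not(Var("A")), Var("B"))), Var("C")))

    def test_parentheses_override(self):
        expr = parse_expression("!(A | B)", {"A", "B"})
        assert expr == Not(Or((Var("A"), Var("B"))))

    def test_constants(self):
        assert parse_expression("0") == Const(0)
        assert parse_expression("A | 1", {"A"}) == Or((Var("A"), Const(1)))

    def test_empty_and_garbage(self):
        with pytest.raises(ParseError):
            parse_expression("", set())
        with pytest.raises(ParseError):
            parse_expression("A @ B", {"A", "B"})

    def test_trailing_token(self):
        with pytest.raises(ParseError):
            parse_expression("A B", {"A", "B"})

    def test_roundtrip_through_writer(self):
        for text in ("A & !B", "!(A | B) & C", "A | B & C", "1", "!A"):
            expr = parse_expression(text, {"A", "B", "C"})
            assert parse_expression(format_expression(expr), {"A", "B", "C"}) == expr


class TestEvaluate:
    def test_and_not(self):
        expr = And((Var("X"), Not(Var("Y"))))
        assert evaluate(expr, {"X": 1, "Y": 0}) == 1
        assert evaluate(expr, {"X": 1, "Y": 1}) == 0

    def test_constant(self):
        assert evaluate(Const(0), {"A": 1}) == 0

    def test_cm_myl7_rule(self, cm_model):
        # atrial steady state: MYL7 turns on when NR2F2=1 and HEY2=0
        rule = cm_model.network.functions["MYL7"]
        state = cm_model.network.state({"NR2F2": 1, "HEY2": 0})
        assert evaluate(rule, state) == 1


class TestSyncStep:
    def test_fixed_point_identity(self, or_absorb_net):
        state = or_absorb_net.state({"A": 1, "B": 0})
        assert sync_step(or_absorb_net, state) == state

    def test_swap(self, swap_net):
        nxt = sync_step(swap_net, swap_net.state({"X": 1, "Y": 0}))
        assert nxt.as_dict() == {"X": 0, "Y": 1}

    def test_clamped_node_keeps_clamp(self):
        net = make_net({"A": "B", "B": "B"}, clamps={"B": 1})
        nxt = sync_step(net, net.state({"A": 0}))
        assert nxt["B"] == 1 and nxt["A"] == 1

    def test_cm_nr2f2_follows_ra_in_one_step(self, cm_model):
        net = cm_model.network.with_clamps({"NOTCH": 1, "GATA4_6": 1, "RA": 1})
        start = net.state(0)  # everything off except the clamped inputs
        assert start["NR2F2"] == 0
        assert sync_step(net, start)["NR2F2"] == 1


class TestAsyncSuccessors:
    def test_fixed_point_self_only(self, or_absorb_net):
        state = or_absorb_net.state({"A": 1, "B": 0})
        assert async_successors(or_absorb_net, state) == frozenset({state})

    def test_swap_both_updates(self, swap_net):
        succ = async_successors(swap_net, swap_net.state({"X": 1, "Y": 0}))
        expected = {swap_net.state({"X": 0, "Y": 0}), swap_net.state({"X": 1, "Y": 1})}
        assert succ == frozenset(expected)

    def test_single_unstable_node(self):
        net = make_net({"A": "A", "B": "A"})
        state = net.state({"A": 1, "B": 0})  # only B is unstable
        succ = async_successors(net, state)
        assert succ == frozenset({state, net.state({"A": 1, "B": 1})})

    def test_fully_clamped(self):
        net = make_net({"A": "A"}, clamps={"A": 1})
        state = net.state(1)
        assert async_successors(net, state) == frozenset({state})

    def test_cardinality_bounds(self, swap_net):
        for bits in range(4):
            succ = async_successors(swap_net, swap_net.state(bits))
            assert 1 <= len(succ) <= swap_net.n_free


class TestPerturbations:
    def test_ko_forces_constant(self, cm_model):
        net = apply_perturbation(cm_model.network, [Perturbation.ko("NR2F2")])
        assert net.effective_function("NR2F2") == Const(0)
        assert "NR2F2" not in net.free_nodes
        assert net.perturbed == frozenset({"NR2F2"})

    def test_oe(self, cm_model):
        net = apply_perturbation(cm_model.network, [Perturbation.oe("HEY2")])
        assert net.effective_function("HEY2") == Const(1)

    def test_original_unmodified(self, cm_model):
        before = dict(cm_model.network.functions)
        apply_perturbation(cm_model.network, [Perturbation.ko("HAND2")])
        assert cm_model.network.functions == before

    def test_empty_list_is_identity(self, swap_net):
        assert apply_perturbation(swap_net, []) is swap_net

    def test_idempotence(self, cm_model):
        once = apply_perturbation(cm_model.network, [Perturbation.ko("HAND2")])
        twice = apply_perturbation(once, [Perturbation.ko("HAND2")])
        assert once == twice

    def test_conflict_raises(self, cm_model):
        with pytest.raises(PerturbationConflictError):
            apply_perturbation(
                cm_model.network,
                [Perturbation.ko("HEY2"), Perturbation.oe("HEY2")],
            )

    def test_unknown_node(self, swap_net):
        with pytest.raises(KeyError):
            apply_perturbation(swap_net, [Perturbation.ko("NOPE")])


class TestNetworkValidation:
    def test_duplicate_nodes_rejected(self):
        with pytest.raises(ValueError):
            BooleanNetwork(["A", "a"], {"A": Const(0)})

    def test_update_map_must_cover_nodes(self):
        with pytest.raises(ValueError):
            BooleanNetwork(["A", "B"], {"A": Const(0)})

    def test_undeclared_literal_rejected(self):
        with pytest.raises(UnknownNodeError):
            BooleanNetwork(["A"], {"A": Var("B")})

    def test_clamp_validation(self):
        with pytest.raises(KeyError):
            make_net({"A": "A"}, clamps={"B": 1})
        with pytest.raises(ValueError):
            make_net({"A": "A"}, clamps={"A": 2})

    def test_state_forces_clamps(self):
        net = make_net({"A": "A", "B": "B"}, clamps={"A": 1})
        assert net.state({"A": 0, "B": 0})["A"] == 1
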