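"""Gate constructors: species inventories, concentrations, truth tables."""

import itertools

import pytest

from dsdlabel.dsd import render_species
from dsdlabel.gates import (
    LOGIC_TABLES,
    enumerate_mapping_modules,
    gates_from_config,
    make_amplification_gate,
    make_fanout_gate,
    make_logic_gate,
    make_mapping_module,
    make_reporter_gate,
    table_from_bits,
)
from dsdlabel.kinetics import UNIT_NM


class TestMappingModule:
    def test_not_module_species_match_printed_strands(self):
        g = make_mapping_module(1, {"f": "t", "t": "f"}, [("mL", "mR")], ("nL", "nR"))
        texts = sorted(render_species(sp) for sp in g.species())
        assert texts == [
            "{T^*} [mL^ f mR^ T^] <nL^ t nR^>",
            "{T^*} [mL^ t mR^ T^] <nL^ f nR^>",
        ]

    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_one_gate_species_per_label_pattern(self, K):
        table = {p: "t" for p in itertools.product("ft", repeat=K)}
        ports = [(f"p{k}L", f"p{k}R") for k in range(K)]
        g = make_mapping_module(K, table, ports, ("oL", "oR"))
        assert len(g.species()) == 2**K
        assert all(c == UNIT_NM for c in g.species().values())

    def test_and_module_output_labels_follow_table(self):
        g = make_logic_gate("AND", [("mL", "mR"), ("nL", "nR")], ("hL", "hR"))
        # exactly one of the four gate species carries output label t
        outs = [sp.uppers[-1].right_tail[1].name for sp in g.species()]
        assert sorted(outs) == ["f", "f", "f", "t"]

    def test_constant_f_table_gives_all_f_outputs(self):
        table = {p: "f" for p in itertools.product("ft", repeat=2)}
        g = make_mapping_module(2, table, [("mL", "mR"), ("nL", "nR")], ("hL", "hR"))
        outs = {sp.uppers[-1].right_tail[1].name for sp in g.species()}
        assert outs == {"f"}

    def test_partial_table_rejected(self):
        with pytest.raises(ValueError, match="partial table"):
            make_mapping_module(2, {("f", "f"): "t"}, [("a", "b"), ("c", "d")], ("e", "g"))

    def test_duplicate_port_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate port"):
            make_mapping_module(1, {"f": "t", "t": "f"}, [("mL", "mR")], ("mL", "mR"))

    @pytest.mark.parametrize("K", [0, 5])
    def test_arity_bounds(self, K):
        with pytest.raises(ValueError):
            make_mapping_module(K, {}, [], ("a", "b"))


class TestLogicGates:
    @pytest.mark.parametrize(
        "kind,cases",
        [
            ("NOT", {(0,): 1, (1,): 0}),
            ("AND", {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 1}),
            ("OR", {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 1}),
            ("XOR", {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 0}),
        ],
    )
    def test_truth_tables(self, kind, cases):
        ports = [("mL", "mR")] if kind == "NOT" else [("mL", "mR"), ("nL", "nR")]
        g = make_logic_gate(kind, ports, ("hL", "hR"))
        for bits, expect in cases.items():
            assert g.eval(bits) == expect

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown gate kind"):
            make_logic_gate("NAND", [("a", "b")], ("c", "d"))


class TestEnumeration:
    @pytest.mark.parametrize("K,count", [(1, 4), (2, 16), (3, 256)])
    def test_number_of_distinct_tables(self, K, count):
        tables = enumerate_mapping_modules(K)
        assert len(tables) == count
        # all distinct, and all total
        assert len({tuple(sorted(t.items())) for t in tables}) == count
        # brute-force oracle: maps {0,1}^K -> {0,1}
        assert count == 2 ** (2**K)

    def test_k3_matches_bruteforce_function_enumeration(self):
        patterns = list(itertools.product("ft", repeat=3))
        seen = {
            tuple(t[p] for p in patterns) for t in enumerate_mapping_modules(3)
        }
        brute = set(itertools.product("ft", repeat=8))
        assert seen == brute


class TestAmplifier:
    def test_unit_target_concentrations(self):
        g = make_amplification_gate(("pL", "pR"), ("qL", "qR"))
        concs = sorted(g.species().values())
        assert concs == [10_000.0, 10_000.0, 20_000.0, 20_000.0]

    def test_fuel_is_twice_gate_concentration(self):
        g = make_amplification_gate(("pL", "pR"), ("qL", "qR"), 2_500.0)
        assert g.fuel_concentration == 2 * g.gate_concentration == 5_000.0

    def test_label_channels_are_disjoint(self):
        g = make_amplification_gate(("pL", "pR"), ("qL", "qR"))
        # the t-channel species share no strands with the f-channel species
        t_strands = {
            st for sp in g.species() for st in sp.strands
            if any(d.name == "t" for d in st)
        }
        f_strands = {
            st for sp in g.species() for st in sp.strands
            if any(d.name == "f" for d in st)
        }
        assert not (t_strands & f_strands)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_amplification_gate(("a", "b"), ("c", "d"), 0.0)


class TestFanOut:
    def test_two_fanout_has_eight_species(self):
        g = make_fanout_gate(2, ("mL", "mR"), [("n1L", "n1R"), ("n2L", "n2R")])
        sp = g.species()
        assert len(sp) == 8  # 6 gate double strands + 2 fuels
        frees = [s for s in sp if not hasattr(s, "uppers")]
        assert len(frees) == 2

    def test_fuel_scales_with_degree(self):
        ports = [(f"n{k}L", f"n{k}R") for k in range(9)]
        g = make_fanout_gate(9, ("mL", "mR"), ports)
        sp = g.species()
        assert len(sp) == 2 * (1 + 9 + 1)
        fuel_concs = {c for s, c in sp.items() if not hasattr(s, "uppers")}
        assert fuel_concs == {2 * 9 * UNIT_NM}

    def test_degree_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_fanout_gate(1, ("a", "b"), [("c", "d")])


class TestGateConfig:
    def test_bitstring_table_matches_and_gate(self):
        assert table_from_bits(2, "0001") == LOGIC_TABLES["AND"]
        with pytest.raises(ValueError):
            table_from_bits(2, "001")

    def test_yaml_config_roundtrip(self):
        import yaml

        doc = """
        - kind: mapping
          K: 2
          table: "0110"
          inputs: [[mL, mR], [nL, nR]]
          output: [hL, hR]
        - kind: amplification
          input: [hL, hR]
          output: [qL, qR]
        - kind: reporter
          input: [qL, qR]
        """
        gates = gates_from_config(yaml.safe_load(doc))
        assert [g.kind for g in gates] == ["mapping", "amplification", "reporter"]
        assert gates[0].table == LOGIC_TABLES["XOR"]
        assert gates[1].fuel_concentration == 2 * UNIT_NM

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown gate kind"):
            gates_from_config([{"kind": "threshold"}])


class TestReporter:
    def test_two_duplexes_and_fluorophore_strands(self):
        g = make_reporter_gate(("pL", "pR"))
        assert len(g.species()) == 2
        assert render_species(g.fluorophore("t")) == "<pL^ t pR^ fluor>"
        assert render_species(g.fluorophore("f")) == "<pL^ f pR^ fluor>"
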