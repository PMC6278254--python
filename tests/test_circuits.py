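"""Circuit compilation, encoding, decoding, and oracle agreement."""

import itertools
import random

import pytest

from conftest import ADDSUB_ORDER, MULT_ORDER, run_word
from dsdlabel.circuits import (
    BinaryWord,
    adder_subtractor_assignment,
    boolean_oracle,
    decode_levels,
    decode_outputs,
    expected_addsub,
    expected_product,
    multiplier_assignment,
    run_mapping_module,
    single_rail_full_adder_netlist,
    twos_complement_sub,
    Netlist,
)
from dsdlabel.dsd import render_species
from dsdlabel.gates import LOGIC_TABLES


class TestBinaryWord:
    def test_string_int_roundtrip(self):
        w = BinaryWord.from_string("00101101")
        assert int(w) == 45
        assert str(BinaryWord.from_int(45, 8)) == "00101101"

    def test_width_and_range_validation(self):
        with pytest.raises(ValueError):
            BinaryWord.from_string("012")
        with pytest.raises(ValueError):
            BinaryWord.from_string("0101", width=8)
        with pytest.raises(ValueError):
            BinaryWord.from_int(256, 8)


class TestComplementArithmetic:
    def test_worked_subtraction_77_minus_150(self):
        value, word = twos_complement_sub(77, 150, 8)
        assert value == 183
        assert str(BinaryWord.from_int(value, 8)) == "10110111"
        assert str(word) == "010110111"  # no carry-out: 77 < 150

    def test_self_subtraction_is_zero_with_carry(self):
        for x in (0, 1, 77, 255):
            value, word = twos_complement_sub(x, x, 8)
            assert value == 0
            assert str(word) == "100000000"  # carry-out set: no borrow

    def test_matches_modular_arithmetic(self):
        rng = random.Random(7)
        for _ in range(200):
            a, b = rng.randrange(256), rng.randrange(256)
            value, _ = twos_complement_sub(a, b, 8)
            assert value == (a - b) % 256

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            twos_complement_sub(-1, 0, 8)
        with pytest.raises(ValueError):
            twos_complement_sub(0, 256, 8)


class TestEncoding:
    def test_table3_input_strands_verbatim(self, addsub):
        asg = adder_subtractor_assignment("00101101", "10010110", 1)
        strands = {render_species(s) for s in addsub.encode(asg)}
        expected = {
            "<S2L^ t S2R^ T^ S2L^ t S2R^>",   # A0 = 1
            "<S3L^ f S3R^ T^ S3L^ f S3R^>",   # A1 = 0
            "<S4L^ t S4R^ T^ S4L^ t S4R^>",
            "<S5L^ t S5R^ T^ S5L^ t S5R^>",
            "<S6L^ f S6R^ T^ S6L^ f S6R^>",
            "<S7L^ t S7R^ T^ S7L^ t S7R^>",
            "<S8L^ f S8R^ T^ S8L^ f S8R^>",
            "<S9L^ f S9R^ T^ S9L^ f S9R^>",
            "<S10L^ f S10R^ T^ S10L^ f S10R^>",  # B0 = 0
            "<S11L^ t S11R^ T^ S11L^ t S11R^>",
            "<S12L^ t S12R^ T^ S12L^ t S12R^>",
            "<S13L^ f S13R^ T^ S13L^ f S13R^>",
            "<S14L^ t S14R^ T^ S14L^ t S14R^>",
            "<S15L^ f S15R^ T^ S15L^ f S15R^>",
            "<S16L^ f S16R^ T^ S16L^ f S16R^>",
            "<S17L^ t S17R^ T^ S17L^ t S17R^>",
            "<S0L^ t S0R^ T^ S0L^ t S0R^>",   # switch: subtraction
        }
        assert strands == expected

    def test_all_zero_word_encodes_all_f(self, addsub):
        asg = adder_subtractor_assignment("00000000", "00000000", 0)
        labels = {s.domains[5].name for s in addsub.encode(asg)}
        assert labels == {"f"}

    def test_missing_bits_rejected(self, addsub):
        with pytest.raises(ValueError, match="missing input"):
            addsub.encode({"A0": 1})

    def test_word_width_validated(self):
        with pytest.raises(ValueError):
            adder_subtractor_assignment("0101", "10010110", 1)


class TestDecodeBands:
    @pytest.mark.parametrize(
        "hi,lo,expect",
        [
            (0.97, 0.02, 1),
            (0.05, 0.95, 0),
            (0.5, 0.5, "ambiguous"),
            (0.97, 0.2, "ambiguous"),
            (0.85, 0.02, "ambiguous"),
        ],
    )
    def test_band_rules(self, hi, lo, expect):
        assert decode_levels(hi, lo) == expect


class TestNetlists:
    def test_single_rail_full_adder_inventory_and_layers(self):
        nl = single_rail_full_adder_netlist()
        tables = [n.table for n in nl.nodes]
        n_and = sum(1 for t in tables if t == LOGIC_TABLES["AND"])
        n_or = sum(1 for t in tables if t == LOGIC_TABLES["OR"])
        n_not = sum(1 for t in tables if t == LOGIC_TABLES["NOT"])
        assert (n_and, n_or, n_not) == (6, 3, 4)
        assert nl.layer_count() == 6

    @pytest.mark.parametrize("bits", list(itertools.product([0, 1], repeat=3)))
    def test_single_rail_adder_matches_arithmetic(self, bits):
        nl = single_rail_full_adder_netlist()
        out = boolean_oracle(nl, dict(zip(["x1", "x2", "c1"], bits)))
        total = sum(bits)
        assert (out["y"], out["c2"]) == (total % 2, total // 2)

    def test_combinational_cycle_detected(self):
        nl = Netlist(inputs=["a"], outputs=["x"])
        nl.add_table(["a", "y"], "x", LOGIC_TABLES["AND"])
        nl.add_table(["a", "x"], "y", LOGIC_TABLES["AND"])
        with pytest.raises(ValueError, match="cycle"):
            nl.eval({"a": 1})

    def test_multiplier_netlist_against_integer_oracle(self, multiplier):
        rng = random.Random(11)
        for _ in range(50):
            a, b = format(rng.randrange(16), "04b"), format(rng.randrange(16), "04b")
            out = boolean_oracle(multiplier.netlist, multiplier_assignment(a, b))
            word = "".join(str(out[k]) for k in MULT_ORDER)
            assert word == expected_product(a, b)

    def test_addsub_netlist_against_integer_oracle(self, addsub):
        rng = random.Random(13)
        for _ in range(50):
            a = format(rng.randrange(256), "08b")
            b = format(rng.randrange(256), "08b")
            sw = rng.randrange(2)
            out = boolean_oracle(addsub.netlist, adder_subtractor_assignment(a, b, sw))
            word = "".join(str(out[k]) for k in ADDSUB_ORDER)
            assert word == expected_addsub(a, b, sw)


class TestStructuralCounts:
    def test_multiplier_inventory(self, multiplier):
        role = lambda g: getattr(g, "role", "")
        assert multiplier.count("mapping", lambda g: role(g) == "partial_product") == 16
        assert multiplier.count("mapping", lambda g: role(g) == "ha_sum") == 4
        assert multiplier.count("mapping", lambda g: role(g) == "fa_sum") == 8
        assert multiplier.count("reporter") == 8
        assert multiplier.count("fanout") == 0

    def test_adder_subtractor_inventory(self, addsub):
        role = lambda g: getattr(g, "role", "")
        assert addsub.count("amplification") == 24
        assert addsub.count("mapping", lambda g: role(g) == "b_conditioning") == 8
        assert addsub.count("mapping", lambda g: role(g) == "fa_sum") == 8
        assert addsub.count("reporter") == 9
        fanouts = [g for g in addsub.gates if g.kind == "fanout"]
        assert len(fanouts) == 1 and fanouts[0].N == 9
        assert len([k for k in addsub.input_ports if k != "A#S"]) == 16

    def test_full_adder_inventory(self, full_adder):
        assert full_adder.count("mapping") == 2
        assert all(g.K == 3 for g in full_adder.gates if g.kind == "mapping")
        assert full_adder.count("fanout") == 3
        assert full_adder.count("amplification") == 2


class TestModuleSimulation:
    @pytest.mark.parametrize("pattern", ["f", "t"])
    def test_not_module_inverts(self, pattern):
        bit = run_mapping_module(LOGIC_TABLES["NOT"], pattern)
        assert bit == (0 if pattern == "t" else 1)

    @pytest.mark.parametrize("kind", ["AND", "OR", "XOR"])
    @pytest.mark.parametrize("pattern", ["ff", "ft", "tf", "tt"])
    def test_two_input_gates_follow_their_tables(self, kind, pattern):
        table = LOGIC_TABLES[kind]
        assert run_mapping_module(table, pattern) == (1 if table[tuple(pattern)] == "t" else 0)


class TestEndToEnd:
    @pytest.mark.parametrize("bits", list(itertools.product([0, 1], repeat=3)))
    def test_full_adder_exhaustive(self, full_adder, bits):
        a, b, c = bits
        word, traj = run_word(full_adder, {"A0": a, "B0": b, "C0": c}, ["S1", "S0"])
        total = a + b + c
        assert word == f"{total // 2}{total % 2}"
        assert traj.settled()

    def test_multiplier_annihilator(self, multiplier):
        word, _ = run_word(multiplier, multiplier_assignment("0000", "1011"), MULT_ORDER)
        assert word == "00000000"

    def test_addsub_zero_sum(self, addsub):
        word, _ = run_word(
            addsub, adder_subtractor_assignment("00000000", "00000000", 0), ADDSUB_ORDER
        )
        assert word == "000000000"

    def test_corrupted_gate_breaks_exactly_that_bit(self, full_adder):
        bad = full_adder.corrupted("S0")
        crn, traj = bad.run({"A0": 1, "B0": 0, "C0": 0})
        dec = decode_outputs(traj, bad)
        oracle = boolean_oracle(bad.netlist, {"A0": 1, "B0": 0, "C0": 0})
        assert dec["S0"]["bit"] != oracle["S0"]  # mismatch flagged on S0
        assert dec["S1"]["bit"] == oracle["S1"]
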