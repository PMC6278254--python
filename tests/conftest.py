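import pytest

from dsdlabel.circuits import (
    compile_adder_subtractor,
    compile_full_adder,
    compile_multiplier_4x4,
    decode_outputs,
    decoded_word,
)


@pytest.fixture(scope="session")
def full_adder():
    return compile_full_adder()


@pytest.fixture(scope="session")
def multiplier():
    return compile_multiplier_4x4()


@pytest.fixture(scope="session")
def addsub():
    return compile_adder_subtractor()


def run_word(circuit, assignment, order, t_end=10_000.0):
    """Close, integrate and decode a circuit's output word (MSB first)."""
    crn, traj = circuit.run(assignment, t_end=t_end)
    return decoded_word(decode_outputs(traj, circuit), order), traj


MULT_ORDER = [f"S{k}" for k in range(7, -1, -1)]
ADDSUB_ORDER = [f"S{k}" for k in range(8, -1, -1)]
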