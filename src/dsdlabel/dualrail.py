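"""Dual-rail seesaw baseline: threshold instability demonstration.

Concentration-encoded (dual-rail) seesaw circuits carry each logical wire
as a pair of species, logic 1 as 0.9-1 units and logic 0 as 0-0.1 units,
and rely on threshold gates that irreversibly absorb sub-threshold signal
before a fuel-driven gate restores the survivor toward one unit.  The
threshold separates high from low only if it sits well between the bands:
thresholds in the edge ranges (0.1-0.2 or 0.8-0.9 units) either let a
logic-0 leak through and be amplified, or eat so much of a logic-1 that
restoration cannot complete in the reaction window.  This module builds a
minimal dual-rail 1-bit adder fragment out of seesaw AND/OR units at the
ODE abstraction level (no strand structure) and reproduces that dichotomy;
the domain-label adder decides logic by hybridization instead of by
concentration and is immune by construction.

A 2-input seesaw unit with threshold ``th`` holds the accumulated input
``w``, an absorber at concentration ``th`` (rate 20x the gate exchange),
and a restoration gate of one unit driven catalytically by the surviving
input.  AND units use threshold 1 + theta, OR units theta, the standard
weight choice for dual-rail seesaw logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .circuits import decode_levels

__all__ = ["SeesawUnit", "simulate_dual_rail_adder", "SEESAW_RATE"]

# gate-exchange rate in /unit/s (1 unit = 10,000 nM); seesaw toeholds are
# deliberately slow compared to the displacement engine's defaults, giving
# the hours-scale kinetics typical of concentration-encoded circuits
SEESAW_RATE = 0.01
THRESHOLD_RATE_FACTOR = 20.0  # threshold toeholds are longer, so much faster

HIGH = 0.9  # units encoding logic 1 on a rail
LOW = 0.1  # units encoding logic 0 on a rail


@dataclass
class SeesawUnit:
    """One integrating seesaw gate: inputs, absorber, restoration gate."""

    name: str
    threshold: float  # absorber concentration, units
    sources: list  # ("const", level) or ("unit", index) flux feeds
    gate: float = 1.0  # restoration gate concentration, units


def _adder_units(theta: float, a: int, b: int) -> list[SeesawUnit]:
    a1, a0 = (HIGH, LOW) if a else (LOW, HIGH)
    b1, b0 = (HIGH, LOW) if b else (LOW, HIGH)
    th_and = 1.0 + theta
    th_or = theta
    units = [
        # layer 1: ANDs (index 0..4)
        SeesawUnit("and_c1", th_and, [("const", a1), ("const", b1)]),
        SeesawUnit("and_s1a", th_and, [("const", a1), ("const", b0)]),
        SeesawUnit("and_s1b", th_and, [("const", a0), ("const", b1)]),
        SeesawUnit("and_s0a", th_and, [("const", a1), ("const", b1)]),
        SeesawUnit("and_s0b", th_and, [("const", a0), ("const", b0)]),
        # layer 2: ORs (index 5..7)
        SeesawUnit("or_c0", th_or, [("const", a0), ("const", b0)]),
        SeesawUnit("or_s1", th_or, [("unit", 1), ("unit", 2)]),
        SeesawUnit("or_s0", th_or, [("unit", 3), ("unit", 4)]),
    ]
    return units


def _integrate(units: list[SeesawUnit], t_end: float) -> np.ndarray:
    n = len(units)
    k = SEESAW_RATE
    kth = THRESHOLD_RATE_FACTOR * k
    # state: [w_0..w_n-1, th_0.., g_0.., out_0..]
    w0 = np.array(
        [sum(v for kind, v in u.sources if kind == "const") for u in units]
    )
    y0 = np.concatenate(
        [w0, [u.threshold for u in units], [u.gate for u in units], np.zeros(n)]
    )
    feeds = [[src for kind, src in u.sources if kind == "unit"] for u in units]

    def rhs(t, y):
        w, th, g, out = y[:n], y[n : 2 * n], y[2 * n : 3 * n], y[3 * n :]
        absorb = kth * w * th
        restore = k * w * g  # catalytic: w is not consumed by restoration
        dw = -absorb
        for i, srcs in enumerate(feeds):
            for s in srcs:
                dw[i] += k * y[s] * y[2 * n + s]  # child's restoration flux
        return np.concatenate([dw, -absorb, -restore, restore])

    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"seesaw integration failed: {sol.message}")
    return sol.y[:, -1]


def simulate_dual_rail_adder(
    threshold: float, inputs: tuple[int, int], t_end: float = 2000.0
) -> dict:
    """Simulate the dual-rail (A, B) half-sum/carry fragment.

    ``threshold`` is the seesaw threshold parameter in units, restricted to
    (0, 1); the decoded (S, C) pair is compared with binary arithmetic and
    a verdict of ``"correct"`` or ``"incorrect"`` returned (any mismatch or
    ambiguous bit counts as incorrect).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1 units")
    a, b = (int(inputs[0]), int(inputs[1]))
    units = _adder_units(threshold, a, b)
    y = _integrate(units, t_end)
    n = len(units)
    out = y[3 * n :]
    rails = {
        "S": (float(out[6]), float(out[7])),  # (rail-1, rail-0)
        "C": (float(out[0]), float(out[5])),
    }
    decoded = {name: decode_levels(*pair) for name, pair in rails.items()}
    expect = {"S": (a + b) % 2, "C": (a + b) // 2}
    ok = all(decoded[k] == expect[k] for k in decoded)
    return {
        "threshold": threshold,
        "inputs": (a, b),
        "rails": rails,
        "decoded": decoded,
        "expected": expect,
        "verdict": "correct" if ok else "incorrect",
    }
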