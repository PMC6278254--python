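"""Deterministic mass-action integration of displacement CRNs.

Concentrations are held in nM internally; the external unit is the
circuits' normalization of 1 unit = 10,000 nM, with decode bands 0.9-1
units (logic 1) and 0-0.1 units (logic 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .dsd import Species, render_species
from .reactions import CRN

__all__ = ["UNIT_NM", "Trajectory", "SolverError", "simulate", "readout"]

UNIT_NM = 10_000.0  # 1 unit concentration, nM


class SolverError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Concentration time series for every species of a CRN (nM)."""

    times: np.ndarray  # (n_t,), strictly increasing, s
    data: np.ndarray  # (n_t, n_species), nM
    species: list[Species]
    names: list[str]

    def column(self, sp) -> np.ndarray:
        return self.data[:, self._find(sp)]

    def _find(self, sp) -> int:
        key = sp if isinstance(sp, str) else render_species(sp)
        try:
            return self.names.index(key)
        except ValueError:
            raise KeyError(f"unknown species {key!r}") from None

    def final(self, sp) -> float:
        return float(self.column(sp)[-1])

    def settled(self, species=None, tol_units_per_s: float = 1e-6) -> bool:
        """True if |d[x]/dt| over the last step is below tolerance (units/s)."""
        if len(self.times) < 2:
            return False
        cols = (
            self.data
            if species is None
            else self.data[:, [self._find(s) for s in species]]
        )
        dt = self.times[-1] - self.times[-2]
        rate = np.abs(cols[-1] - cols[-2]) / dt / UNIT_NM
        return bool(np.max(rate) < tol_units_per_s)

    def settle_time(self, species, tol_units_per_s: float = 1e-6) -> float:
        """Earliest time after which the given species' rates stay below tol."""
        cols = self.data[:, [self._find(s) for s in species]]
        dt = np.diff(self.times)[:, None]
        rate = np.abs(np.diff(cols, axis=0)) / dt / UNIT_NM
        quiet = np.all(rate < tol_units_per_s, axis=1)
        # last interval that was not quiet
        noisy = np.nonzero(~quiet)[0]
        if len(noisy) == 0:
            return float(self.times[0])
        if noisy[-1] == len(quiet) - 1:
            return float("inf")
        return float(self.times[noisy[-1] + 1])

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("time," + ",".join(f'"{n}"' for n in self.names) + "\n")
            for i, t in enumerate(self.times):
                fh.write(f"{t:g}," + ",".join(f"{v:.8g}" for v in self.data[i]) + "\n")


def _compile_rhs(crn: CRN):
    n = len(crn.species)
    m = len(crn.reactions)
    idx = crn.index()
    S = crn.stoichiometry().tocsr()
    k = np.array([rx.rate for rx in crn.reactions])
    r1 = np.empty(m, dtype=np.intp)
    r2 = np.full(m, -1, dtype=np.intp)
    for j, rx in enumerate(crn.reactions):
        r1[j] = idx[rx.reactants[0]]
        if len(rx.reactants) == 2:
            r2[j] = idx[rx.reactants[1]]
    bi = r2 >= 0
    r2safe = np.where(bi, r2, 0)

    def rhs(t, y):
        rates = k * y[r1]
        rates[bi] *= y[r2safe[bi]]
        return S @ rates

    # Jacobian: d(S@rates)/dy, assembled from the per-reaction partials
    rows = np.concatenate([np.arange(m), np.arange(m)[bi]])
    cols = np.concatenate([r1, r2[bi]])

    def jac(t, y):
        d1 = k.copy()
        d1[bi] *= y[r2safe[bi]]  # d rate / d y[r1]
        d2 = k[bi] * y[r1[bi]]  # d rate / d y[r2]
        Dr = sparse.csr_matrix(
            (np.concatenate([d1, d2]), (rows, cols)), shape=(m, n)
        )
        return (S @ Dr).tocsc()

    return rhs, jac


def simulate(
    crn: CRN,
    t_end: float = 10_000.0,
    rtol: float = 1e-8,
    atol: float = 1e-4,
    method: str = "BDF",
    t_eval=None,
) -> Trajectory:
    """Integrate the CRN's mass-action ODEs from its initial concentrations.

    Stiff-capable (BDF with an analytic sparse Jacobian).  Raises
    :class:`SolverError` with species/time context on failure.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = crn.concentration_vector()
    if np.any(y0 < 0):
        raise ValueError("negative initial concentration")
    if not crn.reactions:
        times = np.array([0.0, t_end])
        return Trajectory(times, np.tile(y0, (2, 1)), list(crn.species), crn.names)
    rhs, jac = _compile_rhs(crn)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        jac=jac,
        t_eval=t_eval,
    )
    if not sol.success:
        worst = int(np.argmax(np.abs(rhs(sol.t[-1], sol.y[:, -1]))))
        raise SolverError(
            f"integration failed at t={sol.t[-1]:.3g}s: {sol.message} "
            f"(fastest-moving species: {crn.names[worst]})"
        )
    data = np.clip(sol.y.T, 0.0, None)  # clamp solver noise below 0
    return Trajectory(sol.t, data, list(crn.species), crn.names)


def readout(traj: Trajectory, species, t: float) -> dict[str, float]:
    """Interpolated concentrations at time ``t``, in units of 10,000 nM."""
    if not (traj.times[0] <= t <= traj.times[-1]):
        raise ValueError(f"t={t} outside trajectory span")
    out = {}
    for sp in species:
        name = sp if isinstance(sp, str) else render_species(sp)
        col = traj.column(name)
        out[name] = float(np.interp(t, traj.times, col)) / UNIT_NM
    return out
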