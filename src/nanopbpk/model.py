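"""Seven-state minimal PBPK model: right-hand side, simulation, units.

The model tracks nanoparticle concentrations in plasma, lungs, MPS
(liver + spleen), kidneys and a lumped "others" compartment, plus the
cumulative masses excreted into urine and feces.  Transport is
perfusion-limited: organ *i* receives ``Q_i * C_p`` from plasma and
returns only its unbound pool, ``Q_i * f_i * C_i``.  The bound pool
``(1 - f_i) * C_i`` is subject to first-order excretion in the two
eliminating organs — MPS into feces (rate constant ``k_e_mps``) and
kidneys into urine (``k_e_k``).  In concentration form:

    V_p  dC_p/dt   = sum_i Q_i f_i C_i  -  (Q_lu + Q_mps + Q_k + Q_o) C_p
    V_i  dC_i/dt   = Q_i C_p - Q_i f_i C_i                    (i = lu, o)
    V_mps dC_mps/dt = Q_mps C_p - Q_mps f_mps C_mps - (1-f_mps) k_e_mps V_mps C_mps
    V_k  dC_k/dt   = Q_k C_p - Q_k f_k C_k - (1-f_k) k_e_k V_k C_k
    dM_u/dt = (1-f_k) k_e_k V_k C_k
    dM_f/dt = (1-f_mps) k_e_mps V_mps C_mps

which closes the mass balance exactly: the total tracked mass
``V_p C_p + sum_i V_i C_i + M_u + M_f`` is constant and equal to the dose.
The entire dose starts in plasma: ``C_p(0) = D / V_p``.

The system is linear and time-invariant, so alongside the stiff ODE
integrator (the plasma time constant is fractions of a minute while organ
retention spans days) an exact propagator based on the eigendecomposition
of the rate matrix is available (``method="expm"``).  The two routes agree
to solver tolerance and the exact one is what calibration and sensitivity
analysis use internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import DoseSpec, KineticParams, PhysiologyParams

__all__ = [
    "COMPARTMENTS",
    "CONCENTRATION_COMPARTMENTS",
    "EXCRETA_COMPARTMENTS",
    "rate_matrix",
    "rhs",
    "simulate",
    "SimulationResult",
    "IntegrationError",
    "convert_units",
]

#: State ordering used everywhere: five concentration states then two masses.
COMPARTMENTS = ("plasma", "lungs", "mps", "kidneys", "others", "urine", "feces")
CONCENTRATION_COMPARTMENTS = COMPARTMENTS[:5]
EXCRETA_COMPARTMENTS = COMPARTMENTS[5:]

#: %ID mode normalises the dose to 100, so that concentrations are %ID/mL
#: (equal to %ID/g under unit tissue density) and excreta masses are %ID.
PERCENT_ID = "%ID"
MICROGRAM = "ug"
_UNIT_TAGS = (PERCENT_ID, MICROGRAM)


class IntegrationError(RuntimeError):
    """Stiff integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time: {last_time:g} h)")
        self.last_time = last_time


def rate_matrix(phys: PhysiologyParams, kin: KineticParams) -> np.ndarray:
    """Rate matrix ``A`` of the system in *amount* coordinates.

    With amounts ``a = (V_p C_p, V_lu C_lu, V_mps C_mps, V_k C_k, V_o C_o,
    M_u, M_f)`` the dynamics are ``da/dt = A a``.  Every column of ``A``
    sums to zero, which is the matrix expression of the closed mass
    balance.
    """
    q = {"lungs": phys.q_lu, "mps": kin.q_mps, "kidneys": phys.q_k, "others": kin.q_o}
    f = {"lungs": kin.f_lu, "mps": kin.f_mps, "kidneys": kin.f_k, "others": kin.f_o}
    v = phys.volumes
    elim = {
        "mps": (1.0 - kin.f_mps) * kin.k_e_mps,
        "kidneys": (1.0 - kin.f_k) * kin.k_e_k,
    }

    a = np.zeros((7, 7))
    a[0, 0] = -sum(q.values()) / v["plasma"]
    for idx, organ in enumerate(("lungs", "mps", "kidneys", "others"), start=1):
        a[idx, 0] = q[organ] / v["plasma"]
        a[0, idx] = q[organ] * f[organ] / v[organ]
        a[idx, idx] = -q[organ] * f[organ] / v[organ] - elim.get(organ, 0.0)
    a[5, 3] = elim["kidneys"]   # kidneys -> urine
    a[6, 2] = elim["mps"]       # MPS -> feces
    return a


def rhs(state, phys: PhysiologyParams, kin: KineticParams):
    """Time derivative of the state in *concentration* coordinates.

    ``state`` is ``(C_p, C_lu, C_mps, C_k, C_o, M_u, M_f)``; the returned
    vector holds ``dC/dt`` for the five concentrations and ``dM/dt`` for
    the two excreta masses.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (7,):
        raise ValueError(f"state must have 7 entries, got shape {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state entries must be finite")
    volumes = np.array([phys.v_p, phys.v_lu, phys.v_mps, phys.v_k, phys.v_o, 1.0, 1.0])
    amounts = state * volumes
    return rate_matrix(phys, kin) @ amounts / volumes


@dataclass
class SimulationResult:
    """Trajectories of the model on a time grid.

    ``concentrations`` holds one column per concentration compartment
    (%ID/g or µg/mL depending on ``units``); ``excreta`` holds the
    cumulative urine and feces masses (%ID or µg).
    """

    time: np.ndarray
    concentrations: pd.DataFrame
    excreta: pd.DataFrame
    units: str
    dose: DoseSpec
    method: str = "lsoda"
    phys: PhysiologyParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.units not in _UNIT_TAGS:
            raise ValueError(f"units must be one of {_UNIT_TAGS}, got {self.units!r}")
        n = len(self.time)
        if len(self.concentrations) != n or len(self.excreta) != n:
            raise ValueError("trajectory arrays must share the time-grid length")

    @property
    def dose_amount(self) -> float:
        """The dose in the simulation's own units (100 in %ID mode)."""
        return 100.0 if self.units == PERCENT_ID else self.dose.amount_ug

    def total_mass(self) -> np.ndarray:
        """Total tracked mass at each output time (should equal the dose)."""
        if self.phys is None:
            raise ValueError("physiology not recorded on this result")
        v = self.phys.volumes
        mass = sum(self.concentrations[c].to_numpy() * v[c] for c in CONCENTRATION_COMPARTMENTS)
        return mass + self.excreta.sum(axis=1).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: compartment, time_h, value, unit."""
        conc_unit = "%ID/g" if self.units == PERCENT_ID else "ug/mL"
        mass_unit = "%ID" if self.units == PERCENT_ID else "ug"
        rows = []
        for comp in CONCENTRATION_COMPARTMENTS:
            rows.append(
                pd.DataFrame(
                    {
                        "compartment": comp,
                        "time_h": self.time,
                        "value": self.concentrations[comp].to_numpy(),
                        "unit": conc_unit,
                    }
                )
            )
        for comp in EXCRETA_COMPARTMENTS:
            rows.append(
                pd.DataFrame(
                    {
                        "compartment": comp,
                        "time_h": self.time,
                        "value": self.excreta[comp].to_numpy(),
                        "unit": mass_unit,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def plot(self, ax=None, logy: bool = True):
        """Quick-look trajectory plot (concentrations on one axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for comp in CONCENTRATION_COMPARTMENTS:
            ax.plot(self.time, self.concentrations[comp], label=comp)
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("%ID/g" if self.units == PERCENT_ID else "µg/mL")
        ax.legend()
        return ax


def _propagate_exact(a: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Exact trajectories of ``dx/dt = A x`` via eigendecomposition.

    Falls back to per-interval matrix exponentials when the eigenbasis is
    ill-conditioned (near-defective matrix).
    """
    w, v = np.linalg.eig(a)
    cond = np.linalg.cond(v)
    if np.isfinite(cond) and cond < 1e10:
        c = np.linalg.solve(v, x0.astype(complex))
        out = (v @ (np.exp(np.outer(w, times)) * c[:, None])).real.T
        out[times == 0.0] = x0
        return out
    out = np.empty((len(times), len(x0)))
    x = x0.copy()
    t_prev = 0.0
    for i, t in enumerate(times):
        if t != t_prev:
            x = expm(a * (t - t_prev)) @ x
            t_prev = t
        out[i] = x
    return out


def simulate(
    phys: PhysiologyParams,
    kin: KineticParams,
    dose: DoseSpec,
    t_grid,
    units: str = PERCENT_ID,
    method: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Simulate the model from the intravenous-bolus initial condition.

    Parameters
    ----------
    t_grid
        Strictly increasing output times in hours, starting at 0.
    units
        ``"%ID"`` (default) normalises the dose to 100 so concentrations
        are %ID/g; ``"ug"`` uses the absolute dose in µg.
    method
        ``"lsoda"`` / ``"bdf"`` for stiff numerical integration or
        ``"expm"`` for the exact linear-system propagator.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a one-dimensional time vector")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    if units not in _UNIT_TAGS:
        raise ValueError(f"units must be one of {_UNIT_TAGS}")

    d = 100.0 if units == PERCENT_ID else dose.amount_ug
    x0 = np.zeros(7)
    x0[0] = d  # full dose in plasma, amount coordinates

    a = rate_matrix(phys, kin)
    if method == "expm":
        states = _propagate_exact(a, x0, t_grid)
    elif method in ("lsoda", "bdf"):
        sol = solve_ivp(
            lambda _, x: a @ x,
            (t_grid[0], t_grid[-1]),
            x0,
            method="LSODA" if method == "lsoda" else "BDF",
            t_eval=t_grid,
            jac=lambda _, x: a,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(sol.message, sol.t[-1] if len(sol.t) else 0.0)
        states = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")

    volumes = np.array([phys.v_p, phys.v_lu, phys.v_mps, phys.v_k, phys.v_o])
    conc = pd.DataFrame(states[:, :5] / volumes, columns=list(CONCENTRATION_COMPARTMENTS))
    excreta = pd.DataFrame(states[:, 5:], columns=list(EXCRETA_COMPARTMENTS))
    return SimulationResult(
        time=t_grid,
        concentrations=conc,
        excreta=excreta,
        units=units,
        dose=dose,
        method=method,
        phys=phys,
    )


def convert_units(result: SimulationResult, direction: str) -> SimulationResult:
    """Convert a result between absolute (µg/mL, µg) and relative (%ID/g, %ID) units.

    Under the 1 g/mL density assumption ``%ID/g = 100 * C[µg/mL] / D[µg]``
    and ``%ID = 100 * M[µg] / D[µg]``; the round trip is the identity.
    """
    if direction == "to_percent_id":
        if result.units != MICROGRAM:
            raise ValueError(f"expected a result in µg units, got {result.units!r}")
        factor, new_units = 100.0 / result.dose.amount_ug, PERCENT_ID
    elif direction == "to_microgram":
        if result.units != PERCENT_ID:
            raise ValueError(f"expected a result in %ID units, got {result.units!r}")
        factor, new_units = result.dose.amount_ug / 100.0, MICROGRAM
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return SimulationResult(
        time=result.time,
        concentrations=result.concentrations * factor,
        excreta=result.excreta * factor,
        units=new_units,
        dose=result.dose,
        method=result.method,
        phys=result.phys,
    )
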