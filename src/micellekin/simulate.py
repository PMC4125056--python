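"""Time integration of the micelle-dependent model for the standard
experiment designs: unseeded kinetics, seeded kinetics, postponed seeding
and scans over initial concentration / seed mass / seed delay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import StateVector, rhs_flat, warn_if_boundary_heavy
from .parameters import ConfigurationError, ModelParameters
from .rates import RateTable, build_rate_table

__all__ = ["SimulationSetup", "Trajectory", "initial_state", "simulate", "scan"]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to complete a run."""


@dataclass(frozen=True)
class SimulationSetup:
    """Experimental design of one kinetic run.

    ``seed_mass`` is the mass concentration of preformed polymers
    injected at ``seed_time`` (0 = present from the start; > 0 =
    postponed seeding) as a monodisperse population of size
    ``seed_length``.  ``c0`` is the initial PrP^C concentration; PrP*
    does not exist before the experiment, so v(0) = 0 always.
    """

    c0: float = 1.0
    seed_mass: float = 0.0
    seed_length: int = 50
    seed_time: float = 0.0
    t_end: float = 100.0
    n_points: int = 500
    rtol: float = 1e-8
    atol: float = 1e-12
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.seed_mass < 0 or self.seed_time < 0:
            raise ConfigurationError("c0, seed_mass and seed_time must be >= 0")
        if self.t_end <= self.seed_time:
            raise ConfigurationError("t_end must exceed seed_time")

    def replace(self, **changes) -> "SimulationSetup":
        return replace(self, **changes)


@dataclass
class Trajectory:
    """Macroscopic observables along a simulated run.

    ``micelle_mass`` and ``polymer_mass`` are monomer-weighted sums
    (sum_i i*m_i, sum_j j*u_j): the quantities compared to micelle
    counts and to the ThT signal.  ``snapshots`` optionally holds the
    full state at every output time (rows of the packed state vector).
    """

    times: np.ndarray
    c: np.ndarray
    v: np.ndarray
    micelle_number: np.ndarray
    micelle_mass: np.ndarray
    polymer_number: np.ndarray
    polymer_mass: np.ndarray
    mass_residual: float = 0.0
    snapshots: np.ndarray | None = None
    I_max: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "c": self.c,
                "v": self.v,
                "micelle_number": self.micelle_number,
                "micelle_mass": self.micelle_mass,
                "polymer_number": self.polymer_number,
                "polymer_mass": self.polymer_mass,
            }
        )

    def final_state(self) -> StateVector | None:
        if self.snapshots is None or self.I_max is None:
            return None
        return StateVector.from_flat(self.snapshots[-1], self.I_max)


def initial_state(setup: SimulationSetup, params: ModelParameters) -> StateVector:
    """State at t = 0: all mass in PrP^C except an optional seed.

    The seed is placed monodisperse at ``seed_length`` (number
    concentration ``seed_mass / seed_length``) only when ``seed_time``
    is zero; postponed seeds are injected during :func:`simulate`.
    """
    if setup.seed_length > params.N_max:
        raise ConfigurationError(
            f"seed_length={setup.seed_length} exceeds N_max={params.N_max}"
        )
    if setup.seed_mass > 0 and setup.seed_length < params.n_nucleus:
        raise ConfigurationError("seed_length must be >= n_nucleus")
    state = StateVector.zeros(params.I_max, params.N_max)
    state.c = setup.c0
    if setup.seed_mass > 0 and setup.seed_time == 0:
        state.u[setup.seed_length - 2] = setup.seed_mass / setup.seed_length
    return state


def _integrate(y0, t_span, t_eval, rates, setup, elongate_with_c=False):
    sol = solve_ivp(
        rhs_flat,
        t_span,
        y0,
        method=setup.method,
        t_eval=t_eval,
        rtol=setup.rtol,
        atol=setup.atol,
        args=(rates, elongate_with_c),
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    return sol


def _mass_of_flat(Y: np.ndarray, rates: RateTable) -> np.ndarray:
    """Total mass per row of a (n_times, n_species) state matrix."""
    nm = rates.I_max - 1
    Y = np.atleast_2d(Y)
    return (
        Y[:, 0]
        + Y[:, 1]
        + Y[:, 2 : 2 + nm] @ rates.micelle_sizes
        + Y[:, 2 + nm :] @ rates.polymer_sizes
    )


def simulate(
    setup: SimulationSetup,
    params: ModelParameters,
    *,
    keep_snapshots: bool = False,
    check_boundaries: bool = True,
    _elongate_with_c: bool = False,
) -> Trajectory:
    """Integrate the model over ``[0, t_end]`` on a uniform output grid.

    Postponed seeding integrates seed-free to ``seed_time``, adds the
    seed mass to the running state, and restarts the integrator; the
    conserved total then jumps by exactly ``seed_mass`` at the seed time.
    The relative drift of the total mass over each integration leg is
    recorded in ``Trajectory.mass_residual``.
    """
    rates = build_rate_table(params)
    y0 = initial_state(setup, params).to_flat()
    t_eval = np.linspace(0.0, setup.t_end, setup.n_points)

    if setup.seed_mass > 0 and setup.seed_time > 0:
        pre_mask = t_eval < setup.seed_time
        t_pre = t_eval[pre_mask]
        sol_pre = _integrate(
            y0, (0.0, setup.seed_time), np.append(t_pre, setup.seed_time), rates, setup, _elongate_with_c
        )
        y_seeded = sol_pre.y[:, -1].copy()
        mass_pre = _mass_of_flat(sol_pre.y.T, rates)
        y_seeded[2 + (params.I_max - 1) + setup.seed_length - 2] += (
            setup.seed_mass / setup.seed_length
        )
        sol_post = _integrate(
            y_seeded, (setup.seed_time, setup.t_end), t_eval[~pre_mask], rates, setup, _elongate_with_c
        )
        ys = np.hstack([sol_pre.y[:, :-1], sol_post.y])
        masses = np.concatenate([mass_pre[:-1], _mass_of_flat(sol_post.y.T, rates)])
        expected = np.where(t_eval < setup.seed_time, setup.c0, setup.c0 + setup.seed_mass)
        residual = float(np.max(np.abs(masses - expected) / expected))
    else:
        sol = _integrate(y0, (0.0, setup.t_end), t_eval, rates, setup, _elongate_with_c)
        ys = sol.y
        masses = _mass_of_flat(ys.T, rates)
        m0 = masses[0] if masses[0] > 0 else 1.0
        residual = float(np.max(np.abs(masses - masses[0])) / m0)

    # tolerate solver-scale negative excursions, flag anything larger
    scale = max(1.0, setup.c0 + setup.seed_mass)
    neg_floor = -10.0 * max(setup.atol, setup.rtol) * scale
    worst = float(ys.min(initial=0.0))
    if worst < neg_floor:
        raise IntegrationError(
            f"state went negative beyond solver tolerance (min {worst:.2e}); "
            "tighten rtol/atol or check the rate configuration"
        )
    ys = np.clip(ys, 0.0, None)

    nm = params.I_max - 1
    m_block = ys[2 : 2 + nm, :]
    u_block = ys[2 + nm :, :]
    traj = Trajectory(
        times=t_eval,
        c=ys[0, :].copy(),
        v=ys[1, :].copy(),
        micelle_number=m_block.sum(axis=0),
        micelle_mass=rates.micelle_sizes @ m_block,
        polymer_number=u_block.sum(axis=0),
        polymer_mass=rates.polymer_sizes @ u_block,
        mass_residual=residual,
        snapshots=ys.T.copy() if keep_snapshots else None,
        I_max=params.I_max if keep_snapshots else None,
    )
    if check_boundaries:
        warn_if_boundary_heavy(StateVector.from_flat(ys[:, -1], params.I_max))
    return traj


def scan(
    setup_template: SimulationSetup,
    params: ModelParameters,
    variable: Literal["c0", "seed_mass", "seed_time"],
    values: Sequence[float],
    *,
    simulate_fn=None,
) -> pd.DataFrame:
    """Run one simulation per value of ``variable`` and summarize each.

    Returns a table with one row per value: the half-time, maximal slope,
    inflexion time, lag time and plateau of the polymer-mass trace.
    ``simulate_fn`` may substitute another driver with the same signature
    (e.g. the nucleation-dependent comparator).
    """
    from .observables import KineticTrace, half_time, lag_time, max_slope

    if variable not in ("c0", "seed_mass", "seed_time"):
        raise ConfigurationError(f"cannot scan over {variable!r}")
    if len(values) == 0:
        raise ConfigurationError("scan needs at least one value")
    run = simulate_fn if simulate_fn is not None else simulate

    rows = []
    for value in values:
        setup = setup_template.replace(**{variable: value})
        traj = run(setup, params)
        trace = KineticTrace(times=traj.times, signal=traj.polymer_mass)
        t_half, plateau = half_time(trace, return_plateau=True)
        k_max, t_inflexion = max_slope(trace)
        rows.append(
            {
                variable: value,
                "t_half": t_half,
                "k_max": k_max,
                "t_inflexion": t_inflexion,
                "lag": lag_time(t_half, k_max, plateau),
                "plateau": plateau,
            }
        )
    return pd.DataFrame(rows)
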