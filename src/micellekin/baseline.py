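"""Nucleation-dependent comparator: polymerization without micelles.

In this reference model PrP^C monomers nucleate and elongate polymers
directly — there is no micelle intermediate and no conformational step.
It shares the kinetic engine of :mod:`micellekin.model`: the micelle
rates are zeroed and the polymer ladder elongates with the PrP^C pool,
so fragmentation bookkeeping and mass conservation are identical by
construction.  It reproduces the classical predictions the micelle
model is contrasted with: the half-time collapses to zero under heavy
seeding, and the log-log slope of the half-time versus initial
concentration steepens with the nucleus size.
"""

from __future__ import annotations

import numpy as np

from .model import StateVector, rhs_flat
from .parameters import BaselineParameters
from .rates import build_rate_table
from .simulate import SimulationSetup, Trajectory, simulate

__all__ = ["rhs_baseline", "simulate_baseline"]


def rhs_baseline(c: float, u: np.ndarray, params: BaselineParameters) -> tuple[float, np.ndarray]:
    """Time derivative of the comparator state (c, u_2..u_Nmax).

    Runs the shared engine with the micelle pathway switched off and the
    polymer ladder driven by PrP^C; size-1 fragments return to PrP^C.
    """
    mp = params.as_model_parameters()
    rates = build_rate_table(mp)
    state = StateVector.zeros(mp.I_max, mp.N_max)
    state.c = c
    state.u = np.asarray(u, dtype=float)
    dy = rhs_flat(0.0, state.to_flat(), rates, elongate_with_c=True)
    d = StateVector.from_flat(dy, mp.I_max)
    return d.c, d.u


def simulate_baseline(
    setup: SimulationSetup, params: BaselineParameters, **kwargs
) -> Trajectory:
    """Integrate the comparator for the same experiment designs.

    Accepts the same setup (including seeding and postponed seeding) and
    returns the same :class:`~micellekin.simulate.Trajectory`; the
    micelle series are identically zero.
    """
    mp = params.as_model_parameters()
    return simulate(setup, mp, _elongate_with_c=True, **kwargs)
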