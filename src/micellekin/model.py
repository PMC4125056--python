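"""State vector, reaction fluxes and the coupled right-hand side.

The model chains four processes: (1) Becker-Doring micelle growth by
PrP^C addition/release, (2) conformational conversion inside micelles,
which release stabilized PrP* monomers, (3) nucleation of unstable PrP*
oligomers up to the nucleus size, and (4) irreversible polymer elongation
with binary fragmentation.  The closed system conserves the total
monomer mass

    M = c + sum_i i*m_i + v + sum_j j*u_j,

exactly at the level of the vector field; the truncation boundaries at
``I_max`` and ``N_max`` are no-flux so conservation holds in the
truncated system too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rates import RateTable

__all__ = [
    "StateVector",
    "MicelleFluxes",
    "PolymerFluxes",
    "micelle_fluxes",
    "polymer_fluxes",
    "rhs",
    "rhs_flat",
    "total_mass",
    "boundary_mass_fraction",
]


class NumericalStateError(FloatingPointError):
    """Raised when a state contains NaN or infinite entries."""


@dataclass
class StateVector:
    """Concentrations of every species, indexed by cluster size.

    ``m[k]`` is the concentration of micelles of size ``k + 2``
    (sizes ``2..I_max``); ``u[k]`` of oligomers/polymers of size
    ``k + 2`` (sizes ``2..N_max``).  Aggregates below the nucleus size
    are unstable oligomers; at and above it, stable PrP^Sc polymers.
    """

    c: float
    m: np.ndarray
    v: float
    u: np.ndarray

    @classmethod
    def zeros(cls, I_max: int, N_max: int) -> "StateVector":
        return cls(0.0, np.zeros(I_max - 1), 0.0, np.zeros(N_max - 1))

    @property
    def micelle_sizes(self) -> np.ndarray:
        return np.arange(2, self.m.shape[0] + 2)

    @property
    def polymer_sizes(self) -> np.ndarray:
        return np.arange(2, self.u.shape[0] + 2)

    def to_flat(self) -> np.ndarray:
        """Pack as ``[c, v, m_2..m_Imax, u_2..u_Nmax]``."""
        return np.concatenate(([self.c, self.v], self.m, self.u))

    @classmethod
    def from_flat(cls, y: np.ndarray, I_max: int) -> "StateVector":
        nm = I_max - 1
        return cls(c=float(y[0]), v=float(y[1]), m=np.asarray(y[2 : 2 + nm]), u=np.asarray(y[2 + nm :]))


def total_mass(state: StateVector) -> float:
    """Total monomer mass: c + sum_i i*m_i + v + sum_j j*u_j."""
    return (
        state.c
        + float(state.micelle_sizes @ state.m)
        + state.v
        + float(state.polymer_sizes @ state.u)
    )


@dataclass
class MicelleFluxes:
    """Net upward ladder fluxes through the micelle size ladder.

    ``J_C[k]`` is the net rate of the size ``k+1 -> k+2`` step carried by
    PrP^C (association minus release); ``J_C[0]`` is the dimer-formation
    flux ``a*c**2 - deplete_C_2*m_2``.  ``J_S`` is the analogue for PrP*.
    There is no flux out of the top size ``I_max``.
    """

    J_C: np.ndarray
    J_S: np.ndarray


def micelle_fluxes(state: StateVector, rates: RateTable) -> MicelleFluxes:
    """Net rates of the micelle association/release reactions."""
    m = state.m
    nm = m.shape[0]
    J_C = np.empty(nm)
    J_S = np.empty(nm)
    # dimer step: two free monomers -> smallest micelle
    J_C[0] = rates.assoc_C[0] * state.c * state.c - rates.deplete_C[0] * m[0]
    J_S[0] = rates.assoc_S[0] * state.v * state.v - rates.deplete_S[0] * m[0]
    if nm > 1:
        J_C[1:] = rates.assoc_C[1:] * state.c * m[:-1] - rates.deplete_C[1:] * m[1:]
        J_S[1:] = rates.assoc_S[1:] * state.v * m[:-1] - rates.deplete_S[1:] * m[1:]
    return MicelleFluxes(J_C=J_C, J_S=J_S)


@dataclass
class PolymerFluxes:
    """Elongation and fragmentation rates of the polymer ladder.

    ``F[k]`` is the net elongation flux of the size ``k+1 -> k+2`` step
    (``F[0]`` the PrP* dimer flux ``tau*v**2 - depolym_2*u_2``);
    ``loss[k]`` the fragmentation loss of size ``k+2``; ``gain[k]`` the
    rate at which fragments of size ``k+2`` appear; ``monomer_return``
    the rate at which size-1 fragments return to the free monomer pool.
    Every split yields two fragments, hence the factor 2 in the gains.
    """

    F: np.ndarray
    loss: np.ndarray
    gain: np.ndarray
    monomer_return: float


def polymer_fluxes(state: StateVector, rates: RateTable, monomer: float | None = None) -> PolymerFluxes:
    """Net elongation rates plus fragmentation gain/loss bookkeeping.

    ``monomer`` is the elongating monomer pool (PrP* by default; the
    nucleation-dependent comparator passes PrP^C instead).
    """
    if monomer is None:
        monomer = state.v
    u = state.u
    nu = u.shape[0]
    F = np.empty(nu)
    F[0] = rates.polym[0] * monomer * monomer - rates.depolym[0] * u[0]
    if nu > 1:
        F[1:] = rates.polym[1:] * monomer * u[:-1] - rates.depolym[1:] * u[1:]

    loss = rates.frag * u
    # Uniform kernel: a j-mer splitting produces 2 fragments spread
    # uniformly over sizes 1..j-1, so the gain at any size s < j is
    # 2*frag_j*u_j/(j-1), independent of s.  Suffix sums give all gains.
    sizes = rates.polymer_sizes
    contrib = 2.0 * loss / (sizes - 1.0)
    suffix = np.cumsum(contrib[::-1])[::-1]  # suffix[k] = sum over sizes >= k+2
    gain = np.zeros(nu)
    if nu > 1:
        gain[: nu - 1] = suffix[1:]
    monomer_return = float(suffix[0])
    return PolymerFluxes(F=F, loss=loss, gain=gain, monomer_return=monomer_return)


def _check_finite(y: np.ndarray) -> None:
    if not np.isfinite(y).all():
        raise NumericalStateError("state contains NaN or Inf")


def rhs(state: StateVector, rates: RateTable) -> StateVector:
    """Time derivative of the full micelle-dependent model.

    PrP^C is consumed by every micelle ladder step (the dimer flux twice,
    because two monomers enter the first reaction).  Micelles feel four
    reactions each: PrP^C association/release from below and above, and
    the same pair for PrP*.  PrP* is produced by micelle release, and
    consumed by nucleation/elongation; size-1 fragments return to it.
    """
    _check_finite(state.to_flat())
    mic = micelle_fluxes(state, rates)
    pol = polymer_fluxes(state, rates)

    J = mic.J_C + mic.J_S
    dm = np.empty_like(state.m)
    dm[:-1] = J[:-1] - J[1:]
    dm[-1] = J[-1]

    dc = -2.0 * mic.J_C[0] - mic.J_C[1:].sum()

    du = np.empty_like(state.u)
    du[:-1] = pol.F[:-1] - pol.F[1:]
    du[-1] = pol.F[-1]
    du += pol.gain - pol.loss

    dv = (
        -2.0 * mic.J_S[0]
        - mic.J_S[1:].sum()
        - 2.0 * pol.F[0]
        - pol.F[1:].sum()
        + pol.monomer_return
    )
    return StateVector(c=float(dc), m=dm, v=float(dv), u=du)


def rhs_flat(t: float, y: np.ndarray, rates: RateTable, elongate_with_c: bool = False) -> np.ndarray:
    """Flat-vector right-hand side for the ODE integrator.

    With ``elongate_with_c`` the polymer ladder is driven by the PrP^C
    pool instead of PrP* (the nucleation-dependent comparator run on the
    shared engine); fragment monomers then return to PrP^C as well.
    """
    nm = rates.I_max - 1
    c = y[0]
    v = y[1]
    m = y[2 : 2 + nm]
    u = y[2 + nm :]

    dy = np.empty_like(y)

    # --- micelle ladder (PrP^C in, PrP^C/PrP* out) ---
    J_C = np.empty(nm)
    J_S = np.empty(nm)
    J_C[0] = rates.assoc_C[0] * c * c - rates.deplete_C[0] * m[0]
    J_S[0] = rates.assoc_S[0] * v * v - rates.deplete_S[0] * m[0]
    if nm > 1:
        J_C[1:] = rates.assoc_C[1:] * c * m[:-1] - rates.deplete_C[1:] * m[1:]
        J_S[1:] = rates.assoc_S[1:] * v * m[:-1] - rates.deplete_S[1:] * m[1:]
    J = J_C + J_S
    dm = dy[2 : 2 + nm]
    dm[:-1] = J[:-1] - J[1:]
    dm[-1] = J[-1]

    # --- polymer ladder with fragmentation ---
    w = c if elongate_with_c else v
    nu = u.shape[0]
    F = np.empty(nu)
    F[0] = rates.polym[0] * w * w - rates.depolym[0] * u[0]
    if nu > 1:
        F[1:] = rates.polym[1:] * w * u[:-1] - rates.depolym[1:] * u[1:]
    loss = rates.frag * u
    contrib = 2.0 * loss / (rates.polymer_sizes - 1.0)
    suffix = np.cumsum(contrib[::-1])[::-1]
    du = dy[2 + nm :]
    du[:-1] = F[:-1] - F[1:]
    du[-1] = F[-1]
    du -= loss
    du[: nu - 1] += suffix[1:]
    monomer_return = suffix[0]

    d_elong = -2.0 * F[0] - F[1:].sum() + monomer_return
    dc = -2.0 * J_C[0] - J_C[1:].sum()
    dv = -2.0 * J_S[0] - J_S[1:].sum()
    if elongate_with_c:
        dc += d_elong
    else:
        dv += d_elong
    dy[0] = dc
    dy[1] = dv
    return dy


def boundary_mass_fraction(state: StateVector, width: int = 5) -> tuple[float, float]:
    """Fraction of total mass within ``width`` sizes of each truncation
    boundary (micelle ladder, polymer ladder).  Used to diagnose whether
    the truncation sizes are large enough."""
    tot = total_mass(state)
    if tot == 0:
        return 0.0, 0.0
    mic = float(state.micelle_sizes[-width:] @ state.m[-width:]) / tot
    pol = float(state.polymer_sizes[-width:] @ state.u[-width:]) / tot
    return mic, pol


def warn_if_boundary_heavy(state: StateVector, threshold: float = 0.01, width: int = 5) -> None:
    mic, pol = boundary_mass_fraction(state, width=width)
    if mic > threshold:
        warnings.warn(
            f"{mic:.1%} of total mass sits within {width} sizes of the micelle "
            "truncation boundary; increase I_max",
            RuntimeWarning,
            stacklevel=2,
        )
    if pol > threshold:
        warnings.warn(
            f"{pol:.1%} of total mass sits within {width} sizes of the polymer "
            "truncation boundary; increase N_max",
            RuntimeWarning,
            stacklevel=2,
        )
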