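"""Per-size reaction rates and the binary fragmentation kernel.

Rates are tabulated once per parameter set into a :class:`RateTable`,
indexed by cluster size: micelle rates over ``i = 2..I_max``, polymer
rates over ``j = 2..N_max``.  Depletion (monomer release) laws are
pluggable through a small registry because the spherical-micelle
chemical-potential argument fixes only their asymptotic behaviour:
PrP^C release dominates at small sizes, PrP* release at large sizes and
vanishes at the smallest, where micelles do not transconform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

from .parameters import ConfigurationError, ModelParameters

__all__ = [
    "RateTable",
    "build_rate_table",
    "fragmentation_kernel",
    "register_depletion_law",
    "DEPLETION_LAWS",
]

# A depletion law maps (sizes, q_C, q_S) -> (deplete_C, deplete_S) arrays.
DepletionLaw = Callable[[np.ndarray, float, float], Tuple[np.ndarray, np.ndarray]]

DEPLETION_LAWS: Dict[str, DepletionLaw] = {}


def register_depletion_law(name: str):
    """Register an alternative micelle depletion law under ``name``."""

    def decorator(fn: DepletionLaw) -> DepletionLaw:
        DEPLETION_LAWS[name] = fn
        return fn

    return decorator


@register_depletion_law("surface_power")
def _surface_power(sizes: np.ndarray, q_C: float, q_S: float):
    # i^(-1/3) ~ inverse micelle radius: dominant for small spheres,
    # so it carries the PrP^C release; the complementary part grows with
    # size and carries the PrP* release.
    small = sizes ** (-1.0 / 3.0)
    return q_C * small, q_S * (1.0 - small)


@register_depletion_law("exponential")
def _exponential(sizes: np.ndarray, q_C: float, q_S: float):
    # Chemical-potential-style alternative with the same asymptotics.
    small = np.exp(-((sizes - 1.0) ** (1.0 / 3.0)) / 2.0)
    return q_C * small, q_S * (1.0 - small)


@dataclass(frozen=True)
class RateTable:
    """Size-indexed reaction rates.

    Micelle arrays cover sizes ``2..I_max`` (length ``I_max - 1``),
    polymer arrays cover sizes ``2..N_max`` (length ``N_max - 1``).
    ``assoc_*`` are association rate constants (concentration^-1 h^-1);
    the remaining entries are first-order rates (h^-1).
    """

    assoc_C: np.ndarray
    deplete_C: np.ndarray
    assoc_S: np.ndarray
    deplete_S: np.ndarray
    polym: np.ndarray
    depolym: np.ndarray
    frag: np.ndarray
    n_nucleus: int

    @property
    def I_max(self) -> int:
        return self.deplete_C.shape[0] + 1

    @property
    def N_max(self) -> int:
        return self.polym.shape[0] + 1

    @property
    def micelle_sizes(self) -> np.ndarray:
        return np.arange(2, self.I_max + 1)

    @property
    def polymer_sizes(self) -> np.ndarray:
        return np.arange(2, self.N_max + 1)


def build_rate_table(params: ModelParameters) -> RateTable:
    """Tabulate all per-size rates for ``params``.

    Both monomer isoforms associate to micelles of any size with the same
    constant ``a_mic``.  Depolymerization is ``d_off`` up to the nucleus
    size and zero above it: polymerization is irreversible once the
    nucleus is reached.  Fragmentation is linear in size, ``beta * j``.
    """
    if params.depletion_law not in DEPLETION_LAWS:
        raise ConfigurationError(
            f"unknown depletion law {params.depletion_law!r}; "
            f"registered: {sorted(DEPLETION_LAWS)}"
        )
    i = np.arange(2, params.I_max + 1, dtype=float)
    j = np.arange(2, params.N_max + 1, dtype=float)

    deplete_C, deplete_S = DEPLETION_LAWS[params.depletion_law](i, params.q_C, params.q_S)

    depolym = np.where(j <= params.n_nucleus, params.d_off, 0.0)

    return RateTable(
        assoc_C=np.full_like(i, params.a_mic),
        deplete_C=deplete_C,
        assoc_S=np.full_like(i, params.a_mic),
        deplete_S=deplete_S,
        polym=np.full_like(j, params.tau),
        depolym=depolym,
        frag=params.beta * j,
        n_nucleus=params.n_nucleus,
    )


def fragmentation_kernel(k: int, j: int) -> float:
    """Probability that a polymer of size ``j`` splits at position ``k``.

    The kernel is uniform: each of the ``j - 1`` binary cuts of a
    ``j``-mer is equiprobable, so kappa(k, j) = 1/(j-1) for
    ``1 <= k <= j - 1`` and 0 otherwise.  It is symmetric,
    kappa(k, j) == kappa(j - k, j), and sums to one over ``k``: a
    polymer can only split into two strictly smaller pieces.
    """
    if j < 2:
        raise ValueError(f"fragmentation kernel needs j >= 2, got j={j}")
    if 1 <= k <= j - 1:
        return 1.0 / (j - 1)
    return 0.0
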