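"""Kinetic parameter containers and unit helpers.

The model tracks four populations: PrP^C monomers (``c``), micelles of
``i`` monomers (``m_i``, ``i = 2..I_max``), the amyloid-competent monomer
isoform PrP* (``v``), and PrP* oligomers / PrP^Sc polymers of ``j``
monomers (``u_j``, ``j = 2..N_max``).  All concentrations share one
consistent unit (mg/ml by convention); time is in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = [
    "ModelParameters",
    "BaselineParameters",
    "AVOGADRO",
    "DEFAULT_MOLAR_MASS_KDA",
    "mg_per_ml_to_molar",
    "molar_to_mg_per_ml",
]

#: Default molar mass used by the unit helpers, in kDa.  This is a package
#: default for recombinant PrP 90-231; override it for other constructs.
DEFAULT_MOLAR_MASS_KDA = 16.1

AVOGADRO = 6.022_140_76e23


class ConfigurationError(ValueError):
    """Raised when parameters violate the model's structural constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and truncation sizes for the micelle-dependent model.

    Parameters
    ----------
    a_mic:
        Micelle association rate constant, shared by PrP^C and PrP*
        (both isoforms bind micelles of any size with the same affinity),
        concentration^-1 h^-1.
    q_C:
        PrP^C depletion prefactor: a micelle of size ``i`` releases a
        PrP^C monomer at rate ``q_C * i**(-1/3)`` (dominant for small
        micelles), h^-1.
    q_S:
        PrP* depletion prefactor: a micelle of size ``i`` releases a
        stabilized PrP* monomer at rate ``q_S * (1 - i**(-1/3))``
        (dominant for large micelles; vanishes at the smallest sizes,
        where micelles do not transconform), h^-1.
    tau:
        Polymerization rate constant for PrP* addition to oligomers and
        polymers, concentration^-1 h^-1.
    d_off:
        Depolymerization rate of sub-nucleus oligomers (sizes
        ``2..n_nucleus``); zero beyond the nucleus, where growth is
        irreversible, h^-1.
    n_nucleus:
        Nucleus size ``n``: the smallest thermodynamically stable polymer.
    beta:
        Fragmentation rate per size unit; a polymer of size ``j`` splits
        at rate ``beta * j`` with a uniform binary kernel, h^-1.
    I_max, N_max:
        Truncation sizes of the micelle and polymer ladders.  No-flux
        boundaries keep the truncated system mass-conserving.
    depletion_law:
        Name of a registered depletion rate law (see
        :mod:`micellekin.rates`).
    """

    a_mic: float = 0.1
    q_C: float = 0.06
    q_S: float = 2.0
    tau: float = 6.0
    d_off: float = 0.2
    n_nucleus: int = 4
    beta: float = 0.004
    I_max: int = 3000
    N_max: int = 5000
    depletion_law: str = "surface_power"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("n_nucleus", "I_max", "N_max", "depletion_law"):
                continue
            value = getattr(self, f.name)
            if not value >= 0:
                raise ConfigurationError(f"{f.name} must be >= 0, got {value!r}")
        if self.I_max < 2:
            raise ConfigurationError(f"I_max must be >= 2, got {self.I_max}")
        if not 2 <= self.n_nucleus < self.N_max:
            raise ConfigurationError(
                f"need 2 <= n_nucleus < N_max, got n={self.n_nucleus}, N_max={self.N_max}"
            )

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class BaselineParameters:
    """Parameters of the nucleation-dependent comparator model.

    In the comparator there are no micelles and no conformational step:
    PrP^C monomers polymerize directly, with the same nucleation,
    elongation and fragmentation semantics as the micelle model.
    """

    tau: float = 6.0
    d_off: float = 200.0
    n_nucleus: int = 4
    beta: float = 0.001
    N_max: int = 5000

    def __post_init__(self) -> None:
        for name in ("tau", "d_off", "beta"):
            if not getattr(self, name) >= 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 2 <= self.n_nucleus < self.N_max:
            raise ConfigurationError(
                f"need 2 <= n_nucleus < N_max, got n={self.n_nucleus}, N_max={self.N_max}"
            )

    def replace(self, **changes) -> "BaselineParameters":
        return replace(self, **changes)

    def as_model_parameters(self, I_max: int = 2) -> ModelParameters:
        """Embed the baseline in the full parameter set with the micelle
        pathway switched off (all micelle rates zero)."""
        return ModelParameters(
            a_mic=0.0,
            q_C=0.0,
            q_S=0.0,
            tau=self.tau,
            d_off=self.d_off,
            n_nucleus=self.n_nucleus,
            beta=self.beta,
            I_max=I_max,
            N_max=self.N_max,
        )


def mg_per_ml_to_molar(conc: float, molar_mass_kda: float = DEFAULT_MOLAR_MASS_KDA) -> float:
    """Convert a concentration in mg/ml to mol/l.

    ``molar_mass_kda`` defaults to 16.1 kDa (recombinant PrP 90-231).
    """
    return conc / (molar_mass_kda * 1e3)


def molar_to_mg_per_ml(conc: float, molar_mass_kda: float = DEFAULT_MOLAR_MASS_KDA) -> float:
    """Convert a concentration in mol/l to mg/ml."""
    return conc * molar_mass_kda * 1e3
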