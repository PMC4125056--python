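"""Synthetic-data generators emulating the in vitro measurements.

Three instruments are emulated at desk scale: ThT fluorescence kinetics
(sigmoidal traces acquired in replicate with multiplicative noise),
electron-microscopy micelle diameter measurements (log-normal, mean
around 30 nm), and micelle counts on EM grids over time (Poisson counts
that rise then decay, preceding the polymer half-time).  A geometric
helper estimates how many proteins fit on a micelle's surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .observables import KineticTrace
from .simulate import Trajectory

__all__ = [
    "TraceDesign",
    "MicelleSampleDesign",
    "gen_tht_traces",
    "gen_micelle_diameters",
    "gen_micelle_counts",
    "micelle_protein_count",
]


@dataclass(frozen=True)
class TraceDesign:
    """True sigmoid parameters and acquisition settings of a ThT run.

    The underlying noiseless curve is a logistic sigmoid with plateau
    ``plateau``, midpoint ``t_half`` and maximal slope ``k_max``;
    ``noise`` is the relative (multiplicative Gaussian) noise per point.
    Triplicate acquisition is the default, as in plate-reader protocols.
    """

    plateau: float = 1.0
    t_half: float = 10.0
    k_max: float = 0.25
    noise: float = 0.02
    n_replicates: int = 3
    t_end: float = 30.0
    n_points: int = 121
    baseline: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class MicelleSampleDesign:
    """Design of a synthetic micelle diameter sample (nm)."""

    n: int = 1000
    mean_diameter: float = 30.0
    sigma: float = 0.35
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_diameter <= 0 or self.sigma <= 0:
            raise ValueError("mean_diameter and sigma must be > 0")


def _sigmoid(t: np.ndarray, plateau: float, t_half: float, k_max: float, baseline: float):
    # logistic parameterized by its midpoint and maximal slope
    rate = 4.0 * k_max / plateau
    return baseline + plateau / (1.0 + np.exp(-rate * (t - t_half)))


def gen_tht_traces(design: TraceDesign) -> list[KineticTrace]:
    """Replicate sigmoidal traces with multiplicative Gaussian noise.

    Reproducible for a fixed ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    t = np.linspace(0.0, design.t_end, design.n_points)
    clean = _sigmoid(t, design.plateau, design.t_half, design.k_max, design.baseline)
    traces = []
    for rep in range(design.n_replicates):
        factor = 1.0 + design.noise * rng.standard_normal(t.size)
        traces.append(KineticTrace(times=t, signal=clean * factor, replicate=rep))
    return traces


def gen_micelle_diameters(design: MicelleSampleDesign) -> np.ndarray:
    """Log-normal diameter sample whose distribution mean equals the target.

    The log-mean is set to ``ln(mean) - sigma**2/2`` so that the
    log-normal's expectation is exactly ``mean_diameter``.
    """
    rng = np.random.default_rng(design.seed)
    mu = math.log(design.mean_diameter) - 0.5 * design.sigma**2
    return rng.lognormal(mean=mu, sigma=design.sigma, size=design.n)


def gen_micelle_counts(
    trajectory: Trajectory,
    scale: float,
    *,
    dispersion: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Counting-noise series emulating micelle counts on EM grids.

    Counts at each output time are Poisson with mean
    ``scale * micelle_number(t)`` (grid counts are count data);
    ``dispersion > 1`` switches to a negative binomial with the same
    mean and variance ``dispersion * mean``.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    rng = np.random.default_rng(seed)
    mean = scale * np.clip(trajectory.micelle_number, 0.0, None)
    if dispersion == 1.0:
        return rng.poisson(mean)
    # NB with variance = dispersion * mean: shape r = mean/(dispersion-1)
    r = mean / (dispersion - 1.0)
    p = 1.0 / dispersion
    counts = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    counts[positive] = rng.negative_binomial(r[positive], p)
    return counts


def micelle_protein_count(
    sphere_diameter: float, protein_diameter: float, *, packing_fraction: float = 1.0
) -> int:
    """Number of proteins accommodated on a spherical micelle surface.

    Area-ratio estimate: sphere surface ``pi*D**2`` divided by the
    protein cross-section ``pi*d**2/4``, i.e. ``floor(4*(D/d)**2)``.
    A 30 nm sphere holds about a thousand proteins of ~2 nm diameter.
    ``packing_fraction`` (e.g. 0.9069 for hexagonal packing) scales the
    usable area; the default 1.0 keeps the plain order-of-magnitude
    estimate.
    """
    if sphere_diameter <= 0 or protein_diameter <= 0:
        raise ValueError("diameters must be positive")
    if protein_diameter >= sphere_diameter:
        raise ValueError("protein diameter must be smaller than the sphere diameter")
    return int(math.floor(packing_fraction * 4.0 * (sphere_diameter / protein_diameter) ** 2))
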