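"""Model constants and run-scale parameters.

All quantities are expressed in a dimensionless unit system: lengths in units
of the segment length ``L``, wind speeds in units of the average yearly-maximal
wind ``U0``, and stresses in units of the wood strength ``sigma0``.  The only
place where air density, wind speed and material strength enter is through the
Cauchy number ``C_Y = rho * U0**2 / sigma0``, so none of them appears
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class SimulationParams:
    """Physical and behavioural constants of the simulator.

    Defaults are the reference parameter set used throughout: twigs of
    diameter ``0.1 L``, half-transparent spherical foliages of diameter ``L``,
    a Cauchy number of ``2e-5`` (40 m/s yearly-maximal wind on 100 MPa wood),
    a Weibull modulus of 10 for fracture statistics, and a 100-year return
    period for gusts exceeding ``1.5 U0``.
    """

    L: float = 1.0                      # segment length (reference unit)
    d0: float = 0.1                     # twig diameter [L]
    foliage_diameter: float = 1.0       # [L]
    alpha_fol: float = 0.5              # foliage optical transparency
    C_Y: float = 2e-5                   # Cauchy number rho*U0^2/sigma0
    prod_coeff: float = 4.0             # V_prod = prod_coeff * V0 * l
    e: float = 0.02                     # maintenance (bark) thickness [L]
    S_fol: float = 0.25                 # foliage sail area in strong wind [L^2]
    m: float = 10.0                     # Weibull modulus of wood
    R: float = 40.0                     # island (forest) radius [L]
    p_mut: float = 0.05                 # per-gene mutation probability
    delta_g: float = 0.005              # mutation amplitude
    delta_theta: float = 10.0           # branching-angle jitter s.d. [deg]
    U0: float = 1.0                     # yearly-maximal wind (reference unit)
    gust_factor: float = 1.5            # extreme gust = gust_factor * U0
    return_period: float = 100.0        # years between such gusts
    max_age: int = 1000                 # senescence limit [yr]
    juvenile_age: int = 6               # grace period before the size rule
    min_segments: int = 10              # minimum size after the grace period
    seed_cost_V0: float = 5.0           # seed construction cost [V0]
    initial_reserve_V0: float = 2.0     # reserve of a germinating seed [V0]
    n_sky_angles: int = 32              # solid angles of the sky partition
    n_sky_bands: int = 4                # zenith bands (bands * azimuths = 32)
    n_wind_orientations: int = 8        # azimuths for the felt stress
    nn_gain: float = 5.0                # hidden-layer gain of the growth nets
    # Maintenance-starvation surrogate: a segment that cannot pay its yearly
    # maintenance weakens multiplicatively and is shed once too weak.
    strength_decay: float = 0.5
    strength_recovery: float = 1.25
    shed_threshold: float = 0.05
    central_fraction: float = 0.9       # zone used for allometric statistics
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_fol <= 1.0:
            raise ValueError("alpha_fol must lie in [0, 1]")
        if self.d0 >= self.L:
            raise ValueError("twig diameter must be smaller than L")
        for name in ("L", "d0", "C_Y", "e", "S_fol", "m", "R", "U0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def V0(self) -> float:
        """Twig volume ``pi * L * d0**2 / 4`` [L^3] (~0.0079 L^3)."""
        return math.pi * self.L * self.d0 ** 2 / 4.0

    @property
    def seed_cost(self) -> float:
        return self.seed_cost_V0 * self.V0

    @property
    def initial_reserve(self) -> float:
        return self.initial_reserve_V0 * self.V0

    @property
    def wind_rate(self) -> float:
        """Rate of the exponential yearly-storm-speed distribution.

        Chosen so that ``P(U > gust_factor * U0) = 1 / return_period``.
        """
        return math.log(self.return_period) / (self.gust_factor * self.U0)


@dataclass
class RunConfig:
    """Scale and output controls of a single-island run."""

    params: SimulationParams = field(default_factory=SimulationParams)
    n_initial: int = 2000
    years: int = 300
    genome_file: str | None = None      # None -> uniform random genomes
    snapshot_every: int = 0             # 0 -> no snapshots
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")


@dataclass
class TournamentConfig:
    """Single-elimination tournament over island forests.

    Defaults are a desk-scale toy; the published-scale campaign (32 forests of
    20,000 random genomes, 10,000-year rounds) is obtained by raising the
    knobs.
    """

    params: SimulationParams = field(default_factory=SimulationParams)
    n_forests: int = 4                  # halves every round
    n_initial_first: int = 400          # random genomes in round 1
    n_initial_later: int = 200          # winners sown in later rounds
    n_winners: int = 100                # oldest trees collected per forest
    years_first: int = 60
    years_later: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_winners > self.n_initial_first:
            raise ValueError("winner count cannot exceed the population sown")
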