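"""Closed-form analytical allometry model for wind-safe self-similar trees.

The model assumes three emergent regularities of the simulated forests:
(i) tree skeletons are self-similar with Strahler branching ratio ``R_n`` and
length ratio ``R_l = R_n**(1/D)`` for a fractal dimension ``D``; (ii) the
fractal dimension is about 2.5; (iii) every branch carries the same safety
factor ``S`` against wind-induced fracture, i.e. its relative bending stress
is ``S**(-3/2)``.

A branch of rank ``k`` is fed by ``N_k = R_n**(k-1)`` foliages at mean path
distance ``ell_k = L*(R_l**k - 1)/(R_l - 1) ~ L*R_l**k/(R_l - 1)``, so its
wind-induced relative bending stress is

    sigma_k/sigma0 = (16*alpha/pi) * C_Y * S_fol * N_k * ell_k / d_k**3,

with ``alpha = alpha1*alpha2`` an order-1 geometry factor (mean lever arm,
mean wind-branch inclination).  Setting this to ``S**(-3/2)`` fixes every
diameter, gives the diameter ratio ``R_d = R_n**((D+1)/(3D))``, and yields
allometric exponents that depend on ``D`` only:

    beta_H = 3/(D+1), beta_N = 3D/(D+1),
    beta_B = (2D+5)/(D+1), beta_ML = 3D/(2D+5).

The trunk, always vertical and orthogonal to the wind, is
``alpha2**(-1/3)`` thicker than a randomly oriented rank-1 axis; two
reference diameters are therefore available for the prefactors (see
``prefactors``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass
class AnalyticParams:
    """Constants of the closed-form model (lengths in units of L)."""

    alpha1: float = 0.5      # lever-arm geometry factor
    alpha2: float = 0.5      # wind-inclination geometry factor
    R_n: float = 3.5         # Strahler branching ratio
    D: float = 2.5           # fractal dimension
    S: float = 3.0           # wind safety factor
    S_fol: float = 0.25      # foliage sail area [L^2]
    C_Y: float = 2e-5        # Cauchy number
    L_si: float = 0.1        # segment length [m], for SI conversions
    rho_wood: float = 613.0  # dry wood density [kg m^-3]
    m_fol: float = 0.0018    # dry mass of one foliage [kg]

    def __post_init__(self) -> None:
        if not 1.0 < self.D <= 3.0:
            raise ValueError("D must lie in (1, 3]")
        if self.R_n <= 1.0:
            raise ValueError("R_n must exceed 1")
        if self.S < 1.0:
            raise ValueError("S must be >= 1")

    @property
    def alpha(self) -> float:
        return self.alpha1 * self.alpha2

    @property
    def R_l(self) -> float:
        return self.R_n ** (1.0 / self.D)

    @property
    def R_d(self) -> float:
        return self.R_n ** ((self.D + 1.0) / (3.0 * self.D))


def exponents(D: float) -> tuple[float, float, float, float]:
    """Allometric exponents ``(beta_H, beta_N, beta_B, beta_ML)``.

    At ``D = 2.5`` these round to (0.86, 2.14, 2.86, 0.75); note the identity
    ``beta_ML = beta_N / beta_B``.
    """
    if D <= -1.0:
        raise ValueError("D must exceed -1")
    beta_H = 3.0 / (D + 1.0)
    beta_N = 3.0 * D / (D + 1.0)
    beta_B = (2.0 * D + 5.0) / (D + 1.0)
    beta_ML = 3.0 * D / (2.0 * D + 5.0)
    return beta_H, beta_N, beta_B, beta_ML


def ratios(R_n: float, D: float) -> tuple[float, float, float]:
    """Self-similar ratios ``(R_l, R_d, R_a)`` implied by ``R_n`` and ``D``."""
    if R_n <= 1.0:
        raise ValueError("R_n must exceed 1")
    R_l = R_n ** (1.0 / D)
    R_d = R_n ** ((D + 1.0) / (3.0 * D))
    return R_l, R_d, R_d ** 2


def base_diameters(p: AnalyticParams) -> tuple[float, float]:
    """Rank-1 diameter ``d1`` and trunk-corrected ``d1' = alpha2**(-1/3) d1`` [L].

    ``d1`` solves the constant-safety condition at rank 1:
    ``d1**3 = (16 alpha S^{3/2} / pi) C_Y S_fol R_l / (R_l - 1)``.
    """
    if p.R_l <= 1.0:
        raise ValueError("R_l must exceed 1")
    d1_cubed = (16.0 * p.alpha * p.S ** 1.5 / math.pi) * p.C_Y * p.S_fol \
        * p.R_l / (p.R_l - 1.0)
    d1 = d1_cubed ** (1.0 / 3.0)
    return d1, p.alpha2 ** (-1.0 / 3.0) * d1


def prefactors(p: AnalyticParams,
               reference: str = "d1") -> tuple[float, float, float]:
    """Prefactors ``(c_H, c_N, c_B)`` of the dimensionless allometries.

    ``H = c_H L (d_trunk/L)**beta_H``, ``N = c_N (d_trunk/L)**beta_N``,
    ``B = c_B L^3 (d_trunk/L)**beta_B``.  ``reference`` selects which base
    diameter normalises the trunk diameter: ``"d1"`` (rank-1 axis) or
    ``"d1prime"`` (trunk-corrected).  The two differ by factors
    ``alpha2**(beta/3)``; the defaults with ``"d1"`` give
    ``(37.1, 814, 33.9)``.
    """
    d1, d1p = base_diameters(p)
    d_ref = {"d1": d1, "d1prime": d1p}[reference]
    beta_H, beta_N, beta_B, _ = exponents(p.D)
    R_l, R_d = p.R_l, p.R_d
    if R_d ** 2 * R_l <= p.R_n:
        raise ValueError("divergent biomass sum: R_d^2 R_l must exceed R_n")
    c_H = (R_l / (R_l - 1.0)) * d_ref ** (-beta_H)
    c_N = d_ref ** (-beta_N)
    c_B = (math.pi / 4.0) * d1 ** 2 * R_d ** 2 * R_l \
        / (R_d ** 2 * R_l - p.R_n) * d_ref ** (-beta_B)
    return c_H, c_N, c_B


def biomass_sum(p: AnalyticParams, K: int) -> float:
    """Explicit finite stem-volume sum for a tree of ``K`` Strahler orders [L^3].

    ``B = (pi/4) sum_j R_n**(K-j) d_j**2 l_j`` with ``d_j = d1 R_d**(j-1)``
    and ``l_j = L R_l**(j-1)``; the closed-form prefactor in ``prefactors``
    is its geometric-series limit.
    """
    d1, _ = base_diameters(p)
    total = 0.0
    for j in range(1, K + 1):
        total += p.R_n ** (K - j) * (d1 * p.R_d ** (j - 1)) ** 2 \
            * p.R_l ** (j - 1)
    return math.pi / 4.0 * total


def si_relations(p: AnalyticParams,
                 reference: str = "d1") -> dict[str, tuple[float, float]]:
    """SI-unit allometries as (coefficient, exponent) pairs.

    ``H = a * d_trunk**b`` [m], ``ML_d = a * d_trunk**b`` [kg vs m], and
    ``ML_MS = a * M_S**b`` [kg vs kg] with ``M_S = rho_wood * B`` the stem
    dry mass.  Defaults give ``H ~ 26.7 d**0.857`` and ``ML ~ 202 d**2.14``.
    """
    beta_H, beta_N, beta_B, beta_ML = exponents(p.D)
    c_H, c_N, c_B = prefactors(p, reference)
    L = p.L_si
    a_H = c_H * L ** (1.0 - beta_H)
    a_MLd = p.m_fol * c_N * L ** (-beta_N)
    c_MS = p.rho_wood * c_B * L ** (3.0 - beta_B)
    a_MLMS = p.m_fol * c_N * L ** (-beta_N) * c_MS ** (-beta_N / beta_B)
    return {
        "H_d": (a_H, beta_H),
        "ML_d": (a_MLd, beta_N),
        "ML_MS": (a_MLMS, beta_ML),
    }


def stress_ratio(p: AnalyticParams, k: int) -> float:
    """Relative bending stress ``sigma_k/sigma0`` of a rank-``k`` branch.

    Evaluates the load chain with the self-similar diameters; by
    construction the result is the rank-independent constant ``S**(-3/2)``
    (a closed-loop consistency check of the model).
    """
    d1, _ = base_diameters(p)
    N_k = p.R_n ** (k - 1)
    ell_k = p.R_l ** k / (p.R_l - 1.0)  # geometric-tail path length [L]
    d_k = d1 * p.R_d ** (k - 1)
    return (16.0 * p.alpha / math.pi) * p.C_Y * p.S_fol * N_k * ell_k / d_k ** 3


def sensitivities(p: AnalyticParams,
                  rel_step: float = 1e-6) -> dict[str, dict[str, float]]:
    """Normalised sensitivities of exponents and prefactors to parameters.

    ``s_{q,x} = (x/q) dq/dx`` evaluated at the reference point, with the
    fractal dimension tied to foliage transparency by ``D = 2 + alpha_fol``
    (so transparency acts on the exponents only through ``D``).  Computed by
    central differences of the closed forms.
    """
    alpha_fol_ref = p.D - 2.0

    def _quantities(q: AnalyticParams) -> dict[str, float]:
        beta_H, beta_N, beta_B, beta_ML = exponents(q.D)
        c_H, c_N, c_B = prefactors(q)
        return {"beta_H": beta_H, "beta_N": beta_N, "beta_B": beta_B,
                "beta_ML": beta_ML, "c_H": c_H, "c_N": c_N, "c_B": c_B}

    def _at(alpha_fol=None, C_Y=None) -> dict[str, float]:
        q = p
        if alpha_fol is not None:
            q = replace(q, D=2.0 + alpha_fol)
        if C_Y is not None:
            q = replace(q, C_Y=C_Y)
        return _quantities(q)

    ref = _at()
    out: dict[str, dict[str, float]] = {}
    sweeps = {
        "alpha_fol": (alpha_fol_ref,
                      lambda v: _at(alpha_fol=v)),
        "C_Y": (p.C_Y, lambda v: _at(C_Y=v)),
    }
    for pname, (x0, evaluate) in sweeps.items():
        h = rel_step * x0 if x0 != 0 else rel_step
        hi = evaluate(x0 + h)
        lo = evaluate(x0 - h)
        out[pname] = {
            qname: (x0 / ref[qname]) * (hi[qname] - lo[qname]) / (2.0 * h)
            for qname in ref
        }
    return out


def summary_table(p: AnalyticParams, reference: str = "d1") -> "object":
    """Exponents, ratios and prefactors as a one-row pandas DataFrame."""
    import pandas as pd

    beta_H, beta_N, beta_B, beta_ML = exponents(p.D)
    R_l, R_d, R_a = ratios(p.R_n, p.D)
    d1, d1p = base_diameters(p)
    c_H, c_N, c_B = prefactors(p, reference)
    si = si_relations(p, reference)
    return pd.DataFrame([{
        "beta_H": beta_H, "beta_N": beta_N, "beta_B": beta_B,
        "beta_ML": beta_ML, "R_l": R_l, "R_d": R_d, "R_a": R_a,
        "d1": d1, "d1_prime": d1p, "c_H": c_H, "c_N": c_N, "c_B": c_B,
        "H_si_coeff": si["H_d"][0], "ML_si_coeff": si["ML_d"][0],
        "ML_MS_coeff": si["ML_MS"][0],
    }])
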