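"""Emergent-structure statistics: per-tree summaries, Strahler ratios and
fractal dimension, tapering, area conservation, self-thinning effective
numbers, and weighted RMA/LS log-log fits.

Conventions: crown radius is the 2-D standard deviation
``sqrt(var_x + var_y)`` of the foliage centers projected onto the ground;
leaf mass is taken proportional to the foliage count ``N``; the fractal
dimension is ``D = ln(R_n) / ln(R_l)`` from the Strahler branching and
length ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .architecture import Tree, strahler_orders


@dataclass
class TreeSummary:
    """Macroscopic descriptors of one tree."""

    H: float        # height [L]
    C: float        # crown radius [L]
    N: int          # foliage count
    B: float        # stem volume [L^3]
    d_trunk: float  # [L]
    age: int = 0
    x: float = 0.0
    y: float = 0.0


def tree_summary(tree: Tree, current_year: int | None = None) -> TreeSummary:
    """Height, crown radius, foliage count, stem volume and trunk diameter."""
    if tree.n == 0:
        return TreeSummary(0.0, 0.0, 0, 0.0, 0.0,
                           x=tree.position[0], y=tree.position[1])
    H = float(tree.distal_ends()[:, 2].max())
    centers = tree.foliage_centers()
    if centers.shape[0] > 0:
        C = float(np.sqrt(centers[:, 0].var() + centers[:, 1].var()))
        N = centers.shape[0]
    else:
        C, N = 0.0, 0
    B = float(np.sum(tree.segment_volumes()))
    age = 0 if current_year is None else tree.age(current_year)
    return TreeSummary(H=H, C=C, N=N, B=B, d_trunk=float(tree.col("d")[0]),
                       age=age, x=tree.position[0], y=tree.position[1])


def summaries_frame(trees: list[Tree],
                    current_year: int | None = None) -> pd.DataFrame:
    rows = [tree_summary(t, current_year).__dict__ for t in trees]
    return pd.DataFrame(rows)


# -- Strahler rank statistics -------------------------------------------------

def rank_table(tree: Tree) -> pd.DataFrame:
    """Per-Strahler-rank branch statistics.

    A branch is a maximal run of contiguous equal-rank segments.  Columns:
    ``rank``, branch count ``n``, mean branch length ``l`` [L], mean branch
    diameter ``d`` [L] (per-branch mean of segment diameters), mean branch
    cross-sectional area ``a`` [L^2], and their standard deviations.
    """
    rank, branch = strahler_orders(tree)
    if tree.n == 0:
        return pd.DataFrame(columns=["rank", "n", "l", "d", "a"])
    d = tree.col("d")
    L = tree.params.L
    nb = int(branch.max()) + 1
    seg_count = np.bincount(branch, minlength=nb)
    branch_rank = np.zeros(nb, dtype=np.int64)
    branch_rank[branch] = rank
    mean_d = np.bincount(branch, weights=d, minlength=nb) / seg_count
    mean_a = np.bincount(branch, weights=math.pi * d ** 2 / 4.0,
                         minlength=nb) / seg_count
    length = seg_count * L
    rows = []
    for k in range(1, int(rank.max()) + 1):
        sel = branch_rank == k
        rows.append({
            "rank": k,
            "n": int(sel.sum()),
            "l": float(length[sel].mean()),
            "d": float(mean_d[sel].mean()),
            "a": float(mean_a[sel].mean()),
            "l_std": float(length[sel].std()),
            "d_std": float(mean_d[sel].std()),
        })
    return pd.DataFrame(rows)


@dataclass
class SelfSimilarRatios:
    """Geometric-progression ratios of the Strahler rank statistics."""

    R_n: float
    R_l: float
    R_d: float
    R_a: float
    D: float
    D_ci: tuple[float, float]   # default 80% confidence band
    n_ranks: int


def self_similar_ratios(tree: Tree, max_rank: int = 7,
                        ci_level: float = 0.80) -> SelfSimilarRatios:
    """Branching, length, diameter and area ratios, and fractal dimension.

    Each ratio is the slope of a linear regression of the log quantity
    against rank over the first ``max_rank`` ranks.  ``D = ln R_n / ln R_l``;
    its confidence interval propagates the two slope standard errors
    independently.
    """
    table = rank_table(tree)
    K = min(max_rank, len(table))
    if K < 3:
        raise ValueError("need at least 3 Strahler ranks for ratio fits")
    sub = table.iloc[:K]
    k = sub["rank"].to_numpy(float)

    def _slope(values):
        res = st.linregress(k, np.log(values))
        return res.slope, res.stderr

    s_n, se_n = _slope(sub["n"])
    s_l, se_l = _slope(sub["l"])
    s_d, se_d = _slope(sub["d"])
    s_a, se_a = _slope(sub["a"])
    ln_Rn, ln_Rl = -s_n, s_l
    if ln_Rl <= 0:
        raise ValueError(
            "branch lengths do not increase with rank: D undefined")
    D = ln_Rn / ln_Rl
    var_D = (se_n / ln_Rl) ** 2 + (ln_Rn * se_l / ln_Rl ** 2) ** 2
    z = st.norm.ppf(0.5 + ci_level / 2.0)
    half = z * math.sqrt(var_D)
    return SelfSimilarRatios(
        R_n=math.exp(ln_Rn), R_l=math.exp(ln_Rl), R_d=math.exp(s_d),
        R_a=math.exp(s_a), D=D, D_ci=(D - half, D + half), n_ranks=K,
    )


# -- tapering and area conservation -------------------------------------------

def mean_path_lengths(tree: Tree) -> np.ndarray:
    """Mean distance from each segment to its descendant foliages [L].

    The distance of a path is its number of segments times ``L`` (a twig is
    at distance ``L`` from its own foliage).
    """
    n = tree.n
    parent = tree.col("parent")
    twig = tree.twig_mask()
    L = tree.params.L
    count = np.where(twig, 1.0, 0.0)
    total = np.where(twig, L, 0.0)
    for i in range(n - 1, 0, -1):
        p = parent[i]
        count[p] += count[i]
        total[p] += total[i] + count[i] * L
    return total / count


def tapering_profile(tree: Tree) -> pd.DataFrame:
    """Per-segment pairs (mean foliage distance, diameter) for tapering plots."""
    return pd.DataFrame({
        "mean_path": mean_path_lengths(tree),
        "d": tree.col("d").copy(),
    })


def leonardo_ratios(tree: Tree) -> pd.DataFrame:
    """Cross-sectional area ratio ``(a1 + a2)/a0`` at every two-child node.

    Includes the parent's mean foliage distance, used to restrict averages to
    well-developed nodes.
    """
    parent = tree.col("parent")
    d = tree.col("d")
    ell = mean_path_lengths(tree)
    a = d ** 2  # common pi/4 factor cancels in the ratio
    child_a_sum = np.zeros(tree.n)
    idx = np.flatnonzero(parent >= 0)
    np.add.at(child_a_sum, parent[idx], a[idx])
    nodes = np.flatnonzero(tree.col("nchild") == 2)
    return pd.DataFrame({
        "node": nodes,
        "ratio": child_a_sum[nodes] / a[nodes],
        "mean_path": ell[nodes],
    })


def leonardo_means(tree: Tree,
                   thresholds: tuple[float, ...] = (1.5, 10.0)) -> dict[float, float]:
    """Mean area ratio over nodes whose mean foliage distance exceeds each threshold."""
    df = leonardo_ratios(tree)
    out = {}
    for thr in thresholds:
        sel = df["mean_path"] > thr
        out[thr] = float(df.loc[sel, "ratio"].mean()) if sel.any() else math.nan
    return out


# -- stand statistics ---------------------------------------------------------

def effective_numbers(biomasses: np.ndarray) -> tuple[float, float]:
    """Effective tree number and biomass of a stand.

    ``N_bar = (sum B)^2 / sum B^2`` is the inverse probability that two units
    of mass picked at random come from the same tree; ``M_bar = sum B^2 /
    sum B`` is the biomass-weighted mean biomass.  For ``n`` equal trees of
    mass ``M`` they reduce to ``(n, M)``.
    """
    B = np.asarray(biomasses, dtype=float)
    if B.size == 0:
        raise ValueError("empty biomass list")
    Btot = B.sum()
    B2 = (B ** 2).sum()
    return float(Btot ** 2 / B2), float(B2 / Btot)


# -- log-log regression -------------------------------------------------------

@dataclass
class AllometricFit:
    """A fitted power law ``y = 10**intercept * x**slope`` (log10 space)."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    method: str          # "RMA" or "LS"
    conf_level: float
    n: int
    r2: float

    def contains(self, value: float) -> bool:
        return self.slope_ci[0] <= value <= self.slope_ci[1]


def _weighted_moments(x, y, w):
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    sxx = (w * (x - mx) ** 2).sum() / wsum
    syy = (w * (y - my) ** 2).sum() / wsum
    sxy = (w * (x - mx) * (y - my)).sum() / wsum
    n_eff = wsum ** 2 / (w ** 2).sum()
    return mx, my, sxx, syy, sxy, n_eff


def rma_fit(x, y, w=None, conf_level: float = 0.95,
            log: bool = True) -> AllometricFit:
    """Weighted reduced major axis regression (standard for allometry).

    The slope is ``sign(cov) * SD_y / SD_x`` on (by default) log10-scaled
    data; its standard error uses the usual RMA formula
    ``|b| * sqrt((1 - r^2) / (n_eff - 2))`` with the effective sample size of
    the weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if log:
        x, y = np.log10(x), np.log10(y)
    mx, my, sxx, syy, sxy, n_eff = _weighted_moments(x, y, w)
    slope = math.copysign(math.sqrt(syy / sxx), sxy if sxy != 0 else 1.0)
    r2 = sxy ** 2 / (sxx * syy) if sxx > 0 and syy > 0 else 1.0
    se = abs(slope) * math.sqrt(max(0.0, 1.0 - r2) / max(n_eff - 2.0, 1.0))
    tq = st.t.ppf(0.5 + conf_level / 2.0, max(n_eff - 2.0, 1.0))
    return AllometricFit(
        slope=slope, intercept=my - slope * mx,
        slope_ci=(slope - tq * se, slope + tq * se),
        method="RMA", conf_level=conf_level, n=int(x.size), r2=r2,
    )


def ls_fit(x, y, w=None, conf_level: float = 0.95,
           log: bool = True) -> AllometricFit:
    """Weighted least-squares power-law fit (log10 space), via WLS."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if log:
        x, y = np.log10(x), np.log10(y)
    model = sm.WLS(y, sm.add_constant(x), weights=w)
    res = model.fit()
    ci = res.conf_int(alpha=1.0 - conf_level)
    return AllometricFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        method="LS", conf_level=conf_level, n=int(x.size),
        r2=float(res.rsquared),
    )


def forest_allometry(
    summaries: pd.DataFrame,
    R: float,
    central_fraction: float = 0.9,
    weight: str | None = "N",
    conf_level: float = 0.95,
) -> dict[str, AllometricFit]:
    """RMA fits of H, C, N, B against trunk diameter over a central zone.

    Trees whose trunk lies beyond ``central_fraction * R`` are excluded
    (peripheral trees see less competition and are systematically larger).
    The foliage count ``N`` is the default fit weight.  The derived leaf-mass
    exponent ``beta_ML`` (leaf mass proportional to ``N``, against stem
    biomass) is reported as ``ML`` with slope ``beta_N / beta_B``.
    """
    df = summaries
    r = np.hypot(df["x"].to_numpy(float), df["y"].to_numpy(float))
    sel = (r <= central_fraction * R) & (df["d_trunk"] > 0) & (df["N"] > 0) \
        & (df["H"] > 0) & (df["B"] > 0) & (df["C"] > 0)
    df = df[sel]
    w = df[weight].to_numpy(float) if weight else None
    x = df["d_trunk"].to_numpy(float)
    fits = {}
    for col in ("H", "C", "N", "B"):
        fits[col] = rma_fit(x, df[col].to_numpy(float), w,
                            conf_level=conf_level)
    bn, bb = fits["N"].slope, fits["B"].slope
    bml = bn / bb if bb != 0 else math.nan
    fits["ML"] = AllometricFit(
        slope=bml, intercept=fits["N"].intercept - bml * fits["B"].intercept,
        slope_ci=(bml, bml), method="derived",
        conf_level=conf_level, n=fits["N"].n, r2=math.nan,
    )
    return fits


def self_thinning_fit(N_bar, M_bar, w=None,
                      conf_level: float = 0.95) -> AllometricFit:
    """Pooled log-log fit of effective biomass against effective number.

    Weighted least squares with ``N_bar`` as the default weight; the slope is
    the self-thinning exponent ``beta_ST`` (about -3/2 empirically).
    """
    N_bar = np.asarray(N_bar, dtype=float)
    M_bar = np.asarray(M_bar, dtype=float)
    if N_bar.size < 3:
        raise ValueError("need at least 3 time points")
    if np.allclose(N_bar, N_bar[0]):
        raise ValueError("degenerate series: constant N_bar")
    w = N_bar if w is None else np.asarray(w, dtype=float)
    return ls_fit(N_bar, M_bar, w, conf_level=conf_level)


def sensitivity(p_values, beta_values,
                p_ref: float | None = None,
                beta_ref: float | None = None) -> float:
    """Normalised sensitivity ``s = (p / beta) * d beta / d p`` at a reference.

    The derivative is the slope of a linear regression of ``beta`` on the
    swept parameter values; the reference defaults to the sweep midpoint.
    """
    p_values = np.asarray(p_values, dtype=float)
    beta_values = np.asarray(beta_values, dtype=float)
    if p_values.size < 2:
        raise ValueError("need at least 2 sweep points")
    slope = st.linregress(p_values, beta_values).slope
    if p_ref is None:
        p_ref = float(p_values.mean())
    if beta_ref is None:
        beta_ref = float(np.interp(p_ref, p_values, beta_values))
    return (p_ref / beta_ref) * slope
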