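# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, numerical conventions, the deliberately open design
choices and their rationale, what the synthetic generators emulate, and known
limitations.

## Units and scope

Everything is dimensionless: lengths in the segment length `L`, wind speeds
in the average yearly maximum `U0`, stresses in the wood strength `sigma0`.
Air density, `U0` and `sigma0` enter only through the Cauchy number
`C_Y = rho U0^2 / sigma0` (default `2e-5`, i.e. ~40 m/s winds on ~100 MPa
wood), so fracture statistics are independent of absolute tree size.
Hydraulics (transport costs, embolism) is deliberately outside the model:
the point is to ask how much of tree form follows from light competition and
wind safety alone.  Gravity loads, curved segments and root systems are also
out of scope.

## Structure

Trees are at-most-binary assemblies of cylinders of fixed length `L`;
diameters start at `d0 = 0.1 L` and only ever grow.  Segments are stored
struct-of-arrays in creation order, so every child has a larger index than
its parent; all topological passes (Strahler ranks, subtree sums, load
propagation) are level-by-depth array sweeps that rely on this ordering.
Forests concatenate the per-tree arrays once per year and run every
per-segment pass on the whole island at once; this is what makes
500-year/2,000-tree islands run in a couple of minutes on one core.

Branching frames follow the two-angle-plus-torsion rule: child axes rotate
the parent axis by `theta1` and `theta2` about the branching-plane normal
`b`, and the child normals rotate `b` about each child axis by `gamma`; each
angle is jittered by an independent standard-normal draw times
`delta_theta = 10 deg`.  All rotations are right-handed about the given
axis (the source material fixes no sign convention; one is chosen and used
everywhere).  The three angle genes map affinely to `theta1 in [0, 90]`,
`theta2 in [-90, 0]`, `gamma in [0, 180]` degrees — ranges chosen so a
branching event forks around the parent axis; the gene-to-angle map is a
package choice, as no ranges are prescribed by the model definition.

## Growth networks

Both growth policies are 3-layer perceptrons with three hidden `tanh(5x)`
neurons plus a bias unit, their weights mapped affinely from genes in
`[0, 1]` to `[-1, 1]`.  Three things are open in the model definition and
fixed here as package choices:

- **Input scaling** ("of order 1"): primary inputs are
  `log10(1 + V_res/V0)/3` and `log10(1 + N_fol)/3`; the secondary inputs are
  the felt stress `sigma_max/sigma0` clipped to `[0, 2]` and
  `log10(1 + N_fol_above)/3`.  Logarithmic compression keeps the inputs
  order-1 over the four decades a tree can span.
- **Primary-output squashing**: the allocation fractions are
  `softmax(z1, z2, 0)`, which guarantees `P_seg + P_seed <= 1` and is
  neutral (1/3, 1/3) at zero weights; photosensitivity is
  `p = (1 + tanh z3)/2`.
- **Secondary-output squashing**: `S = 1 + 5 (1 + tanh z)/2 in [1, 6]`,
  whose midpoint 3.5 brackets the safety factors (roughly 2.5–4) that
  evolved populations settle on.

Mutation changes each gene independently with probability 0.05 by a normal
step of amplitude 0.005, clamped to `[0, 1]`; markers mutate like any other
gene but never feed the dynamics.

## Light

The sky is divided into 32 equal solid angles: 4 zenith bands with
cos-zenith boundaries (1, 3/4, 1/2, 1/4, 0) times 8 azimuth sectors, each
cell represented by its normalised direction centroid and carrying 1/32 of
full light.  Per direction the scene is rotated so the cell direction maps
to +z, foliage centers are binned by `floor((x, y)/L)` with a fixed origin
and no jitter, and the k-th foliage from the top of a column receives
`(1/32) alpha_fol^k`.  Ties in height break by foliage index for
determinism.  Segments cast no shadow.  The cell geometry of the partition
is not prescribed beyond "32 equal solid angles"; the band-by-azimuth
partition is exposed in `sky_directions` so alternatives can be swapped in.

## Mechanics

Foliage drag is `(1/2) C_Y (U/U0)^2 S_fol` along the wind at the foliage
center (drag coefficient 1, sail area `S_fol = 0.25 L^2`); segment drag is
`(1/2) C_Y (U/U0)^2 d L ||t x u||^2` perpendicular to the segment in the
wind plane, applied at the midpoint.  Base loads follow the cantilever
transmission rule (children's base forces and moments plus the lever term
`L t x F_top`), evaluated as a leaf-to-root level sweep and verified against
brute-force subtree summation to 1e-12.  The felt stress for
thigmomorphogenesis uses `U = U0` and the maximum over 8 fixed azimuths;
sampling every 45 degrees undersamples the azimuthal stress peak by at most
~9% on random architectures (measured; an exact sweep is available by
passing more azimuths).

Storms draw one speed per year from an exponential distribution whose rate
`ln(100)/(1.5 U0)` puts the 100-year return level at `1.5 U0`, with uniform
azimuth.  Each segment fractures independently with the Weibull probability
`1 - exp[-(V/V0)(sigma/(sigma0 * strength))^10]`; stresses are not
recomputed after partial breakage within a storm, and the root-most break
removes the subtree.

**Maintenance weakening** is a one-variable surrogate (no law is prescribed
in the model definition): a segment that pays only a fraction `f < 1` of its
maintenance multiplies its strength factor by `0.5 + 0.5 f`; full payment
multiplies it by 1.25 (capped at 1); below 0.05 the branch falls in the next
storm regardless of load.  Five fully starved years therefore shed a branch
(`0.5^5 ~ 0.03`).

## Carbon economy

Per segment, the yearly sink is the growth need
`max(0, S * V_fract - V)` — where `V_fract = V * (sigma_max/sigma0)^(2/3)`
is the volume at which the felt stress reaches the strength, so a segment
that reaches its target carries `sigma/sigma0 = S^(-3/2)` — plus maintenance
`pi L d e` with `e = 0.02 L`.  The sink is requested in equal shares from
every foliage above; foliages produce `4 V0 l`, pay requests (pro rata when
short), and bank leftovers in the reserve.  Received carbon pays maintenance
first, the remainder thickens the segment.  The yearly identity

```
production = maintenance paid + diameter growth + reserve deposit
```

holds to 1e-12 relative (it is checked every year of a 50-tree fixture
forest in the tests).  Reserve filled in the secondary phase of a year is
spendable in the primary phase of the same cycle, which realises
"assimilates mobilised the following season" through the in-year step order.

Primary growth builds `floor(P_seg V_res / V0)` segments (children in pairs
per selected twig, odd remainder single) and `floor(P_seed V_res / 5 V0)`
seeds (cost `5 V0` each: initial reserve `2 V0`, first sprout `V0`,
dissemination `2 V0`).  Twig selection interpolates photosensitivity: each
slot takes the best-lit unused twig with probability `p`, else a uniform
unused one — matching both stated endpoints.  If the budget exceeds twice
the number of twigs, only the affordable branchings happen and the unused
budget remains in the reserve.  Seeds disperse at 45 degrees (horizontal
range = release height, uniform azimuth); the island absorbs nothing from
outside and seeds crossing the boundary are lost.

## The yearly cycle and populations

Steps run strictly in the order light → felt stress → secondary growth (and
weakening) → storm → death → primary growth → reproduction, on one shared
random stream with fixed draw order; identical configuration and seed give
bit-identical logs.  Death removes trees older than 1000 years and trees
older than 6 years with fewer than 10 segments.  "Species" is
operationalised as the founding lineage (the marker genes are kept for
colouring only); the species count is the number of distinct living
lineages.

The tournament driver implements single elimination between islands —
random genomes in round 1, merged winner pools (the oldest living trees,
ties by id) sowing the halved number of islands in later rounds.  Default
scales are desk presets (4 islands of 400 trees); the published-scale
campaign (32 islands of 20,000 genomes, 10,000-year rounds) is the same
code with larger knobs and is cluster work, not part of the test suite.

## Analysis conventions

- Height is the highest distal end; crown radius is
  `sqrt(var_x + var_y)` of the foliage centers' ground projection (one of
  several possible 2-D reductions of "standard deviation of the projected
  foliage distribution"); stem volume is the sum of segment cylinders; leaf
  mass is taken proportional to foliage count `N`.
- A branch is a maximal run of equal-Strahler-rank segments; per rank we
  report branch count, mean length, mean diameter and mean area.  The
  self-similar ratios are slopes of log-quantity vs rank over the first 7
  ranks; `D = ln R_n / ln R_l` with an 80% CI from independent propagation
  of the two slope errors.  Trees whose branch lengths do not increase with
  rank have no defined `D` and are flagged.
- Allometric fits are weighted reduced-major-axis regressions on log10 data
  (slope `sign(cov) * SD_y/SD_x`, standard error
  `|b| sqrt((1-r^2)/(n_eff-2))` with the weights' effective sample size);
  least-squares fits go through statsmodels WLS.  Forest fits use foliage
  count as weight and only trees whose trunk lies within `0.9 R`
  (peripheral trees are systematically larger).  Self-thinning is a pooled
  WLS fit of `log M_bar` vs `log N_bar` with `N_bar` weights, where
  `N_bar = (sum B)^2 / sum B^2` and `M_bar = sum B^2 / sum B`.

## Synthetic generators and what the tests show

`synthetic.random_tree` grows topology/geometry fixtures with random angles
and optional log-normal diameter jitter; it has no carbon economy, so it
exercises topology, mechanics and statistics code, not growth dynamics.
`synthetic.self_similar_tree` builds skeletons with exactly integer Strahler
ratios for oracle checks of the ratio fits.  `synthetic.analytic_cohort`
draws tree summaries from the closed-form allometries with independent
multiplicative log-normal scatter (sigma 0.1 in natural log) on every
observed quantity — the errors-in-all-variables situation RMA regression is
built for — over three decades of trunk diameter.  Recovery tests on such
cohorts demonstrate that the fitting machinery is unbiased enough at
n = 1000; they say nothing about whether real (or simulated) forests follow
the closed forms, which is what the island runs probe.

The emergent-ecology tests pool an ensemble of 4 independent islands
(2,000 random genomes, `R = 40 L`, 500 years, seeds 0–3) because tree-level
statistics on a single small island rest on a handful of surviving
lineages.  "Mature" trees are those with at least 6 Strahler ranks, the
least size for which the 7-rank ratio fits are meaningful.  Branch aspect
`l_k/d_k` is summarised per tree by its geometric mean across the fitted
ranks — ratios are treated in log space throughout this analysis.  After
only 500 years selection is rudimentary: safety factors sit near the lower
edge of the published range, and the fitted height exponents on small islands
run slightly high, consistent with the curvilinearity of log H vs log d for
young stands.

## Closed-form model

`analytic` implements the self-similar, constant-safety skeleton model.
Two reference diameters exist: the rank-1 axis diameter `d1` (0.0437 L at
the defaults) and the trunk-corrected `d1' = alpha2^(-1/3) d1` (0.0552 L;
the trunk is always vertical and orthogonal to the wind).  The printed
reference prefactors (37.1, 814, 33.9; SI 26.7 and 202) are reproduced with
`d1` as the normalising diameter, so `reference="d1"` is the default; both
are available because the defining relations can be written with either.
The biomass prefactor is the geometric-series limit of the explicit rank
sum; the finite sum differs from the limit by `(R_n/(R_d^2 R_l))^K` —
about 0.7% at K = 12 — and both forms are exposed.  The leaf-vs-stem-mass
SI coefficient computed from the stated constants is ~0.152, not the 0.124
sometimes quoted alongside these relations; it is therefore treated as a
qualitative quantity here.  Sensitivities `s = (p/q) dq/dp` are central
differences of the closed forms with the fractal dimension tied to foliage
transparency by `D = 2 + alpha_fol`, the empirical relation between canopy
openness and space filling.

## Known limitations

- One storm per year and a single uniform wind profile; no resonant
  dynamics, no within-canopy shelter, no drag reconfiguration.
- The weakening/recovery constants (0.5, 1.25, 0.05) are surrogates; they
  set the ~5-year shedding time scale but were not calibrated to data.
- Desk-scale islands (`R = 40 L` and below) select a periphery-adapted
  strategy; interior/periphery niche coexistence needs the full-size
  islands.
- The 8-azimuth felt stress can miss the true azimuthal peak by up to ~9%.
- Allometric exponents from short runs are biased by young, non-self-similar
  trees; the closed-form comparisons are only meaningful for mature stands.
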