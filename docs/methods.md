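# Methods

This note records the models behind each stage, the defaults and why they
were chosen, the numerical choices, and what the synthetic world does and
does not emulate.

## Chronograms and tree statistics

A chronogram is held with explicit node ages (Ma before present); edge
lengths are derived from ages on write. Ages are computed from root-to-tip
depths on read, tips are snapped to age 0, and ultrametricity is enforced
within a relative tolerance (default 1e-4 of the crown age — dated trees
from external pipelines carry rounding noise; the error names the worst
offending tip).

**Species age** defaults to the age of the tip's parent node (the tip's
stem age, equal to its terminal branch length for present-day tips); an
alternative — the crown age of the smallest labeled clade containing the
tip — is available via `tip_species_ages(..., method="labeled_clade")`.

**DR statistic.** For tip i with root-to-tip edge lengths l_1 (terminal) …
l_N, ES_i = Σ_j l_j 2^−(j−1) and DR_i = 1/ES_i (species/Ma). Each edge on
the path contributes once regardless of node degree, so multifurcations are
tolerated.

**Clade-constrained augmentation.** Unsampled species assigned to a named
(monophyletic) clade are grafted sequentially in sorted-name order: a
branch is drawn uniformly among all branches strictly inside the clade
(the clade's stem edge excluded; branches created by earlier grafts are
eligible), and the attachment time uniformly along that branch. Uniform-
on-branches is the least-informative reading of "random addition"; the
alternative (uniform over time slices) would weight recent, branch-rich
intervals more heavily. Existing node ages are never touched, so all
pre-existing pairwise divergence times are preserved exactly and the tree
stays ultrametric by construction.

## Brownian-motion ancestral states

Each thermal-niche variable (MAT, MTWM, MTDQ — species means over cleaned,
in-extent records) is reconstructed independently under univariate BM. The
implementation is the two-pass peeling algorithm: an upward pass folds tip
values into per-node conditional means and variances (the independent-
contrasts recursion, with multifurcations folded child by child), a
downward pass combines each node's subtree message with the message from
the rest of the tree. This is algebraically identical to GLS with the BM
covariance matrix C (C_ij = shared root-to-MRCA path length): the root
estimate is â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x, and the test suite checks every node
against an independently coded dense-matrix oracle.

The BM rate is the full ML estimate σ̂² = Q/n (Q the GLS residual quadratic
form, accumulated as the sum of squared standardized contrasts), matching
the convention of the standard fast reconstruction functions. For the
**root interval**, however, the package uses the exact finite-sample form:
under BM the pivot (â − a)/√(Q/(n−1)·h) with h = (1ᵀC⁻¹1)⁻¹ is exactly
t-distributed with n−1 degrees of freedom, so the 95% interval uses
Q/(n−1) and a t quantile. The normal-quantile/ML-rate interval is slightly
anticonservative (~94% realized coverage at n = 64); the t form is exact
for every tree, which the suite verifies both by coverage and by a
Kolmogorov–Smirnov test of the pivot.

The "ancestral niche" consumed downstream is the root state of each
variable; per-node states and variances are written for diagnostics.

## Paleotemperature-dependent birth–death models

Rates are deterministic functions of a paleotemperature curve T(t)
(piecewise-linear interpolation of (age, °C) samples, clamped at the
endpoints): constant λ0; linear max(0, λ0 + α·T(t)); or exponential
λ0·e^{α·T(t)}. The default registry of seven models is
{λ const, μ=0}, {λ const, μ const}, {λ lin, μ=0}, {λ exp, μ=0},
{λ lin, μ const}, {λ exp, μ const}, {λ exp, μ exp} — a reconstruction
spanning the constant/linear/exponential families for both rates; it is
configurable.

**Likelihood.** With t measured backward from the present and sampling
fraction f, E(t) solves E′ = μ − (λ+μ)E + λE², E(0) = 1 − f. The branch
equation D′ = −(λ+μ)D + 2λED is linear in D, so branch factors telescope
through I(t) = ∫₀ᵗ (λ+μ−2λE); E and I are obtained from a single adaptive
solve (LSODA, reporting tolerances rtol 1e-10 / atol 1e-12) with dense
output evaluated at all node ages. The crown-conditioned log-likelihood is

    logL = n log f − Σ_edges [I(t_parent) − I(t_child)]
           + Σ_internal (k_children − 1) log λ(t_node) − 2 log(1 − E(t_c)),

i.e. n−1 speciation factors including the crown node, divided by
(1 − E(t_c))² for the survival of both crown lineages. Stem conditioning
and the no-root-λ variant are available behind flags. Degenerate inputs
raise: λ identically zero, E leaving [0,1], total rate above 1e3/Ma
(unphysical and needlessly stiff), or E reaching 1 before the crown
(survival impossible; detected by an ODE event). For f = 1, μ = 0,
constant λ the expression collapses to (n−1)log λ − λ·L_tot exactly, and
for constant rates it matches the classical closed form — both are test
oracles.

**Fitting and selection.** Bounded L-BFGS-B on the free parameters
(λ0, μ0 ≥ 0 by bounds), multi-start with a moment heuristic
(λ0 = (n−1)/L_tot, α = 0, μ0 = λ0/10) plus seeded jitter; failed
evaluations return a large finite penalty so numerical gradients stay
usable; the search runs at relaxed ODE tolerance and the final logL is
re-evaluated at the tight one. AICc uses n = number of branching times
(n_tips − 1; configurable to n_tips) and k = estimated parameters only
(f is always fixed by the user).

The default temperature-dependence bounds are α ∈ [−0.3, 0.3] per °C — an
e-folding of the rate every 3.3 °C at the edge, wider than any plausible
empirical response. This window is a modelling decision, not a numerical
convenience: with α unbounded the optimizer reliably climbs the
high-turnover ridge of time-varying birth–death models (λ(t) and μ(t)
exploding jointly into the past with α_λ ≈ α_μ at the bound), a
manifestation of the family's well-documented non-identifiability that
yields large but meaningless likelihood gains on any tree, including trees
simulated under constant rates. The likelihood itself is exact in that
region (verified against the constant-rate closed form at high turnover);
the restriction is on what counts as an interpretable model. Optima pinned
to a box edge are flagged `converged=False`. Bounds are overridable per
fit.

## Occurrence QC

Filters apply in a fixed order and a record's flag is the first filter it
triggers: (1) missing/unparseable/out-of-bounds coordinates; (2) latitude
exactly equal to longitude, excluding the origin; (3) a zero coordinate,
or both coordinates integer-valued ("either-zero-or-both-integer", the
common cleaning practice; an "any integer" variant is available); (4) not
covered by the land mask; (5) outside the species' native-range polygon
(skipped with a log note when no polygon is known). The origin (0, 0) is
deliberately owned by filter 3, not filter 2: both coordinates zero is a
zero-coordinate artifact, not an equal-coordinate transposition. Boundary
points count as inside polygons (closed polygons, `covers` semantics).
Total removal is order-invariant (a record is removed iff any enabled
filter triggers); only the flag attribution depends on the canonical
order. Cleaning is idempotent.

**Variable selection** prunes greedily: while any pair has |r| ≥ 0.75, the
member of the worst pair with the larger mean |r| against all other
variables is dropped (ties toward the later column); zero-variance columns
are dropped first with a warning. A PCA on standardized retained columns
reports variance fractions and per-variable contributions (squared
loadings weighted by the PC1–PC2 explained variances). In the bundled
synthetic world the three temperature surfaces differ by exact constants
(r = 1 by construction), so the pruning step is exercised by dedicated
fixtures rather than wired between extraction and reconstruction in the
default pipeline, which needs all three variables downstream.

## Spatial pattern

The grid lives in a cylindrical equal-area projection with standard
parallel 30° (Behrmann; authalic radius 6 371 007.181 m):
x = R cos30°·λ, y = R sinφ/cos30°. Cells are 100 km × 100 km, half-open on
both axes, anchored at the projection origin. Cell counts are projection-
and origin-dependent, so no attempt is made to match any particular
published cell total; the projection is configurable.

Per cell: richness = distinct species with ≥1 record; evolutionary time =
the oldest species age among them; mean DR = their unweighted mean tip DR
(each species once, however many records it has); present climate = the
record-level mean of extracted values (a raster-pixel mean would weight
area rather than sampling; record-mean matches how species niches are
summarized). Species present in the occurrences but absent from the tree
count toward richness and are excluded from the age/DR aggregates, with a
log note — upstream clade-constrained augmentation is the intended way to
avoid this. Deviation: Δ_v = |present mean − ancestral root state| per
variable, min–max normalized across all listed cells (a constant column
normalizes to zero), summed to a score in [0, 3].

Latitudinal trends use a hand-rolled LOESS — local polynomial fits with
tricube weights, span 0.75 and degree 2 by default — because the available
library smoother is restricted to local-linear fits. The smoother
reproduces constants exactly; windows with too few distinct abscissae
reduce the polynomial degree automatically; empty latitude bands are
reported as missing, never zero.

## Synthetic world

The generator produces the study conditions the pipeline assumes, with
ground truth recorded for every object:

- **Chronograms**: forward birth–death simulation from two crown lineages,
  time-inhomogeneous rates handled by thinning against a grid bound
  (4097-point maximum of λ+μ inflated 5%), conditioned — like the
  likelihood — on both crown lineages surviving, and retried until a
  minimum tip count (bounded retries; the attempt count is recorded).
  Default conditions: crown age 37.44 Ma; exponential temperature forcing
  λ0 = 0.16/Ma, α = −0.055 per °C on a linear cooling curve (2 °C at
  present, +0.2 °C/Ma into the past); μ0 = 0. These give diversification
  accelerating as the world cools and ~100–400 surviving species.
- **Niches**: one BM trait per species (root 6.66 °C, σ² = 1 °C²/Ma) used
  as the MAT optimum.
- **Climate**: MAT(lat) = 27 − 0.55·|lat| + N(0, 0.5²) per cell;
  MTWM = MAT + 8; MTDQ = MAT − 10 (exact offsets, so the three surfaces
  satisfy MTWM ≥ MAT ≥ MTDQ everywhere by construction).
- **Occurrences**: each species is centered on the northern-hemisphere
  latitude band whose mean MAT best matches its optimum, at a random
  on-land longitude, with a rectangular range polygon; records scatter
  with 3° Gaussian jitter, rejection-sampled onto land, inside the range,
  and clear of the QC filters. A fraction (default 0.1) is corrupted by
  one of the five mechanisms matching the filters, with the mechanism
  recorded per record.
- **Geography**: two rectangular continents; everything else is sea.

Problem sizes in the tests and the acceptance script (tens to a few
hundred species, tens of records per species, 1° climate cells) are the
package's chosen desk-scale study conditions; all statistical checks are
sized to them. What the world does *not* emulate — real coastlines and
topography, spatial sampling bias, dispersal limitation beyond the range
polygons, niche evolution other than BM, correlated climate variables —
bounds what passing tests show: they validate the estimators and the
pipeline plumbing, not the biology of any real clade.

## Determinism

One master seed derives per-stage seeds (affine map, kept below 2³¹);
every stochastic routine takes an explicit seed; outputs carry no
timestamps. Two runs with the same config and seed are byte-identical,
which the suite asserts by hashing every product.

## Known limitations

- The birth–death simulator's thinning bound is a grid maximum with a 5%
  safety margin; a rate function oscillating faster than the 4097-point
  grid could in principle exceed it (the bundled forms are monotone
  transforms of a piecewise-linear curve and cannot).
- Temperature-dependent model fits are only as identifiable as the data
  allow; the α window above is a guardrail, not a cure, and bound-pinned
  fits should be treated as unreliable.
- LOESS profiles are evaluated on the observed latitude range only; no
  extrapolation.
- The native-range filter depends entirely on the supplied polygons; with
  none it silently (but loggedly) passes records through.
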