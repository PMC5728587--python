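# Methods

## The model

A microbial range expansion leaves a frozen record of its genetic
competition: once the population becomes locally monoclonal at an initial
radius `R0`, the frontier consists of sectors separated by domain walls.
`sectorwalk` reduces the frontier to those walls — annihilating and
coalescing random walkers on a ring — and models everything downstream of
`R0`.

One Monte-Carlo move:

1. pick one of the `N` walls uniformly at random;
2. hop it one cell width `a` to the right with probability
   `(1 + r_ij)/2`, else left, where `r_ij` is the antisymmetric bias of
   the wall's type (strain `i` on the left, `j` on the right);
3. if the hop reaches or crosses the nearest wall in the hop direction,
   the two walls react instantly at that wall's position: they
   *annihilate* (both removed) when the outer flanking strains match and
   *coalesce* (single wall joining the outer flanks) when they differ;
4. advance time by `1/N` generations and the length expanded by `d/N`,
   where `d` is the length the colony expands per generation.

In radial geometry the ring inflates, `R = R0 + d t` with `L = R − R0`,
and the angular hop is `δφ = a/R`; in linear geometry `R = R0` forever.
Walls are off-lattice: positions are continuous reals in `[0, 2π)`.

The microscopic parameters map onto the coarse-grained ones as

    Dw = a² / (2 d)        wall diffusion constant per length expanded
    vw_ij = a r_ij / d     deterministic wall velocity per length expanded

and the initial radius is fixed by the cell count, `R0 = N0 a / (2π)`.

Three derived combinations control the dynamics:

    Ls = Dw / vw²                selection length scale
    κ  = sqrt(R0 / Ls)           inflationary selection strength
    φc = sqrt(8 Dw / R0)         angular correlation length of neutral domains

Observables collapse under `L → L/Ls`, `φ → φ/φc` at fixed κ; the fitting
layer exploits this to compare one observed correlation function against a
cache of simulated universal curves, one per candidate κ.

## Assumptions

* Wall motion is diffusive with a single constant `Dw` for all wall types.
  Real colony boundaries can wander super-diffusively; the diffusive
  approximation is adopted because it fits the ensemble statistics well.
* A common chiral drift of all walls is ignored: sector *widths*, which is
  what every estimator here uses, are unaffected by a uniform drift.
* No new mutations, no interactions beyond expansion-velocity differences.
* The frontier is one-dimensional; no attempt is made to represent the
  colony interior or its height profile.

## Numerical choices

* **Collision tolerance.** A hop "reaches" its neighbour when the gap is
  at most `δφ (1 + 1e-9)`.  The relative tolerance matters: the initial
  cells sit on a lattice whose spacing exactly equals the hop length, so
  contact would otherwise be missed by one ulp of floating-point rounding.
  Genuine gaps are never within `1e-9 δφ` of a tie except through that
  lattice effect.
* **Radius update.** `R` advances by `d/N` per hop (continuously with
  `t`), and `δφ` uses the pre-hop radius.  The alternative, advancing `R`
  once per whole generation, differs by `O(1/N)` and vanishes for large
  `N0`.
* **Two inoculation modes.** `iid` (default) draws each founder cell's
  label independently from the inoculated fractions, reproducing the
  stochastic spread of initial compositions of a well-mixed droplet;
  `exact` places `round(N0 f_i)` cells of each strain (largest-remainder
  rounding) in uniform random order.
* **Ensembles.** Replicate generators are spawned from one
  `SeedSequence`, so results are reproducible bit for bit and independent
  of execution order.  Two code paths exist — a compiled kernel and a
  plain-Python single-hop reference — compiled from the same conventions
  and cross-checked statistically in the tests.
* **Angular integrals** are exact sums over a uniform grid (default 500
  bins); occupancies are rasterised exactly from wall positions, never
  point-sampled.  Correlation functions are circular FFT correlations of
  the binned fields.
* **ΔP regression.** The annihilation asymmetry is the least-squares slope
  through the origin of mean cumulative `A − C` against mean cumulative
  `A + C`, discarding the first 5% of collisions as burn-in; the SE is a
  between-replicate bootstrap.  The exact window the original measurement
  used is not specified anywhere; this default is a documented choice.
* **Crossover solver.** The transcendental balance
  `κ ln(1 + x) = sqrt(1 − 1/(1+x))` (`x = L_I/R0`) is solved by Brent's
  method on `[1e-9, max(1e3, 10 e^{1/κ})]`; the bracket covers the
  `κ² e^{1/κ}` blow-up at small κ and the residual is below `1e-10` over
  `κ ∈ [1e-2, 1e3]`.
* **Ls fit uncertainty.** Candidate `Ls` values are scored by
  inverse-variance-weighted SSE; each candidate receives probability
  proportional to `1/WSSE` and the interval is the 2.5–97.5% range of
  that normalised distribution.  This deliberately follows the stated
  measurement convention rather than a χ² likelihood; it is a
  non-standard uncertainty rule and its intervals are typically wide with
  a long upper tail in `Ls`.
* **Fitted component.** The cross-correlation between the competing pair
  is fit by default: cross-correlations detect fitness differences more
  reliably than self-correlations.

## What the synthetic data emulate — and what they do not

The fixture generator produces local-fraction fields `f_i(φ, L)` on a
polar grid by running the simulator at a stated truth and rasterising each
snapshot, plus single-sector boundary traces.  An optional *overlap blur*
emulates the one segmentation artifact that matters for the
heterozygosity-based fit: where fluorescence masks overlap at a domain
boundary, the local fraction is split equally among the overlapping
strains, so `H(φ=0)` fails to vanish and the artifact weakens as domains
coarsen.  Nothing else about imaging is emulated — no illumination
gradients, no stitching seams, no segmentation errors in sector interiors,
no super-diffusive wandering.  Passing recovery tests on these fixtures
therefore demonstrates correctness of the estimators under the model's own
assumptions plus the boundary-overlap artifact, not robustness to every
real imaging pathology.

## Problem sizes

Default study conditions used by the tests and the acceptance script,
chosen to resolve each effect with comfortable Monte-Carlo headroom:

* annihilation asymmetry: `N0 = 2000`, 300 replicates (equal fractions)
  and 500 replicates (10/10/80), run on a linear front to `L = 500 R0`;
* heterozygosity law: `N0 = 3000`, 200 replicates, five lengths
  `L/R0 ∈ {0.25, 0.5, 1, 2, 4}`;
* single-wall calibration: 10⁴ wall hops × 1000 tracked walls;
* sector laws: `N0 = 500`, 1000 replicates to `R = 4 R0`;
* collapse: κ = 0.4 realised at `(N0, d) = (1000, 1)` and `(10000, 10)`
  (wall velocities 10× apart), 80 replicates each;
* universal-curve cache: `N0 = 1000`, 32–48 replicates per κ, built
  lazily at the requested candidates (a dense 25-point log-spaced κ grid
  is unnecessary when candidates are evaluated directly).

## Known limitations

* **Per-collision statistics are microscopically sensitive.** The ratio of
  annihilations to coalescences per collision is not a universal quantity.
  On a non-inflating front the hop length stays commensurate with the
  initial cell lattice and the model realises the q-state voter model
  exactly: simulated ΔP matches `(3−q)/(q−1)` for equal fractions and
  ≈ 0.51 for the 10/10/80 inoculum.  On an inflating front the positions
  de-commensurate and the full-record ΔP for *unequal* fractions drifts
  lower (≈ 0.43 at `N0 = 2000`, late-time local value ≈ 0.39); the
  equal-fraction values are protected by label symmetry and unaffected.
  An independent zero-temperature Glauber lattice simulation confirms the
  voter-model values.  ΔP comparisons against the voter-model theory are
  therefore run in linear geometry, where that theory applies exactly.
* **Contact-scale corrections to the erf law.** The neutral
  heterozygosity follows `H0 erf(sqrt(1+R0/L) |φ|/φc)` to within ~1% of
  `H0` for `φ ≳ 1.5 φc`; below that, reactions at one hop length (rather
  than zero separation) leave a small positive excess that vanishes as
  `N0 → ∞`.  Because the erf rise — the only `Dw`-sensitive region — sits
  at `φ ≲ φc`, the heterozygosity-based `Dw` fit inherits a downward bias
  of roughly 9% at `N0 = 3000`.  This is a property of the microscopic
  model, not of the estimator; it shrinks with `a/(φc R0)`.
* Open-ended radial runs are refused: on an inflating ring the total
  angular diffusion is bounded, so distant walls may never meet and
  fixation need not occur in finite length.  Radial runs require snapshot
  lengths or an explicit `L_max`.
* The sector-trace mean excludes replicates after sector loss, which
  biases the mean width upward once losses are common; with the default
  initial width `π/2` losses are negligible, but narrow initial sectors
  should be analysed with the loss counts in hand (they are reported).
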