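# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `dlgrowth`, and what the synthetic tests do and do
not demonstrate about real colonies.

## Lattice model

Cells and nutrient live on an `L_x x L_y` grid with solid (reflecting) walls,
emulating a petri dish.  One site holds at most one cell but any number of
free nutrient packets.  Absorbing one packet buys one cell division, which is
the discrete essence of diffusion-limited growth: where packets fail to
arrive, the colony cannot advance.

Each time step applies three sub-phases in a fixed order:

1. **Move** — every free packet, with probability `p_m = 0.8`, performs `s`
   unit moves in uniformly random cardinal directions.  A move into a wall is
   blocked and that unit move is forfeited (no redraw).  `s` is the number of
   nutrient steps per cell generation, i.e. the packet diffusivity in lattice
   units is `p_m * s / 4` (mean-squared displacement `p_m * s` per step over
   `2d = 4`).
2. **Absorb** — each packet sharing a site with a cell whose store is below
   `storage_cap = 4` is absorbed with probability `p_a` (default 1, see
   below).
3. **Reproduce** — each cell with store ≥ `reproduction_cost = 1` and at
   least one vacant cardinal neighbour places, with probability `p_r = 0.5`,
   a daughter (store 0) in a uniformly random vacant neighbour and pays the
   cost.  Cells are processed in uniformly random order, so daughters placed
   earlier in a step block vacancies for cells processed later.

Total nutrient is conserved as
`free + stored + reproduction_cost * (nu - nu0)`, which the code asserts
after every run.

**Seeding scenarios.**  `uniform_single`: one cell at the centre site
(`ceil(L/2)` in 1-based coordinates), packets uniform over all sites;
`uniform_two_seeds`: two cells vertically centred at `centre ± L_x/8`
(separation one quarter of the domain width); `nutrient_column`: central
cell, all `round(c0 * L_x * L_y)` packets uniform over the rightmost column.
Runs stop at cell density 0.2 (0.1 for the nutrient column), at a step cap,
or when growth has become impossible (no free packets, no cell able to pay
the division cost); the terminator is always reported.

**Absorption probability.**  Only the existence of an absorption probability
is conventional; its value is not.  We probed `p_a` over two orders of
magnitude: the three scenario indices (`I_theta ≈ 0.19`, `I_c ≈ 0.39`,
`I_b ≈ 0.99` at `s = 3`, `c0 = 1`) are reproduced only in the fast-absorption
regime, while small `p_a` lets packets percolate through the colony,
flattening gradients and destroying directed growth (`I_b → 0.65`).  The
default is therefore `p_a = 1`.  The cost of this choice is that the colony
front advances much faster than the packet diffusivity, so the lattice
relative spread `Delta = slope(nu vs t) / (p_m s / 4)` is of order 10, not of
order 1; converting a lattice `Delta` to a physical one requires a
lattice-to-physical calibration that is not identifiable from the model
itself.  `delta_from_lattice` documents its convention in its output.

**Random numbers.**  The simulation stream is counter-based (splitmix64
keyed on the run seed and the time-step index), so advancing a state one
step at a time is bit-identical to a single kernel invocation, and every
result is reproducible from its seed.  Initial placement uses a separately
seeded numpy generator.

## Spatial indices

* `I_theta` — angles of all cells about the unweighted centroid, binned into
  `n_bins = 16` equal arcs (the bin count is a reported parameter, not a
  universal constant); counts scaled by `nu / n_bins`; the index is the
  population standard deviation of the scaled counts.  0 for angularly
  uniform colonies; the supremum for a single occupied bin is
  `sqrt(n_bins - 1)` (unreachable exactly for finite sets, since angle
  offsets about the centroid must straddle the centre).  For `n` uniform
  points it decays like `sqrt(n_bins / n)`.
* `I_c` — fraction of cells whose x-coordinate lies strictly inside the open
  strip between the two seeds' x-coordinates.  Uniform twin colonies score
  ≈ 0.5; a depleted gap pushes the value below 0.5; growth toward each other
  pushes it above.  (The complementary convention `1 - nu_c/nu` circulates
  as well; this package reports the cell fraction *between* the seeds, the
  quantity consistent with the reference values it reproduces.)
* `I_b` — fraction of cells right of the domain midline, ties counting half,
  so mirror symmetry gives exactly 0.5 and `I_b > 0.5` means right bias.

Seed positions for experimental images must be supplied by the user; the
package does not infer them.

## Relative spread

`Delta_m` is the least-squares slope of colony area against time (for two
points this is the difference quotient; a single observation needs an
explicit zero-area age origin).  `Delta_n` defaults to glucose,
`D_0 = 4.03e-2 mm^2/min` in water, corrected for gel as
`(1 - 2.3 w) D_0` with `w` the agar weight fraction.  `Delta = Delta_m /
Delta_n` after unit reconciliation.  Published reference values are printed
to two significant figures; the test tolerance of 7% absorbs that rounding.

## Continuum model

The dimensionless system `m_t = D m_xx + m n`, `n_t = n_xx - c_hat m n` on
`x in [0, 1]` is solved by the method of lines: uniform grid of 501 nodes
(odd, so `x = 0.5` is a node), second-order central differences, zero-flux
boundaries via mirrored ghost nodes, stiff integration (LSODA, banded
Jacobian with interleaved `(m_i, n_i)` ordering, `rtol = 1e-8`,
`atol = 1e-10`), 201 stored output times.  Zero-flux walls were chosen to
match the lattice model's solid dish walls; together with the antisymmetric
reaction terms they make `c_hat * int(m) + int(n)` exactly conserved, which
every solve can assert (observed drift ~1e-15, tolerance 1e-6).  `I_b(t)` is
the right-half fraction of `int(m)` by trapezoid quadrature; the maximum is
taken over stored times, so it is a sampled approximation of the continuous
maximum.

**Initial conditions.**  `m0 = exp(-a (x - 0.5)^2)`,
`n0 = N exp(-a (x - 0.75)^2)` with sharpness `a = L^2 = 6889` by default
(`L = 83`, the usable width of a petri dish in mm).  The `L^2` factor is
what rescaling `x` by `L` in the dimensional Gaussians produces; the
alternative convention `a = L` (a published rendering of the same
conditions) is selectable via `ic_sharpness`.  The choice matters: with the
wide (`a = L`) profiles the cell bump overlaps the nutrient bump and
differential amplification of the overlap tail biases the colony at any
`D`, whereas with the narrow profiles bias requires actual cell transport,
confining directed growth to `D` within a decade or two of 1 at moderate
`N` — the regime structure the rest of the analysis relies on.  The package
defaults to `a = L^2` because only that choice yields the documented
structure: no bias along `N = 1`, onset at `N ≈ 1e3` for `D << 1`, and the
global maximum of max `I_b` at the top nutrient level near `D ~ 0.1-1`.

**Regime map.**  `regime_sweep` tabulates max `I_b` over a
`(log10 D, log10 N)` grid (default integer decades over `10^-6..10^3` and
`1..10^5`; finer resolution is a parameter).  Per-cell solver failures are
recorded, not fatal.  At the map's top row the `D = 0.1` and `D = 1` cells
differ by ~1e-3, so the argmax should be read as a plateau near unit `D`
rather than a sharp point.

**Classification.**  `classify_dlg(Delta, N)` uses the measured relative
spread as a stand-in for the diffusivity ratio `D` (both compare colony and
nutrient spread on the same footing) and thresholds the looked-up max `I_b`
at 0.52.  The threshold is a package convention: it separates the no-bias
plateau (values ≤ 0.504 for `N ≤ 1e2` away from `D ~ 1`) from the onset of
directed growth near `D = 1`, and it is reported alongside every verdict.
Queries outside the map raise instead of clamping.

## Synthetic data

The generators emulate the *statistical structure* the indices respond to —
angular uniformity versus sector-confined branches, constructed left/right
fractions, twin discs with a depleted strip, linear area growth with
Gaussian noise, one-pixel-per-point masks — each with closed-form ground
truth and full determinism under a seed.  They do not emulate optics,
segmentation error, cell-scale texture, or curved growth laws; passing the
synthetic suite therefore validates the measurement pipeline, not the
biology of any particular image.

## Problem sizes used in the test suite

Ensemble checks use 20 independently seeded realisations: the three standard
scenarios at 200 x 200 (the reference geometry), and the `(s, c0)` trend
corners `{1, 37} x {1, 7}` at 100 x 100, a size at which the trend directions
match the 200 x 200 behaviour while a full sweep stays interactive.  The
reduced regime map uses integer decades.  These sizes are the package's
standing defaults for its own verification and are stated in the relevant
tests.

## Known limitations

* The lattice model is 2-D, single-occupancy, without cell death, motility
  or toxin fields; the continuum model is 1-D without chemotaxis and is not
  meant to reproduce branch-scale morphology.
* Under fast absorption the nutrient-speed trends weaken or invert: faster
  packets make the colony front a more efficient absorber, so the
  depleted-gap signal `I_c` deepens at large `s` rather than small, and the
  screening signal `I_theta` at `c0 = 1` is nearly flat in `s` (both remain
  strongly dependent on `c0`).  Slow-absorption rule variants restore
  `s`-sensitivity but sacrifice directed growth; see the
  absorption-probability discussion above.
* The mapping from lattice `Delta` to physical `Delta` is conventional
  (`Delta_n = p_m s / 4`), and absolute lattice `Delta` values should not be
  compared against measured colonies without an independent calibration of
  site size and step duration.
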