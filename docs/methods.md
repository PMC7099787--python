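# Methods

This note records the conventions, parameter choices and known limitations
behind `quadframe`'s frame construction and survey-design machinery.

## Raster model and geometry conventions

A `PopulationGrid` is a row-major array of non-negative person counts with
its origin at the top-left corner; the row index increases southward.
Cell extents are half-open, `[x_min, x_max) × (y_min, y_max]`, so adjacent
units never double-count a cell.  Only projected, metre-unit CRSs are
accepted; rasters in degree units must be reprojected upstream — mixing
degrees into the side-length arithmetic would silently corrupt the area
constraint.  Nodata cells are masked out and treated as population zero in
every sum, but stay in the mask so coverage can be reported.  Cells are
assigned to a polygon (a stratum, a region) by their *centre*: it is
deterministic, order-independent, and for 100 m cells the difference from
area-weighted assignment is far below the uncertainty of any modelled
population surface.

## Gaussian smoothing

Modelled surfaces often pile a settlement's population into a few sharp
cells.  Before framing, the surface is relaxed with an isotropic Gaussian
kernel, σ = 500 m by default (5 cells at 100 m resolution), truncated at
4σ.  Smoothed values stay fractional; the frame reports populations from
the smoothed surface.

Mass conservation is exact by construction rather than approximate: each
*source* cell's kernel is renormalised over the valid destination cells,
i.e. with kernel `K` and 0/1 mask `m`, output `= m · K(v / K(m))`.  By
kernel symmetry `K(m)` evaluated at a source cell is exactly that cell's
total kernel weight over valid destinations, so no mass leaks off the grid
edge or into masked-out cells; a final rescale absorbs float round-off
(≤ 1e−6 relative is asserted, machine precision observed).  One side
effect worth knowing: near a mask edge the renormalisation *concentrates*
mass inward, so a constant field is an exact fixed point only at cells
more than two kernel radii from the boundary, and the global maximum can
rise marginally when the input maximum sits within that band.  On
settlement-like fields whose peak is interior, the maximum never
increases.  A σ below half a cell cannot spread mass at the grid
resolution; the input is returned unchanged with a warning.

## Quadtree decomposition

Each window splits into four quadrants, depth-first NW, NE, SW, SE, until
it satisfies `population < pop_max` **and** `side ≤ side_max`, with
defaults 3500 persons and 3000 m.  The population test and the reported
unit populations use the same (smoothed, masked) surface.

*Root window.*  Two regimes:

- If `side_max_cells < max(n_rows, n_cols)` the grid is padded (zero
  population, masked out) to a square of side `side_max_cells · 2^m`, the
  smallest such covering the grid.  Leaves then land on exact multiples of
  `side_max_cells`, so the area ceiling binds at exactly 3 × 3 km on a
  100 m raster — pure power-of-two padding cannot achieve that.
- If the whole grid already fits within the area ceiling, the ceiling can
  only bind at the root, and the smallest power of two covering the grid
  is used instead so quadrants halve evenly.

*Odd sides.*  A window of odd side `s` splits at `floor(s/2)` (30-cell
windows → 15 → 7/8 …), giving quadrants square up to one cell of
asymmetry; `side_m` reports the longer dimension.

*Edges and masks.*  Units wholly inside padding, or containing no
masked-in cell, are dropped.  Units that overlap the valid mask are kept
whole — their extent may reach past the raster edge — with population
summed over valid cells only.  Zero-population units are retained: they
are genuine frame members (selection probability zero, but part of the
spatial partition).  A single cell at or above `pop_max` cannot be split;
it is emitted as a leaf flagged `over_threshold` rather than raising,
since an over-threshold cell is a property of the input surface, not an
error of the decomposition.

The partition is deterministic: unit ids encode the quadrant path from the
root, so identical inputs give identical frames.  Population sums use
plain array-slice summation (no summed-area-table subtraction), which
keeps leaf sums bit-identical to an independent reference recursion and
conservation at the 1e−9 relative level.

## UGC baselines and homogeneity metrics

`ugc_partition` tiles the grid with fixed-size squares anchored at the
raster origin; partial edge tiles are retained, and tiles without a
masked-in cell are dropped — national statistics are therefore computed
over the masked study area, not the bounding box.  `frame_metrics` reports
n, min, max, mean, std and cv = std/mean per scope.  The std uses the
population denominator (ddof 0): with thousands of units the choice is
immaterial, but it must be fixed for exact tests.  cv is a ratio, not a
percent.  Units are assigned to regions by centroid, ties on shared
boundaries going to the lowest region_id.

## Stratification and allocation

Strata are the intersection of admin regions with population type, with a
fixed precedence inside each region: IDP camps first, then urban EAs minus
any IDP overlap, then rural as the remainder — the three pieces partition
the region exactly.  Overlapping admin regions are rejected outright.

Allocation is standard Neyman, `n_h = n · N_h S_h / Σ N_h S_h`: the
stratum sample grows with stratum size and with the within-stratum
standard deviation of the target outcome (S_h is an input, typically
estimated from a prior survey wave).  Integerisation is by largest
remainder with ties broken by stratum_id; a floor (default 2 PSUs, the
minimum for stratum-level variance estimation) is enforced by raising
deficient strata and re-sharing the remainder proportionally among the
rest, iterating until stable.  Deliberate oversampling is expressed as
explicit per-stratum overrides, honoured exactly before the proportional
share is computed.  If every `N_h·S_h` is zero the allocator falls back to
equal shares with a warning rather than dividing by zero.

## Selection

First stage: with-replacement systematic PPS.  Units with positive
population are cumulated in frame emission order (recorded in provenance,
so draws are replayable); with total `T` and `k` hits, one uniform start
`u ∈ [0, T/k)` generates hit positions `u + j·T/k`.  A unit larger than
the interval is selected with certainty, possibly more than once
(multiplicity).  The 20% replacement list is drawn by an independent
systematic pass with a separately derived seed; a substituted PSU inherits
the *original* PSU's selection probability, since an empty PSU is
out-of-scope and the replacement stands in for it by assumption.  All
randomness flows from one master seed through labelled
`SeedSequence`-based splitting (`derive_seed`), and every record carries
the derived seed that produced it.

Last stage: within each SSU a structure is drawn uniformly, then one
household uniformly within the structure, so a household's probability is
`1/(n_structures · n_households_in_its_structure)`.  An SSU with no
structures is marked for replacement, not an error.

## Weights

`P1 = k · n_hi / N_h` is an expected-hit rate and may exceed 1 for
certainty units; inside the weight it is capped at 1 (a certainty unit's
inclusion probability is 1) and the cap is flagged on the record.
SSU segmentation follows three field rules: fewer than 12 structures → the
PSU is not segmented (1 SSU); 12–150 → the standard 12 SSUs; more than
150 → `ceil(n/12)` SSUs of ~12 buildings; and the SSU count scales with
the PSU's selection multiplicity.  One household is interviewed per SSU,
so `P2 = n_ssu / households_in_psu` and `w = 1/(min(P1,1) · P2)`.
`weight_diagnostics` reports the max/min ratio, the relvariance
`cv²(w) = n Σw²/(Σw)² − 1` (equivalently the ddof-0 variance of the
mean-1-scaled weights), and the Kish unequal-weighting effect
`deff_w = 1 + cv²(w)` — the weighting component of the design effect only;
cluster-homogeneity components are out of scope.

## Synthetic study areas

The generator emulates the spatial regime the method targets: compact
settlement clusters on a vast near-empty background.  Clusters are
isotropic truncated-Gaussian blobs renormalised inside the grid so each
integrates exactly to its nominal total (conservation tests are sharp);
background is uniform.  Defaults: 512 × 512 cells of 100 m (~51 km
square), 12 clusters with spreads 300–900 m and totals 5,000–80,000
people, background 0.02 persons/cell.  Those spreads keep even the
largest cluster's peak cell well below the 3500-person threshold, while
the totals force deep splits inside settlements.  Boundaries: a
rectangular admin partition, urban disks of 2 km radius around cluster
centres, and one 500 m IDP square beside the first cluster.

What the fixtures do *not* emulate: covariate-driven dasymetric structure,
anisotropic settlement shapes along roads or coasts, zero-probability
masks (water), or error in the population model itself.  Passing tests
demonstrate the algorithmic guarantees (conservation, constraint
satisfaction, unbiasedness of the weighting identities) — not that any
particular real-world surface is accurate.

## Pipeline

`run_pipeline` executes inputs → smooth → stratify → frames (quadtree per
stratum plus UGC baselines and metrics) → allocate → sample → weights,
writing each artifact and a manifest (parameters, derived seeds, input
checksums, row counts).  Outputs contain no timestamps, so a rerun with
the same config is byte-identical.  In the pipeline's synthetic runs the
structure/household counts needed for SSU plans are derived from unit
population at a mean household size of 5.37 persons with one household
per structure — a deliberate simplification; on real deployments these
come from imagery-based structure counts.

## Problem sizes

The default test and acceptance configurations are desk-scale by design:
random rasters up to 64 × 64 for oracle equivalence, 256 × 256 clustered
surfaces for constraint checks, the full 512 × 512 default for the
homogeneity comparison, 10,000 seeded draws for PPS frequency checks,
1,000 replicates for the Horvitz–Thompson recovery check, and 50 seeded
512 × 512 rasters in `scripts/acceptance.py`.  The entire suite runs in
well under a minute on one CPU.

## Known limitations

- The exact frame produced from a given real raster depends on the root
  anchoring (here: the raster origin) and the smoothing edge conventions;
  other choices shift unit boundaries and frame statistics slightly.
- Rectangular-leaf or arbitrary-shape decompositions are out of scope;
  units are square up to one cell of odd-split asymmetry.
- Nomadic populations have no fixed residence and are not representable in
  an area frame of this kind; they require a separate design.
- S_h estimation from microdata, weight trimming/winsorisation, and full
  design-effect estimation (cluster effects) are outside the package.
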