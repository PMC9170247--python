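# Methods

## The biological setting

Zebrafish notochord precursors are coin-shaped cells stacked in a single
row, so every cell touches exactly two neighbors.  Over development they
adopt one of two fates — inner vacuolated cells or surface sheath cells —
under the control of juxtacrine Notch signaling: the ligand Jag1a activates
Notch in the neighboring cell, Notch activity drives the Her-type
repressors her6/her9, and these repress *jag1a*.  The package models this
circuit, analyzes when it patterns, and reimplements the two measurement
pipelines used to characterize it (mosaic-overexpression image
quantification and a marker-gene specificity score on single-cell UMI
counts).

## Lattice GRN models (`grn_models`)

Cells live on a 1-D lattice with periodic (ring) or reflecting (finite
stack) boundaries.  Neighbor coupling is the *mean* of the two neighbor
values, so periodic and reflecting lattices share parameter scales and the
coupling is invariant to coordination number.  Species order is fixed as
(N, L, S, R), restricted per model.  All rates are per model time unit and
concentrations are in arbitrary units; none of the qualitative conclusions
depend on the unit choice.

**Lateral induction** (species L, S):

    dS_i/dt = k_trans_act * <L>_i - gamma_S * S_i
    dL_i/dt = beta_L * S_i^h / (K_act^h + S_i^h) - gamma_L * L_i

**Lateral inhibition** (L, S, R): the signal activates a repressor which
shuts off the ligand,

    dS_i/dt = k_trans_act * <L>_i - gamma_S * S_i
    dR_i/dt = beta_R * S_i^h / (K_R_act^h + S_i^h) - gamma_R * R_i
    dL_i/dt = beta_L * K_L_rep^h / (K_L_rep^h + R_i^h) - gamma_L * L_i

**Cis/trans mutual inactivation** (N, L, S): receptor and ligand are
irreversible mass-action sinks for each other, both within a cell (rate
constant `K_cis`) and between neighbors (`K_trans`); only trans complexes
release signal, and the Her repressor arm is folded into a single Hill
repression of ligand production by S:

    dN_i/dt = beta_N - gamma*N_i - K_cis*N_i*L_i - K_trans*N_i*<L>_i
    dL_i/dt = beta_L*K_S^h/(K_S^h + S_i^h) - gamma*L_i - K_cis*L_i*N_i - K_trans*L_i*<N>_i
    dS_i/dt = K_trans*N_i*<L>_i - gamma_S*S_i

`K_cis` and `K_trans` are parameterized as interaction-strength rate
constants (larger = stronger), so "cis stronger than trans" reads directly
as `K_cis > K_trans`.  Cis binding is non-signaling.  `h = 1` is the
non-cooperative case; `h >= 1` is enforced.  Production rates and
interaction constants may be zero (term absent); degradation rates and
Hill constants must be positive.  `0^h` evaluates to 0 for `h >= 1`.

### Default parameters

Stored in the packaged `data/default_params.yaml`, never hard-coded:

* cis/trans: `beta_N = beta_L = 10`, `gamma = gamma_S = 1`, `K_S = 1`,
  `h = 1`, `K_cis = K_trans = 1`, lattice n = 30.  Chosen so the HSS is
  unique and positive over the whole phase-diagram grid.
* induction: `beta_L = 10`, `gamma_L = gamma_S = k_trans_act = 1`,
  `K_act = 0.5`, `h_act = 2`.  The high-ligand homogeneous state
  (L* ≈ 9.97) is linearly stable at every coupling mode, so the circuit
  relaxes to a homogeneous high-ligand/high-signal pattern — the behavior
  the lateral-induction topology is known for.
* inhibition: `beta_L = beta_R = 10`, all degradations and
  `k_trans_act = 1`, `K_R_act = K_L_rep = 1`, `h = 2`.  At the HSS the
  feedback-loop gain exceeds the degradation product, the most unstable
  coupling mode is m = −1, and simulations settle into an alternating
  ligand/signal pattern.

## Linear stability analysis (`stability`)

The homogeneous steady state (HSS) — identical concentrations in every
cell — is found by multi-start root finding: 64 log-spaced starting points
over [1e-3, 1e2] for the two leading species (signal seeded at its
quasi-steady value), polished with a hybrid Powell solver, accepted at
residual < 1e-10.  Mutual-inactivation circuits can be multistable, so no
uniqueness is assumed; among componentwise-positive roots the one with the
largest ligand concentration is returned (documented tie-break).  A failed
search raises a convergence error carrying the best residual.

On a periodic lattice, the linearization is block-circulant and splits per
spatial mode into `J(m) = J_intra + m * J_nbr`, with `J_intra` the analytic
own-cell Jacobian, `J_nbr` the derivative with respect to the neighbor
average, and `m = cos(2*pi*k/n) in [-1, 1]`.  Because the trans terms
depend on the own-cell concentration through the product with the neighbor
average, the diagonal of `J_intra` carries the depletion terms
`-K_trans*<L>` and `-K_trans*<N>` evaluated at the HSS — omitting them
spuriously destabilizes trans-dominated regimes.  The analytic blocks are
verified against central finite differences of the full lattice right-hand
side in the tests.

The Maximal Lyapunov Exponent (MLE) is the maximum over modes of the
spectral abscissa (largest real eigenvalue part) of `J(m)`: the escape rate
from the homogeneous state.  MLE > 0 means the HSS is unstable and
patterning ensues; the argmax mode m = −1 corresponds to the period-2
alternating pattern.  The default mode set is the n lattice modes plus a
201-point envelope over [-1, 1].  Spectral abscissa, not modulus, because
this is continuous-time stability.

The phase diagram sweeps the MLE over a log grid of (K_cis, K_trans) —
default 21x21 over [1e-2, 1e2]^2 — warm-starting each HSS search from the
neighboring grid point and falling back to the full multi-start search.
Failed grid points carry NaN, are reported with their coordinates, and are
excluded from sign summaries.  Without cooperativity (h = 1) the unstable
region lies strictly where `K_cis > K_trans`; at h = 3 patterning also
occurs with negligible cis-interaction.  These sign-structure properties —
not a pixel-for-pixel picture, since the published figure's grid and fixed
parameters are not printed — are the reproduction target, and the exported
figure uses the same red-positive/blue-negative convention.

Mode decomposition assumes periodicity; finite reflecting lattices are
analyzed only through the assembled full Jacobian.

## Simulation and classification (`simulate`)

Initial conditions multiply the HSS by `1 + u`, `u ~ U(-eps, +eps)` with
`eps = 0.01` by default — a multiplicative perturbation is scale-free and
seedable; the noise model of the original simulations is not stated.
Integration uses LSODA at rtol 1e-8 / atol 1e-10, default horizon 500 time
units with one automatic doubling if `max|rhs| >= 1e-6` at the end; 200
frames are stored regardless of horizon.  Stored states are clipped to zero
with a logged count (undershoot is bounded by solver tolerance).

A steady ligand profile is labeled `homogeneous` when its coefficient of
variation is below 0.05; `alternating` when no two positive cells (10%-of-
max rule) are adjacent and the positive fraction lies in [0.4, 0.6]; and
`other` otherwise.  The positive-fraction window is a package choice — the
original pattern labels are visual.  Two caveats are documented: odd-n
periodic rings frustrate perfect alternation (even n is the default), and
weakly unstable cis/trans points produce genuine period-2 patterns whose
low state exceeds 10% of the high state, which the positivity-based label
cannot see; the quantitative stability-consistency check (spread of ligand
across cells grows ≥10-fold when MLE > 0.01, shrinks ≥10-fold when
MLE < −0.01) is the test used there.

## Pattern statistics (`pattern_stats`)

* Positivity: a cell is negative when its intensity is strictly below 10%
  of the per-sample maximum, hence positive at >= 10% (the threshold cell
  is positive).
* Adjacency statistic: mean number of positive neighbors per positive
  cell, range [0, 2]; 2 when all cells are positive on a ring, 0 for
  perfect alternation.  End cells of linear arrays contribute their single
  neighbor; circular evaluation is the default since the "equals 2" bound
  presumes two neighbors.  Both conventions are exposed.
* Fate proportion: vacuolated / (vacuolated + sheath).

## Imaging pipeline (`imaging`)

Channels are min-max normalized to [0, 1] (constant images map to zeros
with a warning) and Gaussian-smoothed with sigma 3 px, reflective borders.
Segmentation 1 keeps pixels strictly above both the global threshold
(1.5x the image median, computed on the whole normalized smoothed channel)
and the local mean over a uniform disc of 120 px diameter (implemented as a
121-px disc — radius 60 including the center pixel — with reflective
padding; computed via FFT convolution, identical to direct evaluation to
numerical precision).  Segmentation 2 fills holes with 5 binary dilations
followed by 9 binary erosions (4-connected unit cross per iteration; the
extra erosions trim cell-boundary pixels), labels 8-connected components,
and keeps objects with area >= 3500 px^2.  Segmentation 3 subtracts the
8-px disc dilation of the mask (the boundary zone) from its 25-px disc
dilation; the 25-px dilation starts from the thresholded mask by default,
with a flag to start from the dilated boundary instead.  Morphology-first,
then labeling, then the area filter.  Relative intensity is the mean signal
inside (region ∩ organ) over the mean in (organ \ region); the organ mask
is supplied externally (drawn manually in practice).

The whole mask chain is invariant to affine intensity changes of the raw
image, since normalization absorbs them.

## Specificity score (`scrna_score`)

Counts are normalized per cell to UMIs per million; zero-total cells are
excluded with logged ids.  With per-gene group means `Expr_N` (in-group)
and `Expr_NN` (out-group),

    score = Expr_N^2 / (Expr_NN + pseudocount)
          = Expression x Enrichment

with a pseudocount of 1.0 in the denominator — the handling of zero
out-group expression is otherwise unspecified, and the pseudocount bounds
the enrichment of absent genes without moving well-expressed genes.  The
ranked table reports the score with a 10^-3 display scaling, matching the
units of the bundled 15-gene reference ranking of notochord-enriched genes
(18 hpf); that scaling is an output convention, not part of the score.  Two
rows of the bundled table are internally inconsistent with their own
expression x enrichment product (col2a1a and si:dkey-12l12.1, both
plausibly print typos) and are excluded from round-trip checks.  A natural-
log `log(UMI + 1)` transform is a display option only and never enters the
score.  Group labels are inputs; clustering and annotation are out of
scope.

## Synthetic data (`synthetic_data`)

All generators are pure functions of (parameters, seed) and return the
data together with its ground truth.

* Lattice profiles: high = 1.0, low = 0.05, optional truncated Gaussian
  noise.
* Microscopy: 7 elliptical cells (semi-axes ~40 x 70 px, jittered) abutting
  in a row (2-px gaps) inside a horizontal organ band of a 220 x 640
  image; a seeded mosaic subset (35% of cells, constrained to be
  non-adjacent, as sparse mosaic injections rarely label neighbors) fills
  the cell channel at 1.0; the signal channel carries baseline 0.2 in the
  organ and baseline x enrichment (default 3) inside mosaic cells;
  additive Gaussian noise sd 0.02, truncated at zero.  Cell sizes are set
  so objects survive the pipeline's net 4-px erosion well above the
  3500-px^2 area filter.  The generator deliberately omits texture, uneven
  illumination, and 3-D effects, so pipeline recovery results bound what
  the pipeline can do on clean geometry, not on difficult real images.
* Counts: gamma-Poisson (negative binomial, shape 2) UMIs over 100 genes
  and 200 cells (50 in-group), log-normal base expression weights
  (sigma 1), log-normal per-cell depth (median 10k, sigma 0.3).  Planted
  markers (default 10, folds log-uniform in 20-100x) are drawn from the
  30th-60th base-expression percentile: usable markers must be expressed,
  while a marker carrying a large share of the library would distort
  per-cell normalization.  Because planting inflates the in-group library,
  realized CPM-scale enrichments are compressed below the nominal fold
  (a single 100x gene measures ~50-80x); the recovery tests account for
  this.  The generator does not model ambient RNA, doublets, or batch
  effects.

## Problem sizes and numerical choices

Tests and the acceptance checks use: 21x21 phase-diagram grids, lattices of
n = 30 cells (n = 4-8 for the full-Jacobian oracle), 20 seeds for
simulation and imaging recovery, and 50 seeds for marker recovery and null
calibration — sizes at which every statistical band in the tests is stable
across reruns.  HSS tolerance 1e-10; steady-state flag 1e-6; Jacobian
finite-difference verification at 1e-5 relative; mode/full-Jacobian
agreement at 1e-8.

## Known limitations

Deterministic ODEs only (no Gillespie noise, delays, growth, or division);
1-D lattices only; the cis/trans model keeps the reduced 3-species form
(the explicit repressor variant exists only in the lateral-inhibition
model); no weakly nonlinear analysis or continuation — the mode envelope is
the only wavelength information; the imaging pipeline is 2-D and expects
pre-stitched, pre-registered single planes.
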