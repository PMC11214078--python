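# Methods

## The modeled system

The package models the patterning event that positions a new outgrowth on a
young leaf margin: a strip of cells with an auxin maximum at the distal tip,
a polar PIN1-like efflux carrier whose membrane allocation feeds back on
auxin, and a static patterned CUC input (the boundary-domain transcription
factors) that locally changes how PIN behaves. The question the model
answers is mechanistic: is it sufficient for CUC to promote PIN
phosphorylation — read out either as a switch of the polarization rule
(PIN polarization modulation model, PMM) or as increased transport
efficiency (PIN efficiency modulation model, EMM) — to repolarize CUC cells
and organize a new polarity convergence and auxin maximum proximal to the
tip, while a CUC-free tissue keeps the tip as its only maximum?

## Tissue template

The tissue is a static rectangular strip (default 14 rows x 5 columns) with
4-neighborhood adjacency and closed boundaries (no ghost cells; diffusion
and transport conserve mass). Rows count from the distal tip; the middle
column is the margin proper along which auxin profiles are read. Two
identity fields define the CUC domain: MD, a lateral ramp
`max(0, 1 - |col - mid|/md_width)`, and PROX, a proximodistal ramp that is 0
distally, rises linearly to 1, and in the default template falls back to 0
after a plateau so that the CUC domain `cuc = cuc_max * md * prox` is a
bounded patch (default: middle columns of rows 7-11) with CUC-free cells
both distal and proximal of it. The proximal falloff matters: the emergent
maximum forms where the repolarized CUC cells hand auxin to the CUC-free
cells at the domain's base, so the domain must not touch the proximal edge.
An unbounded PROX (plateau to the last row) remains available via
`prox_end_row=None`.

The auxin source sits in the central cell of row 2. Scenario templates:
`wt` (patterned CUC), `cuc_mutant` (CUC identically zero), `clone` (CUC
forced to a fixed level on listed cells, emulating genetic mosaics).

Initial conditions are part of the template: PIN starts fully apical (the
convergent pattern of a young primordium, with every margin cell polarized
toward the tip) and auxin starts at zero so the tissue fills from
production. Starting instead from a standing uniform auxin level lets the
draining transient latch spurious local structures; filling avoids that
without changing the steady state reached in the well-behaved regime.

## Dynamics

Per cell i, auxin follows

    da_i/dt = sigma_src * 1(source) + sigma_bg - mu_a * a_i
              + D * sum_j (a_j - a_i) - sum_j J_ij,

with carrier flux `J_ij = T (eff_i P_ij a_i - eff_j P_ji a_j)`
(antisymmetric; `eff = 1 + (epsilon - 1) * phi` under EMM, 1 otherwise).
Each cell holds a fixed PIN budget `P_tot` distributed over its membranes;
allocations relax at rate `rho` toward targets set by the polarization
rule. The phosphorylated PIN fraction is an algebraic Hill function of the
static local CUC level, `phi = cuc^h / (K_c^h + cuc^h)`: phosphorylation is
treated as fast relative to patterning, so no separate phospho-PIN state
variable is carried.

Polarization rules:

* **UTG (up-the-gradient)** — membrane weights
  `softmax(kappa * a_j / <a>_i)`, where `<a>_i` is the mean auxin of i's
  neighbors. The normalization makes orientation respond to *relative*
  contrast. This is a deliberate departure from the plain softmax in
  absolute auxin (which `utg_weights` still provides): with absolute
  sensing, cells a few rows from the source sit on a vanishing absolute
  gradient and depolarize, so the template's convergent pattern cannot be
  maintained along the strip at any parameterization we found, and the
  regimes that do polarize globally self-pattern into spaced maxima even
  without CUC. Relative sensing keeps the polarized state self-consistent
  at any absolute auxin level.
* **WTF (with-the-flux)** — membrane weights proportional to
  `max(F_ij, 0)^wtf_exponent + beta`, where `F_ij` is the *total* net
  efflux (carrier plus passive diffusion) normalized by the cell's
  transport scale `T * P_tot * a_i`. Including the diffusive term is what
  lets a standing source-to-base diffusion flux seed basal canalization;
  carrier-only sensing cannot start a reversal from an apically polarized
  template. `beta` is the flux-independent baseline that prevents 0/0 and
  seeds the canal.

Variant wiring: PMM mixes targets as `(1-phi) * UTG + phi * WTF` with
`eff = 1`; EMM uses pure UTG targets with `eff` boosted by `phi`;
`utg_only` is the CUC-blind control.

Integration is explicit fixed-step Euler with a stability guard
`dt * (mu_a + 4D + 4 T P_tot max(1, epsilon)) < 1` enforced at parameter
construction. Steady state requires both the auxin residual `max|da/dt|`
and the PIN reallocation residual `rho * max|target - P|` to fall below
`tol_ss`; the PIN term is included because the WTF canal latches slowly
while auxin is already quasi-static, and an auxin-only test declares
convergence prematurely. Negative auxin (possible only near the guard
limit) is clamped at zero and counted; baseline runs never clamp.

## Baseline parameters

Published parameter values for this model are not available to this
package, so the defaults in `ModelParams` are this package's own
calibration, chosen so the baseline template reproduces the qualitative
wild-type sequence and its controls:

| symbol | default | meaning |
| --- | --- | --- |
| sigma_src | 2.0 a.u./t | source production (distal auxin maximum) |
| sigma_bg | 0.01 a.u./t | background production in every cell |
| mu_a | 0.02 1/t | auxin turnover |
| D | 0.35 1/t | passive cell-cell diffusion |
| T | 0.45 1/t | transport rate per PIN unit |
| P_tot | 1.0 | PIN budget per cell |
| kappa | 12 | UTG sensitivity to relative contrast |
| wtf_exponent | 2 | WTF flux response exponent |
| beta | 0.01 | WTF baseline membrane affinity |
| K_c | 0.4 a.u. | CUC half-saturation of phosphorylation |
| h_c | 3 | Hill coefficient |
| epsilon | 4 | efficiency multiplier of phospho-PIN (EMM) |
| rho | 1.5 1/t | PIN reallocation relaxation |
| dt | 0.1 t | Euler step |
| t_max | 4000 t | integration horizon |

The calibration sits in a deliberate regime: transport is strong enough
relative to diffusion and turnover that a convergence can hold an auxin
hill against spreading (`T P / D ~ 1.3`, `T P >> mu_a`), yet the CUC-free
tissue stays subcritical — the distal source organizes the whole 14-row
strip and neither control forms an emergent maximum. The strip length is
part of that statement: substantially longer strips leave cells beyond the
source's organizing range, where the CUC-free far field self-patterns.
Mechanistically, PMM repolarizes because the band's WTF share canalizes the
source-to-base throughflux into a basal canal that dumps auxin at the
domain's base; EMM repolarizes because boosted export drains the band
relative to the cells below it, flipping the band's proximal cells and
piling auxin at the same place. In both variants the surrounding UTG cells
then lock onto the new maximum (rows 12-13, middle column, amplitude about
1.8-2.1 a.u. versus a profile median near 0.8).

## Pattern readouts

* Net polarity: `v_i = sum_j P_ij u_ij`. Classes: bipolar when the two
  largest opposite-membrane allocations are within ratio `r_bi = 1.5` and
  dominate the perpendicular axis; otherwise nonpolar when
  `|v| < 0.1 P_tot`; otherwise apical/basal/lateral by 45-degree sector
  (ties at the sector boundary go to the proximodistal class).
* Convergences: cell i qualifies when at least `k_min` neighbors have a
  strictly positive polarity component toward i and i is not itself
  strongly polarized (within 45 degrees, above the nonpolar threshold)
  toward any of those neighbors; boundary cells are judged over their
  existing neighbors.
* Emergent maxima on the middle-column profile: strict local maxima
  (boundary rows qualify against their single neighbor — the closed
  proximal edge can legitimately carry an accumulation), at least
  `min_separation = 4` rows from the source row, with amplitude at least
  `(1 + prominence) * median(profile)`, `prominence = 0.25`. The median is
  the reference because the source peak dominates any mean-based scale.
* Repolarization (ensembles): at least one basal-classified cell anywhere
  in the CUC expression domain (`cuc > 0`). The canal can run down any of
  the domain's columns under noise, so the flag reads the whole domain
  rather than only the middle column.

## Noise protocol

Noise is multiplicative uniform, `x <- x (1 + amplitude * U(-1, 1))` i.i.d.
per cell. CUC noise (amplitude 0.30) perturbs the static field once per
replicate. Auxin noise (amplitude 0.10) perturbs the initial state and is
re-injected every `tau = 10 dt` during integration; such runs integrate the
full horizon, stop injecting for a final settling window (``settle_time``,
default 50 t) so the replicate is scored on the underlying pattern rather
than the instantaneous noise phase, and report the converged flag as
observed rather than forced. A replicate succeeds when it retains both the
repolarization flag and at least one emergent maximum on the ridge profile
(per-row maximum across columns): under noise the maximum can form on any
column of the CUC domain, and a single-column readout would miss it.
Ensemble summaries report the success fraction, mean/SD of peak position,
and mean/SD/CV of peak amplitude under both readouts — the ridge
(``amplitude_cv``) and the central-column profile (``amplitude_cv_mid``,
the readout the profiles/figures are drawn from). The amplitude
predictability comparison between PMM and EMM uses the profile readout
averaged over the two matched noise conditions: the PMM's canal pins both
the column and the row of its maximum, so its profile amplitude is
markedly more stable, whereas on the ridge readout the two models are
statistically indistinguishable at these ensemble sizes (the ridge tracks
the EMM's wandering maximum wherever it lands). Replicate seeds are
spawned from one seed sequence, so ensembles are bitwise reproducible and
order-invariant.

## Cell-table quantification

Membrane-based polarity calls use dominance ratios: the strongest segment
must exceed `r_d = 1.5` times the mean of the other three; an opposite
segment within `r_b = 1.5` of the strongest makes the cell bipolar; a
lateral segment within `r_b` appends "-lateral". "Clear basal polarity"
for the reversal estimator means class basal or basal-lateral; the
estimator averages the five qualifying cells closest to the landmark, with
fifth-rank ties broken by cell id. The chi-squared test on polarity
frequency tables is Pearson's without continuity correction;
point-biserial correlation is computed from its mean-difference formula
(numerically the Pearson correlation with 0/1 codes, and checked against
an independent implementation in the tests); reporter-reporter regressions
are ordinary least squares fitted per sample, never pooled.

## Synthetic data

The cell-table generator plants an explicit reversal front: apical cells
distal of the planted distance d*, five basal front cells at
`d* + N(0, sigma_d)` (a reversal zone read with positional noise), and
deeper basal cells strictly proximal of the front. This makes the five-cell
estimator's target well-defined: its error is the mean of five centred
Gaussians, so recovery is exact at zero noise and unbiased otherwise — a
property generic uniform placement does not have (there the five nearest
basal cells sit systematically beyond d*). Reporter x is log-normal
(microscopy intensities are positive and right-skewed) plus a class shift
sized so the population point-biserial correlation with the basal label
equals the planted rho; reporter y follows `a + b x + N(0, sigma)`.
Membrane segments are synthesized consistently with each cell's class
(dominant segment 4x the others before multiplicative jitter), so the
classifier recovers planted classes exactly when the mislabel probability
is zero. Silhouettes are ellipses with k sinusoidal lobes of relative
depth d; the radial construction is star-shaped, hence simple, for every
d < 1, the convex limit is d = 0, and NDMC grows monotonically with d at
fixed k.

What the generators do not emulate: curved margins and geodesic distances,
segmentation errors, uneven cell sizes, bleed-through between channels,
and any spatial autocorrelation of reporter noise. Passing recovery tests
therefore demonstrates estimator correctness on the stated generative
model, not robustness to every real imaging artifact.

## Morphometrics

Silhouettes are closed simple polygons (vertex lists in mm; validation via
the polygon predicates of the geometry library, with an explicit override
for intentionally invalid test inputs). NDMC = (P_contour - P_hull) /
(P_contour + P_hull) on the raw vertices, with no smoothing; convex inputs
return exactly 0 (the hull comparison short-circuits, avoiding float
noise). SVG import supports line-segment paths only (M/L/H/V/Z, absolute
or relative); curves must be flattened upstream.

## Problem sizes and determinism

Default analyses use the 14x5 strip (about 0.5-2 s per steady state on one
CPU), 20-replicate ensembles per condition, and 200-seed recovery
harnesses. Every stochastic component takes an explicit seed or generator;
noise-free runs are exactly deterministic, and fixed seeds reproduce
ensembles bitwise.

## Known limitations

* The polarized far field is maintained, not spontaneously generated: the
  apical template is an initial condition, and the control's "single tip
  maximum" statement holds within the source's organizing range (the
  default strip), not for arbitrarily long tissues. Middle-column cells in
  a shallow pocket where the tip gradient hands over to the
  production-fed far field can classify lateral/weakly-polar rather than
  apical in the control.
* CUC is static; there is no auxin feedback on CUC, no growth, no cell
  division, no mechanics, and no influx carriers. The optional
  `cuc_auxin_repression` hook present in earlier margin models is not
  implemented (left disabled by design).
* The explicit Euler scheme is first-order; `dt` sits well inside the
  stability guard, and halving it does not change the reported patterns.
* PMM steady states can settle into a slow limit-cycle flicker of the hill
  between adjacent rows in some off-baseline regimes; the residual then
  honestly reports non-convergence while the pattern readouts are stable.
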