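# Methods

## The privatization model

The model describes a well-mixed batch co-culture of two yeast genotypes:
a cooperator that secretes periplasmic invertase, hydrolyzing sucrose to
glucose and fructose, and a cheater that lacks the enzyme. Hydrolysis
happens at the cooperator's surface, so a fraction α of the released
monosaccharide is captured by the producing cell before it diffuses away;
the remainder joins a common pool shared equally by every cell. With x the
cooperator frequency, per-cell resource shares are R_co = αr + (1−α)rx and
R_ch = (1−α)rx, where r is the amount of sugar released per cooperator.
Fitness is Monod-saturating, f = fmax·R/(Km+R), and cooperators pay a
constant cost C for enzyme production.

Assumptions worth making explicit:

- **Static per-capita allocation.** Resource shares depend on the current
  composition only; there is no within-batch depletion dynamics and no
  spatial structure (no cell clumping or neighbourhood sharing).
- **Frequency, not density.** The state variable is the cooperator
  fraction; absolute population size is assumed to recover to the same
  carrying capacity each batch.
- **Fitness differences act multiplicatively over a batch.** A transfer of
  Δt generations multiplies each type's abundance by exp(f·Δt) with f
  evaluated at the start-of-batch composition. Equivalently the
  cooperator log-odds move by (f_co − f_ch)·Δt per transfer. This
  single-evaluation discretization treats the transfer as the natural time
  unit; it is exact for constant fitness and accurate whenever the
  frequency moves modestly within one batch.

Because the cheater's share (1−α)rx grows with x while the cooperator
always enjoys the extra private αr, the gap g(x) = f_co − f_ch is strictly
decreasing (the richer cooperator share sits higher on the saturating
curve, where marginal resource is worth less). Hence at most one interior
root: cooperators invade when rare if g(0) > 0, cheaters invade when rare
if g(1) < 0, and both conditions together give protected coexistence at a
unique x*.

## Parameters

| symbol | meaning | units | default |
|--------|---------|-------|---------|
| fmax | maximal per-generation fitness | 1/generation (dimensionless rate) | 1.0 |
| Km | half-saturation resource share | sugar units (same as r) | 1.0 |
| C | cost of cooperation | fitness units | 0.1 |
| r | sugar released per cooperator | sugar units | 1.0 |
| α | fraction retained (privatization) | dimensionless ∈ [0,1] | 0.01 |

The ancestral retention fraction is ~1% (about 99% of hydrolysis products
diffuse into the medium), so `ANCESTRAL_ALPHA = 0.01` is the baseline;
evolved genotypes are represented simply by larger α (duplicated hexose
transporters) and, optionally, larger r (duplicated invertase). fmax and
Km have no published values for this system; the defaults fmax = Km = 1
set the fitness and resource scales and every operation takes them
explicitly, so the defaults never silently matter.

## Numerical choices

- **Root finding.** x* is found by bracketing bisection on [0,1]
  (default tol 1e−10, on both the bracket width and |g|). Monotonicity of
  g makes the root unique and bisection unconditionally convergent;
  nothing here is performance-critical enough to justify a
  derivative-based method. Boundary convention: g(0) ≤ 0 → x* = 0
  (competitive exclusion), g(1) ≥ 0 → x* = 1 (fixation).
- **Serial transfers.** One transfer advances log2(dilution) generations
  (6.64 for 1:100). x = 0 and 1 are absorbing. The deterministic
  simulator omits demographic drift: a 1:100 bottleneck of a saturated
  5 mL culture still passages ~10⁵–10⁷ cells, so drift is negligible
  against selection and against colony-count noise. A finite-N binomial
  bottleneck option exists for sensitivity checks (off by default).
- **Assay scheduling.** Assays nominally every 50 generations map to the
  nearest transfer; a half-transfer of slack lets the nominal
  200-generation assay land on transfer 30 (199.3 generations).
- **Calibration.** `calibrate` minimizes squared residuals between the
  simulator and an observed trajectory over (α, C) — coarse 8×6 grid,
  L-BFGS-B refinement from the three best starts, Nelder–Mead polish —
  with fmax, Km, r held fixed: frequency-only data cannot identify all
  five constants. A flat trajectory is flagged non-identifiable. Optional
  inverse-variance weights (binomial, with a variance floor of 1/(4n))
  give an approximate maximum-likelihood fit.

## Identifiability of (α, C)

Privatization and cost are nearly collinear on frequency data: over the
window of frequencies a trajectory actually visits, raising α lifts g
almost uniformly, which lowering C mimics almost exactly. Profiling the
sum of squares along α (minimizing over C) on noise-free synthetic
trajectories shows a shallow valley spanning most of [0.1, 0.9] at the
noise level of a 6-line × 200-colony experiment, for every (Km, r)
combination we examined. Joint (α, C) recovery from noisy data of this
design is therefore not meaningful — the fit wanders the valley — and the
package's noisy-recovery benchmark instead holds C at its known value and
fits α alone, which tightens the α interval to about ±0.01. This mirrors
experimental practice: the cost of cooperation is measured independently
(monoculture growth kinetics), while the trajectory is used for the
privatization parameter. Noise-free joint recovery remains exact to
~1e−13 and is tested as such.

The noisy benchmark uses Km = 2 (other constants at default) so that the
truth (α = 0.3, C = 0.08) yields interior coexistence with a plateau at
x* ≈ 0.85 — a trajectory that saturates below fixation, like the
coexistence outcome the assay design is meant to resolve — rather than
the fixation trajectory the same truth gives at Km = 1.

## The synthetic-data generator

`synth` emulates the study design: six replicate sucrose coevolution
lines (three for neutral-control sugars), started at 1:1, transferred
1:100 daily for 30 transfers, assayed at generation 0 and every ~50
generations by plating ~200 colonies and counting hygromycin-resistant
(cheater) ones; n_resistant ~ Binomial(n, 1−x_true). Colony number is
fixed at 200 by default (a Poisson(200) option mimics "~200 colonies").
Controls are exactly neutral (α = 0, C = 0). Child seeds for every
(line, assay) cell derive from the master seed via numpy's SeedSequence
keyed on the indices, so single records regenerate in isolation and
tables are byte-stable.

What it deliberately does **not** model: demographic drift and mutation
(each line's latent trajectory is identical; real lines diverge),
between-line environmental variation, plating/counting error beyond
binomial sampling, the slight cooperator advantage seen in glucose
controls, and any evolution of α itself during the run (genotypes have
fixed parameters; "evolved" strains are represented by a different α).
Passing tests therefore validate the machinery and the statistical
calibration of the observation model, not the biological completeness of
the dynamics.

## The α×r response surface

The qualitative claim — coexistence rises non-linearly with α while the
per-cell release r has comparatively little effect — is checked on
α ∈ [0.01, 0.9] (30 points) × r ∈ {0.5, 1, 2, 5} at fmax = 1, Km = 0.5,
C = 0.05, constants chosen so the grid spans the full
exclusion → coexistence → fixation range with a quarter of the cells
interior. On this sweep x*(α) is non-decreasing for every r; the α-driven
range is the full unit interval while the mean (over α) spread across r
is 0.101 (frozen as a regression value, along with the max spread 0.462
which occurs near the clamping transition, where r does matter). The
r-insensitivity is thus a statement about the typical, not worst-case,
effect — and holds only qualitatively: this package makes no numerical
claim about the original response surface, whose axes and constants are
not published.

## Statistics

Cooperator frequency from a plate is p̂ = 1 − k/n (k resistant of n);
intervals are 95% Wilson score (well-behaved at p̂ near 0 or 1, which
fixation and sweep trajectories actually produce). Replicate summaries
report across-line mean and sample SD of p̂ per generation. Group
comparisons use the classical pooled-variance Student t-test, two-sided
(paired and Welch variants behind flags); identical zero-variance groups
return t = 0, p = 1 by convention. No multiple-testing correction is
applied.

## Known limitations

- The equilibrium and trajectory predictions are only as meaningful as
  the unpublished constants fmax, Km, C allow; all quantitative outputs
  should be read relative to an explicitly stated parameter set.
- The exponential-weight update assumes within-batch fitness constancy;
  strong frequency change within a single day would need a finer
  discretization.
- Calibration identifies the (α, C) combination, not each separately,
  unless one is fixed externally (see above).
- The model cannot by itself reproduce the magnitudes of any particular
  wet-lab frequency outcome without calibration; it demonstrates
  mechanism (increased privatization moves cooperators from minority to
  majority), not fitted biology.
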