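# Methods

## The model

`tcaflux` implements steady-state positional 13C-isotopomer analysis of the
TCA cycle for cells labeled with [U-13C]glucose, in the tradition of
glutamate-multiplet flux analysis. The network is a single, well-mixed
compartment with seven lumped carbon-transfer steps:

1. glycolysis feeds a pyruvate pool; each glycolytic pyruvate molecule is
   uniformly 13C-labeled with probability `enrichment` (default 1.0, since
   the labeling medium contains only [U-13C]glucose);
2. LDH equilibrates lactate with pyruvate (lactate reports the pyruvate
   pool);
3. PDH decarboxylates pyruvate to acetyl-CoA (ACCOA.C1 <- PYR.C2,
   ACCOA.C2 <- PYR.C3); a flux `1 - f_pdh` of acetyl-CoA turnover comes from
   unlabeled sources (fatty acids, unlabeled substrates);
4. pyruvate carboxylase (`y_pc`) carboxylates pyruvate to oxaloacetate with
   an unlabeled CO2-derived C4;
5. citrate synthase / aconitase / IDH are condensed into one step making
   alpha-ketoglutarate from OAA + acetyl-CoA (OAA.C1 lost as CO2); GDH
   exchange is taken as fast, so glutamate labeling equals
   alpha-ketoglutarate labeling — glutamate is the measured reporter;
6. KGDH and the four-carbon leg (succinyl-CoA, succinate, fumarate, malate)
   are lumped into one pool with 50:50 symmetric scrambling (C1<->C4,
   C2<->C3) applied once before OAA formation, representing passage through
   the symmetric fumarate intermediate; unlabeled anaplerosis `y_s` enters
   this pool;
7. PEPCK (cataplerosis `y_pc + y_s`, closing the OAA balance) feeds PEP, and
   pyruvate kinase returns a cycling flux `pk` of PEP to pyruvate.

All fluxes are relative to citrate synthase (CS = 1, one cycle turn). The
free parameters are `f_pdh` in [0, 1] and `y_pc`, `pk`, `y_s` >= 0 with
`pk <= y_pc + y_s` (cycling cannot exceed cataplerosis). The pyruvate pool
is closed with a configured glycolytic inflow `g` (default 2.0 relative to
CS, a typical glycolytic:oxidative ratio for proliferating cultured cells),
so the recycled fraction of pyruvate is `pk / (g + pk)`.

Each pool with `n` carbons carries a probability vector over its `2^n`
positional isotopomers. One model evaluation is a fixed point of the
stochastic carbon-transfer map; it is solved by sweep (Gauss-Seidel)
iteration in dependency order, L1 tolerance 1e-10, at most 10,000 sweeps
(typically ~30 suffice: every cycle of the update map carries weight < 1, or
loses memory through fumarase scrambling, so iteration contracts
geometrically). A single-pass "first turn" mode starts all intermediates
unlabeled and reproduces the textbook entry patterns: PDH entry labels
glutamate C4-C5, carboxylase entry labels C2-C3.

An independent Monte-Carlo oracle back-traces single molecules through the
same stochastic source choices (recursion truncated at `max_depth` = 200
levels, beyond which carbons count as unlabeled; the truncation bias decays
geometrically with depth and is far below sampling error at 20,000
molecules). Agreement between the two implementations is a standing
cross-validation test.

## Multiplets

A carbon's 13C resonance splits by which adjacent carbons are labeled:
singlet (none), doublet (one; named by the coupled pair, e.g. C2D12),
doublet-of-doublets/"quartet" (both, unequal couplings), or triplet (both,
equal couplings, 1:2:1). Fractions are conditional probabilities among
molecules labeled at the observed position, matching areas normalized to
the total resonance area. Default one-bond couplings (literature-typical,
configurable): glutamate J12 = 53, J23 = J34 = 34, J45 = 51 Hz; lactate
J12 = 55, J23 = 35 Hz. J23 = J34 makes glutamate C3 collapse to S/D/T.
Quantified resonances are glutamate C2-C5 and lactate C2 (lactate C2
doublets are the unique signature of pyruvate cycling: with a pure tracer
they are nonzero iff `pk > 0`). C1 resonances and long-range couplings are
not modeled.

## Estimation

`IsotopomerFluxModel.fit` minimizes the weighted SSE between observed and
predicted ratios (weights `1/sem^2` when a sem column is present, else 1)
with scipy's bounded trust-region least squares. The constraint
`pk <= y_pc + y_s` is enforced by reparameterization `pk = c (y_pc + y_s)`,
`c` in [0, 1], keeping the search box rectangular: `f_pdh` in [0, 1],
`y_pc`, `y_s` in [0, 5]. Multi-start: the conventional initial vector
(PDH, PK, Y_PC, Ys) = (0.2, 0.3, 0.1, 0.2) plus nine seeded uniform draws
from the box; the best converged start wins (ties by first found within
1e-10). Lactate C2 multiplets enter the objective by default — they are what
identifies `pk`; `include_lactate=False` restricts to glutamate only.
Fitting is per sample; condition-level values are means +/- SEM of
per-sample fits.

Uncertainty is a parametric bootstrap that regenerates data through the
same measurement-noise mechanism the tables are assumed to carry: Gaussian
area noise at a moment-matched scale estimate (per-resonance
renormalization turns iid area noise of variance s^2 into row variance
s^2 (1 - 2p + m p^2); the scale is matched on rows far enough from the
clipping boundary, with a residual-dof correction), clipped at zero and
renormalized per resonance, around the fitted ratios; a chi-square draw
per resample propagates the uncertainty of the scale estimate itself.
Refits start from the point estimate; intervals are percentile. Classical
residual resampling (pooled, leverage-standardized or sign-flip) ignores
the per-resonance correlation and censoring of this noise and measurably
under-covers here; the parametric scheme is calibrated (92-95% measured
coverage at nominal 95% in the seeded recovery study).

Model variants (`full`, `no_cycling` with pk = 0, `no_pc` with y_pc = 0) are
ranked by AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n-k-1) with k the free-flux
count. Group contrasts use the Welch two-sample t test (two-sided by
default; one-sided available).

## Synthetic data

`generate_dataset` emulates replicate NMR multiplet tables: per condition, a
true flux vector (preset or user-specified), n = 4 replicates, additive
Gaussian noise (sd 0.01) on each multiplet area, clipped at zero and
renormalized per resonance — mimicking non-negative line-fit area error.
Optional per-replicate lognormal flux variability (`flux_cv`) adds
biological spread. Preset flux values are invented defaults chosen only to
satisfy the studied qualitative orderings (knockout raises cycling and
carboxylase flux; inhibitors pull them back; DMOG partially restores them);
they are not measurements.

What a green test does establish: the estimator recovers known fluxes from
data generated by the same forward model at realistic noise, the two
independent model implementations agree, and condition contrasts of the
preset magnitudes are detectable at n = 4. What it does not: correctness of
the lumping assumptions for real cells, robustness to baseline/phasing
artifacts, natural-abundance background (off by default, optional), or
compartmentation effects — none of which the generator simulates.

A known, deliberate consequence of the clipped noise model: multiplets whose
true area is zero acquire a positive mean ~ sd/sqrt(2 pi) (~0.004 at the
default sd). This censoring acts like a small genuine cycling signal, so
AICc model selection prefers the cycling variant even for data generated
with pk = 0; the selection test documents this (see the fit/compare test
suite). With pk well above zero, selection and recovery are unaffected
(median absolute error < 0.03 per flux at default noise); the pk estimate
itself carries a small positive bias (~+0.01) from the same mechanism.

## Spectra

The optional spectrum stage renders multiplet patterns as sums of unit-area
Lorentzians (default linewidth 1.0 Hz FWHM) on a ppm grid (default 13C
frequency 150.13 MHz) — doublets split by J, quartets at +/-J1/2 +/- J2/2,
triplets at -J, 0, +J with 1:2:1 — and recovers areas by non-negative linear
least squares against the same templates (linewidth optionally refined by a
bounded 1-D search). Chemical-shift centers are config constants; only
relative line positions matter. Round-trip recovery is exact without noise
and within 0.01 per fraction at SNR 50. Sub-grid splittings are recorded as
warnings; a collinear template set raises a conditioning error rather than
returning garbage.

## Numerical notes and degenerate inputs

- Distributions are renormalized each sweep; conservation (sum 1, no
  negatives) is asserted to 1e-9 on every emitted distribution.
- A resonance with zero 13C area raises an explicit zero-area error (never a
  silent NaN); inside optimization such candidate flux vectors are repelled
  with a large finite penalty residual.
- Flux vectors violating admissibility are rejected before iteration.
- All randomness flows through explicit integer seeds (numpy Generator /
  Python Random); identical seeds give bit-identical tables, fits, and
  bootstrap intervals, and CLI artifacts are byte-identical (sorted JSON
  keys, fixed float precision).
- Steady-state solutions inside one fit are warm-started from the previous
  evaluation; each public `fit`/`bootstrap_ci` call resets the warm state so
  results do not depend on call history.
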