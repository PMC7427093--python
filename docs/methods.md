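# Methods

This note documents the models implemented in `ddstate`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter for
reproducibility.

## Hydrodynamic inference of oligomeric state

The core inference treats the protein as a rigid isotropic sphere in a
continuum solvent.  Rotation and translation are converted to the radius of
the hydrodynamically equivalent sphere by the Stokes–Einstein–Debye and
Stokes–Einstein relations,

    tau_c = 4 pi eta r_h^3 / (3 k_B T),        D = k_B T / (6 pi eta r_h),

and the radius to an effective globular-protein weight by the power law
MW[kDa] = A (r_h/nm)^b.  The oligomer number is the mean predicted weight
over the monomer sequence weight, rounded half away from zero and clamped
to >= 1.

Assumptions and their consequences:

- **Isotropy.** Death domains are compact and near-globular, so a single
  scalar tau_c is adequate.  Elongated proteins would need an anisotropic
  diffusion tensor, which is out of scope.
- **Continuum solvent.** The hydrodynamic radius includes the hydration
  shell; the power-law calibration absorbs the average hydration of
  folded, globular proteins.  Disordered or highly elongated chains fall
  off the calibration and would be over-weighted.
- **Sphere-model scaling.** An ideal rigid dimer has twice the volume of
  the monomer (tau_c x2, D x2^(-1/3)); real side-by-side dimers tumble
  slightly more slowly than that, which only strengthens a dimer call.

Tunable parameters:

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 303.15 | K | the standard 30 degC acquisition temperature for these samples |
| viscosity | pure water at T | Pa s | Vogel correlation `2.414e-5 * 10^(247.8/(T-140))`, ~1% accurate over liquid water; 0.797 mPa s at 303.15 K. Buffer and D2O corrections are an explicit user override, never an implicit default |
| mw_A, mw_b | 1.91, 2.85 | kDa, – | calibrated once in log–log space against reference globular-protein (radius, weight) pairs in the 1–3 nm range; `ddstate.hydro.calibrate_rh_mw` re-derives them from any pair set, and the constants live in `RunConfig`, not in code |

The power law is an empirical approximation: compact folded proteins
scatter by several percent around it, and a single exponent cannot fit
monomer- and dimer-sized particles simultaneously to better than ~4%.
The oligomer call is robust to this because it only needs the predicted
weight to the nearest multiple of the monomer weight.  When the rotational
and translational calls round to different oligomer numbers the rotational
call wins (rotation senses r^3 and discriminates more sharply) and the
result carries a `disagreement` flag.

Sequence weights are average (not monoisotopic) masses — residue masses
plus one water — computed with Biopython's protein mass table; the empty
chain returns the mass of water.

## Rotational correlation times from relaxation interference

The TROSY/anti-TROSY doublet components of each amide relax at rates
R_alpha < R_beta; half the difference is the dipole–CSA cross-correlation
rate eta_xy.  The forward model is

    eta_xy = p * dN * P2(cos theta) * (4 J(0) + 3 J(omega_N)),
    p  = mu0 h gH gN / (16 pi^2 sqrt(2) r_NH^3),
    dN = gN B0 dSigma / (3 sqrt(2)),
    J(w) = (2/5) tau_c / (1 + (w tau_c)^2),

with gyromagnetic-ratio magnitudes, so eta_xy > 0 and is strictly
increasing in tau_c over [0.1, 100] ns (the 4J(0) term grows linearly; the
bounded 3J(omega_N) term cannot reverse it — asserted by a dense scan in
the tests).  Spin constants default to r_NH = 1.02 Å, dSigma_N = −160 ppm,
theta = 17°, the conventional amide interaction parameters; the proton
frequency defaults to 600 MHz.  All of these live in `RunConfig`.

Numerical choices: decay fits are unweighted nonlinear least squares on
intensities (TROSY decay noise is approximately additive; a log-linear
start point makes convergence immediate), inversion is Brent root finding
on [0.1, 100] ns to 1e-4 ns, and the per-residue tau_c uncertainty is
propagated from the two rate standard errors through the local slope of
the forward model.  Because generator and estimator share the forward
model, round-trip tests are insensitive to the exact spin-constant values;
the constants only matter when comparing against externally measured
rates.

Ensemble summaries are the arithmetic mean and standard error over an
explicit residue window; the death-domain core spans residues ~339–417, and
the window is always a caller decision because the structured span differs
between constructs.

## Translational diffusion

Stejskal–Tanner attenuation is fitted by nonlinear least squares with the
diffusion weighting b(g) = (gamma g delta s)^2 (Delta − delta/3).
Rectangular gradient pulses (shape factor s = 1) are the default; a
sine-shape factor of 2/pi is available on `GradientSeries`.  Convection is
assumed to be compensated upstream by the pulse sequence.  The
infinite-dilution extrapolation is a weighted straight line
D(c) = D0 (1 − k_c c) — the minimal (first-order, virial-like) model for
obstruction; a single-concentration input passes through with an
`extrapolated=False` flag instead of failing.  A non-monotone attenuation
beyond ~5x a robust (MAD-based) residual scale triggers a convection
warning rather than an error.

## Kinetics

**Deamidation (first order).**  ln I is regressed on time (weighted when
per-point errors exist), matching the logarithmic presentation in which
such data are inspected; a direct nonlinear fit of the exponential would
differ only in noise weighting.  t_1/2 = ln 2 / k holds exactly by
construction.  A rate within two standard errors of zero raises a
degenerate-fit warning.  Time unit: days.

**Dimerization (second order, irreversible).**  [M]_t = [M]0/(1+[M]0 k t)
is fitted to monomer fractions rescaled by [M]0 = 1/LPR, so the rate
constant is in (mole_lipid/mole_protein) s^-1 and is invariant to the LPR
the experiment was run at — the natural unit system when the reaction is
confined to a bilayer.  Initialization uses the two-point closed-form
estimate; k is bounded below by 0.  Time unit: seconds (hours and days
convert via `TimeCourse.in_seconds`).

**Gel densitometry.**  Band intensity is taken proportional to protein
*mass*, so the monomer fraction is I_monomer / sum(I) with no molar
correction for oligomer bands.  This convention matters: a molar
convention would halve the dimer contribution, shifting fitted rate
constants by up to ~30% late in a course.

**LPR estimator.**  N_lip = 2 S_cell/S_lip (both leaflets) and
N_prot = C_prot N_A/(MW C_cell), with the cell density converted from
cells/mL to cells/L to match the per-litre expression level.  The shipped
`ECOLI_GEOMETRY` preset (4 um^2 cell surface, 0.6e-6 um^2 per DMPC-like
lipid, 6 mg/L expression of a 21,486 g/mol construct at 2.4e9 cells/mL,
N_A = 6e23) yields LPR ≈ 191, reported alongside its one-significant-figure
rounding (200) because the inputs are order-of-magnitude estimates.

## Chemical-shift analytics

Generalized shift perturbations use sqrt(dH^2 + (0.2 dN)^2); 0.2 is the
common amide nitrogen weighting and is configurable.  Classification of
perturbed residues is strictly greater than the threshold (default
0.1 ppm).  Secondary Calpha shifts subtract a shipped random-coil table
(Wishart-type peptide values, provenance in the data file header) with no
neighbor corrections.  Two-state populations come from least-squares
deconvolution of a 1D projection into Lorentzian lines (the natural
solution lineshape; Gaussian/Voigt were considered and rejected as extra
parameters the data cannot constrain), with populations the normalized
areas; any component below 2% of total area flags the fit degenerate.
Peak matching across states and time points is by (residue, atom) key
only — nearest-peak fallback is deliberately disabled because assignment
files are authoritative.

## Synthetic data: what it does and does not emulate

Every generator is a pure function of (parameters, seed) and its noiseless
output round-trips through the matching estimator to numerical precision —
the module-pair contract anchoring the test suite.  Defaults emulate the
study conditions: TRACT decay pairs (12 delays, 4–120 ms, base rate
15 s^-1) whose alpha/beta rates differ by exactly 2 eta_xy(tau_c);
16-point gradient ramps 0.02–0.5 T/m with delta = 4 ms, Delta = 100 ms;
deamidation sampled at {0, 2, 4, 6, 9, 12, 16, 19} days; dimerization at
{0, 2, 5, 10, 20, 30, 50, 70} hours; two-Lorentzian projections on a
512-point ppm grid.  Noise defaults are 2% relative for spectral
intensities and 3% for gel densitometry — typical instrument figures,
stated as assumptions.

Not emulated: raw FIDs and spectral processing, peak overlap and
assignment ambiguity, baseline and phase artifacts, exchange broadening,
anisotropic tumbling, and gel background subtraction.  Passing tests
therefore demonstrate correctness of the estimators given
correctly-extracted intensities, not robustness to upstream processing
errors.

## Problem sizes and the acceptance script

`scripts/acceptance.py` recomputes four quantities from scratch: the
rotationally predicted weight of the rat death domain (closed form), the
E. coli membrane LPR (closed form), and two stochastic TRACT recoveries —
the ensemble mean over 60 residues generated at 5.78 ns with 3% relative
noise, and the monomer→dimer decrement between datasets generated at
5.78 ns and 6.83 ns.  Sixty residues matches the size of a structured
death-domain core.  The decrement uses a paired design: both datasets
share one noise realization (common random numbers), the standard
variance-reduction technique for estimating a difference of means — it
tightens the decrement's seed-to-seed spread from ~0.1 ns to ~0.003 ns
without touching noise level or sample size.  The whole script runs in
about one second.

## Known limitations

- The radius→weight power law is calibrated for compact globular proteins;
  it mis-estimates disordered or elongated chains.
- The first-order fit in log space down-weights late, low-intensity points
  relative to a direct exponential fit when errors are homoscedastic.
- Lorentzian-only deconvolution cannot represent unresolved multiplet
  structure; strongly overlapping components (< half a linewidth apart)
  are flagged but not resolved.
- The LPR estimator inherits the order-of-magnitude uncertainty of its
  inputs; only its leading digit is meaningful.
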