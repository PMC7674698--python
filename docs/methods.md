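# Methods

`pedidose` computes organ doses from a paediatric dynamic kidney test
(⁹⁹ᵐTc-DTPA renography) by combining three models: a stylized voxel phantom
of a 5-year-old child, a minute-by-minute biokinetic model of tracer
excretion graded by kidney function, and a photon Monte Carlo that tallies
energy deposition per organ.  The integrated dose per organ is

    D(organ) = ∫₀ᵀ A(t) · B₀ · exp(−λt) dt            [mGy]

with `A(t)` the per-decay dose-rate coefficient of the source distribution
current at time `t` (MeV/g per decay, converted with 1 mCi = 2.22·10⁹
decays/min and 1 MeV/g = 1.602·10⁻⁷ mGy), `B₀` the administered activity
(1 mCi by default so results read directly as mGy/mCi), and `λ` the ⁹⁹ᵐTc
decay constant (half-life 6.01 h, λ = 1.9221·10⁻³ min⁻¹; the decay weights
sum to 1/λ ≈ 520.26 min over an infinite horizon).  `A(t)` is
piecewise-constant over 1-min frames, so the integral is evaluated with
exact per-frame decay weights — the discretization introduces no quadrature
error, which the tests verify against a 0.001-min trapezoid oracle at 10⁻⁶
relative tolerance.

## Phantom

The phantom is a trunk-only stylized model: an elliptical-cylinder
soft-tissue body (half-axes 10.2 × 7.2 cm, height 49 cm, consistent with a
5-year-old's ~55 cm chest circumference) containing voxelized ellipsoidal
organs.  Eight organs use published paediatric compositions, densities and
volumes (lungs 980 cc at 0.260 g/cc, heart 218 cc, stomach 119.4 cc, liver
562 cc, colon 149.7 cc, small intestine 265 cc, testes 1.57 cc, ovaries
1.66 cc).  Four tissues that the published table omits are filled from
ICRP 89 / ICRU 46-style reference values, since the anatomy source for this
age is the ICRP reference child:

* kidneys — soft-tissue composition, density 1.05 g/cc, 110 g for the pair
  (ICRP 89 reference 5-year-old), i.e. 52.38 cc per kidney;
* bladder wall — 25 g shell around the content;
* bladder content — water, 70 cc (a stylized part-filled paediatric
  bladder; the choice sets the bladder-to-gonad distance and therefore
  scales gonad doses at the ~10% level);
* whole-body soft tissue — the mean of the eight published organ
  compositions at 1.04 g/cc.

Each organ is rasterized at the chosen voxel size (default 2 mm) and its
scale is calibrated by bisection until the realized voxel volume matches the
target within 1% (preferring 0.5%); voxels too coarse to resolve the gonads
within 1% raise an error instructing a finer voxel.  Organs are placed in a
fixed order and each claims only free soft-tissue voxels, so organs conform
to already-placed neighbours instead of overlapping — the label grid is a
strict partition.  This is also how the anatomical constraints the analysis
relies on are realized: the liver ellipsoid is centred so it straddles and
therefore wraps the right kidney's superior pole (the two are voxel-adjacent
by construction), the testes sit ~1 cm inferior to the bladder, and the
ovaries flank the bladder symmetrically.  Paired organs are placed
mirror-symmetrically about the midsagittal plane on a grid whose x-extent is
symmetric, so mirroring the phantom swaps left/right labels exactly (tested
bit-for-bit); the liver, stomach and heart are deliberately asymmetric.
Organ masses are voxel count × voxel volume × density; the testis pair comes
out at 1.633 g and the ovary pair at 1.726 g.

Limitations: no skeleton, no lungs-air anatomy beyond the 0.260 g/cc lung
density, no mucosal substructure, no arms/legs/head.  The pelvis is
mirror-symmetric around the midline bladder, so left/right gonad dose
differences under near-normal function (a few tenths of a percent in the
reference data, driven by asymmetric pelvic anatomy) are below this
phantom's resolvable asymmetry; laterality effects only emerge here when a
retained-kidney source makes them large.

## Biokinetics

A glomerularly filtered tracer is modelled with two source compartments plus
the bladder: at injection the activity splits equally between the kidneys;
a kidney with relative function `f ∈ [0, 1]` drains linearly at `f/20` of
its initial content per minute (complete excretion at `20/f` min; 20 min is
the normal transit time), and a kidney with `f = 0` never drains.  Drained
activity accumulates in the bladder content; there is no voiding and no
blood-pool background.  The dynamic test window is 60 one-minute frames.
Beyond it the source positions are frozen (static residual) out to the
integration horizon: 100 min when both kidneys are normal and 1000 min when
either is degraded, matching the reference-comparison convention; gonad
doses are evaluated over the 60-min test window, the stated maximum duration
of the examination.  Linear drainage was chosen over exponential washout
because the model is anchored to a sharp "emptied by 20 min" statement that
an exponential never satisfies.  Radioactive decay is deliberately absent
from the compartment fractions — it enters once, through the decay weight in
the dose integral.

Kidney-function staging follows the NKF-K/DOQI GFR bins (stage 1: ≥90,
2: 60–89, 3: 30–59, 4: 15–29, 5: <15 mL/min/1.73 m²), implemented as
half-open intervals.

## Photon transport

Photons are sampled from the ⁹ᵐTc line spectrum — 18.3 keV (2.1%),
18.4 keV (3.99%), 140.5 keV (89.06%); 0.9515 photons per decay — uniformly
within the source organ's voxels, and tracked by delta (Woodcock) tracking
against an energy-dependent majorant cross-section, which is exact for voxel
geometries without explicit boundary crossings.  Physics:

* photoelectric absorption deposits the photon energy in the voxel's organ;
* incoherent scattering uses free-electron Klein–Nishina sampling
  (rejection with envelope 2 on the differential cross-section); the
  electron share is deposited locally and the photon continues;
* coherent (Rayleigh) scattering is excluded from the default cross-section
  (a ≲2% effect in tissue over 10–160 keV) and can be enabled, in which
  case angles follow a single Thomas–Fermi form factor;
* kerma approximation throughout: at ≤140.5 keV secondary-electron ranges
  in tissue are well below the 2-mm voxel, so electron transport is not
  modelled;
* photons below 10 keV deposit their residual energy locally; photons
  leaving the grid are terminated;
* internal-conversion/Auger electrons and fluorescence from the non-photon
  4.85% of decays are not transported and no local correction is applied by
  default.

Elemental mass attenuation coefficients (photoelectric, incoherent,
coherent; H, C, N, O, Na, P, S, Cl, K; 10–160 keV) are committed as a static
table and combined by the mixture rule with log–log interpolation.  The
table was generated once (`scripts/make_attenuation_table.py`) from the
Cromer–Liberman photoabsorption compilation, the closed-form Klein–Nishina
total cross-section for incoherent scattering, and a Thomas–Fermi
form-factor integral for coherent scattering.  Against standard water
reference values the resulting totals agree to ~1% above 100 keV — the
region that controls ⁹⁹ᵐTc transport — and sit ~5% low at 10–30 keV, where
Cromer–Liberman photoabsorption falls below Scofield-based tabulations;
hydrogen photoabsorption (absent from the compilation, a ~0.1% effect) uses
a hydrogenic Born power law.  The soft-tissue total at 140 keV is checked in
the tests against an independently recorded compilation value (0.152 cm²/g)
at 2%.

Tallies are F6-style energy depositions per organ, normalized to MeV/g per
source decay (the 0.9515 photons/decay yield folded in), with relative
errors from ≥10 independent batches; `run_until_converged` adds batches
until named organs reach a target relative error (3% is the convention the
analysis uses).  Verification oracles in the test suite: exponential
first-collision distances through a uniform slab (3σ), inverse-square
fall-off of the dose to thin concentric shells in vacuum (3σ), Klein–Nishina
mean scattering cosine against numerical quadrature (3σ), energy
conservation in an effectively infinite absorber, and exact left/right dose
swaps on the mirrored phantom within statistics.

## Scenario evaluation and variance control

`run_scenario(method="frames")` transports every unique source frame
(identical frames — the long static tail — share one transport run and one
random stream).  Each unique frame's stream is derived from the base seed
plus a stable digest of the frame's compartment fractions, so identical
frames are identical across scenarios as well (common random numbers), and
results are bit-reproducible for a given seed.  Errors of duplicated frames
are perfectly correlated and are propagated that way.

Because transport is linear in the source distribution, any frame's
dose-rate map is the fraction-weighted combination of three per-compartment
maps (kidney L, kidney R, bladder content) — the MIRD S-value
factorization.  `run_scenario(method="svalue")`, `compartment_dose_maps` and
`integrate_with_maps` implement this route: three transport runs serve every
scenario and horizon, variance for the 0.8 g gonads drops by an order of
magnitude at equal cost, and dose *orderings* across scenarios (testis dose
versus function level, impaired versus normal kidney) become deterministic
functions of one shared map set.  The scenario sweep and the ordering checks
use this route; the two routes are tested to agree within their combined
statistical errors.

## Problem sizes

Default runs use the 2-mm phantom (106 × 76 × 250 voxels).  The test suite
uses 10³–4·10⁵ histories per run; the acceptance script uses 2·10⁶ histories
per unique frame for the normal scenario (4.2·10⁷ total) and 10⁶ for the
impaired scenario, which puts kidney tallies near 0.1% and integrated testis
doses near 4% relative error.

## Known limitations

* The stylized phantom reproduces reference organ volumes and the stated
  anatomical relations, not the reference child's true shapes; absolute
  cross-organ doses carry geometry error well beyond counting statistics
  (tens of percent), which is why end-to-end comparisons use a wide band
  while arithmetic and physics checks are tight.
* A kidney with zero function retains its full uptake for the whole
  integration horizon under the frozen-tail model; over 1000 min this
  self-irradiation dominates every other contribution, so abolished-function
  kidney doses are an order of magnitude above reference coefficients that
  assume clearance from the body.
* No bladder voiding, no blood-pool compartment, no absolute GFR→drainage
  calibration (function levels are relative), photon-only transport.
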