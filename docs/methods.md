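# Methods

## Problem and model

The package estimates how different contaminated ground surfaces
contribute to the external photon dose at points inside and around
single-family houses, for a uniform surface deposition of a 0.662 MeV
gamma emitter (the ¹³⁷ᵐBa line following ¹³⁷Cs decay) at unit areal
activity. The dosimetric endpoint is air kerma free-in-air; the reported
quantities are *dose-contribution fractions*: the kerma a source region
delivers to an observation point divided by the summed kerma from all
regions at that point. Fractions are independent of the absolute source
normalisation, which is kerma per photon emitted per m² (one photon per
decay; multiply by 0.944 photons/decay and the activity to get absolute
dose rates for ¹³⁷Cs).

## Scenario

The synthetic neighbourhood covers 16,250 m²: fifteen rectangular lots in
three rows of five (row depths 32.93/32/30 m, lot width 31 m, every lot
area within 875–1050 m²) flanking an L-shaped street (6 m wide, 18 cm
asphalt, the 15-element mixture at ρ = 2.5784 g/cm³), with a far-field
ground annulus extending to a 500 m truncation radius. Each lot carries a
15 m × 10 m single-storey house (2.5 m walls, 11 rooms in two bands, one
1.2 m × 1.2 m window per room with a 0.9 m sill, 7 cm wood partitions,
10 cm concrete floor slab, 2 cm wood roof). Two construction flavours are
modelled: *brick* (0.25 m solid brick walls) and *wood* (22 mm wood +
150 mm mineral wool + 13 mm wood). Properties P12–P15 are instrumented
with 30 cm air-filled detector spheres at the eleven room centres and at
the garden centroid, all 1 m above ground.

Points that are deliberate modelling choices rather than published facts:

* The exact lot map and house drawings of the original study area are not
  published; the builder reproduces the *printed* areal constraints with
  a parameterised layout and representative Northern European
  construction build-ups, all overridable through the configuration. The
  scenario metadata flags the construction as representative.
* Default placements put the houses of the street-facing rows 4 m from
  the street, the central-row house P14 in the middle of its lot, and
  P15 drawn back from both street arms. Rows are staggered sideways by
  ±2 m so window lines do not align across the neighbourhood (a perfectly
  periodic grid would open artificial window-to-window streaming
  corridors for distant sources; the effect on the results turned out to
  be about one percentage point).
* The far-field region is an annulus between the neighbourhood rectangle
  and the truncation radius. At 0.662 MeV the photon mean free path in
  air is ≈ 108 m, so 500 m (≈ 4.6 mean free paths) truncates the tail at
  a sub-percent level of the total; doubling the radius changes the
  far-field contribution by far less than the buildup-model uncertainty.
* Sources sit exactly at the air–soil (or air–asphalt) interface; a 0.5 m
  soil slab under the whole world supplies ground backscatter. Ground
  roughness, source penetration into soil, vegetation and contamination
  of roofs or walls are out of scope.

## Physical data

Elemental interaction coefficients (photoelectric, incoherent and mass
energy-absorption, 16 elements, 18-point grid over 0.01–0.8 MeV) are
embedded as plain text and combined by the standard mixture rule with
log-log interpolation. They were generated once
(`scripts/generate_coefficients.py`): the incoherent part is the exact
free-electron Klein–Nishina cross-section with an empirical binding
reduction (δ = 0.21 Z^0.75 / E_keV^0.9, calibrated against standard
reference tabulations at 0.06–0.662 MeV); the photoelectric part is a
piecewise log-log interpolation through reference anchor values, with
trace elements filled by Z-power scaling between anchored neighbours.
Coherent (Rayleigh) scattering and fluorescence escape are omitted; at
the source energy their effect on air kerma is at the percent level.
The embedded tables agree with the frozen reference spot values for H,
C, O, Si, Ca, Fe to better than 2%, and reproduce the textbook water
attenuation (0.0857 cm²/g) and air kerma-per-fluence (3.1 × 10⁻¹² Gy·cm²)
at 0.662 MeV to better than 1%.

## Monte-Carlo engine

Analog transport: uniform birth position on the region, isotropic
direction, 0.662 MeV; free paths sampled against the exact heterogeneous
optical depth along ray-traced segments; collisions branch between
photoelectric absorption and Compton scattering with table probabilities;
Compton kinematics use Kahn's rejection sampling of the free-electron
Klein–Nishina law (validated against quadrature of the differential cross
section). Photons are terminated below 10 keV (sub-cutoff photons are
irrelevant to air kerma at 1 m height); Russian roulette guards the
(analog-unity) weights. Secondary electrons are not transported: kerma is
scored from fluence via μ_en/ρ, matching the free-in-air endpoint.

Estimators: a track-length fluence tally in the 30 cm detector spheres
("analog"), and a next-event point-detector estimator ("next-event",
default) scoring the analytically attenuated expected contribution of
every birth and Compton event to every detector. Each (region, detector)
tally carries batch statistics and a convergence report: total relative
error < 0.10, 1/√N error decay across batches (within a factor of two),
batch-mean drift, relative variance-of-variance < 0.10, and a
no-dominant-history test; failing pairs are flagged in the matrix, never
silently accepted.

## Point-kernel engine

Regions are tessellated into cells (≤ 1 m² squares for gardens and
street, clipped to the polygons, with 4× subdivision near the detector; a
polar grid centred on the observation point for the far-field annulus and
open-field disks, whose cell areas tile the analytic region area). Each
cell contributes `S_A dA · e^(−Σμᵢlᵢ) · B · k(E₀) / (4π r²)` along the
straight path. The engine is deterministic and exactly linear in areal
activity and additive over regions.

Buildup uses the Berger form `B(x) = 1 + a x e^{bx}` per material, with
the dominant-layer rule: the factor of the material with the largest μ·l
on the path, evaluated at that material's own optical thickness and
clamped at μr = 10. The parameters were fitted at 0.662 MeV against this
package's own Monte-Carlo engine (`scripts/fit_buildup.py`) in the
configurations where they are applied: building materials on
slab-between-source-and-detector problems, air on ground-ring sources
over a soil half-space (an infinite-medium fit would overstate the
missing lower-half-space scatter by roughly 40%), water and soil on
infinite-medium point-source problems. The three candidate application
rules (factor at total depth, at the dominant layer's own depth, product
over layers) were compared against the Monte-Carlo engine on a
two-property neighbourhood before freezing; the own-depth variant tracked
it best throughout.

Known limitation: for observation points whose line of sight to a source
region is blocked by a building, the true dose is dominated by air and
ground scatter *around* the shield; a line-of-sight kernel cannot
represent this (skyshine kernels are out of scope), and such pairs are
underestimated several-fold even though their uncollided component is
exact. Summed over all regions the point-kernel matrix stays within
about 25% of the Monte-Carlo matrix at every observation point; the
Monte-Carlo engine is the exactness reference wherever a shadowed pair
matters.

## Analysis layer

Fraction tables divide each matrix row by its sum (rows re-sum to 1
within 10⁻⁶; error propagation uses the uncorrelated approximation).
Occupancy weighting collapses room fractions to house level with weights
hours/Σhours — the default 14 h/day profile is 8 h bedroom (OP1), 3.5 h
living room (OP10), 1 h kitchen (OP9), 1 h dining room (OP11), 0.5 h
bathroom (OP2); the remaining 10 h of the day are spent away from home
and contribute nothing, so house-level fractions are unaffected and
absolute doses are per-14-h-indoor day. Isodose sets rank cells by
contribution (ties broken by distance to the observation point, then cell
index) and accumulate greedily to the requested percentage; on equal-area
grids this greedy set is provably minimal, which the tests verify by
exhaustive search on small grids. The indoor "average" per property is
the unweighted mean over OP1–OP11; occupancy weighting is applied only in
the house-level report.

## Scale of the shipped computations

The default full-scenario run (both flavours, 1 m² cells, ≈ 19,000 source
cells × 48 observation points each) takes about 90 s on one CPU and is
what the acceptance script reports. Monte-Carlo cross-validations in the
test suite run on toy scenes and a two-property mini neighbourhood at
4,000–30,000 histories per region — enough for 3σ agreement tests at the
few-percent to 20% level. The statistics of the buildup calibration runs
(20,000–40,000 histories) leave a few-percent uncertainty on the fitted
parameters, quoted as-is.

## What the synthetic scenario does and does not show

The generator reproduces the printed areal constraints, source
definitions, detector layout and occupancy profile of the study design,
with representative construction defaults standing in for the unpublished
house drawings. Qualitative findings are robust to that substitution and
are reproduced here: the largest single contribution at indoor points
comes from the house's own garden; the wooden house, being less
shielding, receives a larger own-garden share than the brick house and a
smaller share from remote areas; the street contributes more to the
street-facing properties; total indoor kerma is lower in the brick house
at every point. Quantities that depend on the absolute wall mass and
window layout — the precise own-garden percentage indoors, and how much
higher the garden point's own-share is than the indoor average — shift by
around five to ten percentage points with plausible alternative
construction details, and should be read with that uncertainty in mind.
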