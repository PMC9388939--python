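# Methods

## Scope and model overview

The package reproduces, at desk scale, the comparison chain for
out-of-field organ doses in a pediatric brain irradiation delivered
once with six non-coplanar static fields (3DCRT) and once with seven
coplanar sliding-window fields (IMRT), 54 Gy in 30 fractions at 6 MV.
Three stages are modelled: a measurement stage (TLD dose reduction
with an uncertainty budget), a calculation stage (simplified Monte
Carlo photon transport on a voxel phantom, driven by the plan tables
and dynamic MLC logs), and a comparison stage. Doses from a treatment
planning system are import-only; the package never computes them.

## Phantom

The phantom is a labelled voxel grid in a right-handed patient frame
(+x patient-left, +y anterior, +z superior, cm), isocenter at the PTV
geometric center, voxel centers at `origin + (ijk + 0.5)·voxel`.
Organs are parametric primitives (ellipsoid/box/cylinder) painted in
list order; later specs overwrite earlier ones. Since no CT data is
distributable, each out-of-field organ center is placed along a fixed
anatomical direction scaled to exactly the reference PTV-to-organ
center distance — the center distance is the quantity the analysis
uses, so it is reproduced by construction; shapes are plausible
surrogates, not segmented anatomy. The default grid is 2 × 2 × 3 mm
(~0.9 M voxels); a clinical-resolution preset (0.09766 × 0.09766 ×
0.3 cm, ~4.7 × 10⁷ voxels) is available for the full-scale geometry.

The PTV is an ellipsoid read as 9.8 cm³ volume (axis ratios
1.55 : 1.25 : 1). The published figure "9.8 cm(3)" is ambiguous
between a volume and an axis length; the volume reading matches a
realistic pediatric target and is configurable.

Interaction data: each material carries μ/ρ and μen/ρ tables on a
25-point grid spanning 0.01–7 MeV, interpolated log-log with no
extrapolation. Water, air and cortical bone are surrogate compilations
patterned after the standard reference data; soft-tissue-like organs
and thyroid reuse the water shape rescaled so the 6 MeV μen/ρ equals
the values used in the measurement reduction (0.0179 and 0.0194
cm²/g). Lung uses soft-tissue composition at 0.26 g/cm³ for
transport, while the kerma-to-dose conversion in the TLD chain uses
the measured-campaign coefficients — consistent with the measurement
protocol, which treats all non-thyroid organs as generic soft tissue.

## Plans and MLC logs

Plan files are versioned TSV mirroring the clinical field tables; jaw
consistency (Field X = X1 + X2 within 0.05 cm) is validated per row.
The 3DCRT fields are static jaw-defined fields with the MLC retracted.
MLC logs are a documented text dialect (vendor binary formats are
proprietary): a header plus one row per control point with the
cumulative MU fraction and 60 + 60 leaf-tip positions (cm at
isocenter); bank A may never pass bank B, and MU fractions must be
non-decreasing (normalized to end at 1). Leaf widths follow a
120-leaf model: 0.5 cm for the central 40 pairs, 1.0 cm outboard.

The IMRT simulation strategy subsamples every 5th of 100 control
points (1-based indices 5, 10, …, 100), 20 snapshots per field — 140
jobs for the 7-field plan — each assigned an equal share of the field
MU. Equal weighting is the simplest consistent reading of uniform
index sampling; the true per-snapshot MU apportionment inside the
reference calculation is not documented.

## Transport engine

Photon-only Monte Carlo with the kerma approximation: organ dose is
scored as fluence × E × μen/ρ with a track-length estimator
accumulated at every Woodcock delta-tracking collision (expected
track length per collision is 1/Σ_majorant). Secondary electrons are
assumed to deposit locally — the same electronic-equilibrium
assumption the TLD reduction makes — so electron transport and the
associated cutoff are not needed. The photon cutoff is 0.01 MeV
(table floor); sub-cutoff photons deposit their residual energy
locally.

Interactions: Compton scattering sampled from the Klein–Nishina
distribution (Kahn's method) with the energy-transfer deposited
locally; photoelectric absorption; pair production above 1.022 MeV
depositing E − 1.022 MeV and emitting two back-to-back 511 keV
photons. The incoherent channel is split off the total attenuation
via the Klein–Nishina cross-section times the material electron
density; the remainder is photoelectric below and pair above
threshold. Rayleigh scattering is omitted (≤ a few % at MV energies).
An analog energy ledger (deposited + escaped = emitted) is maintained
independently of the kerma tally as a conservation check.

Source and head surrogate: a point-ish source (1.2 mm FWHM focal
spot) 100 cm above the isocenter fires at points sampled uniformly
over the jaw bounding box + 1 cm margin on the isocenter plane. The
base history weight carries the sampled area relative to 100 cm², so
tallies are per unit primary fluence and comparable across field
sizes. Photons aimed at blocked regions carry the MLC (1.7 %) or jaw
(0.2 %) transmission as weight; 0.1 % of histories are emitted as
isotropic (downward-hemisphere) head leakage at the base weight.
These are typical published values for this linac class — the full
treatment head is deliberately not modelled. The default spectrum is
a parametric 6 MV shape (Gamma-like fluence, mean ≈ 1.7 MeV) on
[0.1, 6] MeV; a monoenergetic mode serves the physics tests.

Geometry: gantry rotates the beam about the patient's
superior–inferior axis (gantry 0 = anterior, supine patient),
collimator about the beam axis, couch about the vertical axis. The
delivery is isocentric (SAD 100 cm); the per-field SSD column is
recorded and validated but the patient surface, not a repositioning,
determines the actual SSD, as in clinical SAD setups.

Variance reduction and statistics: Russian roulette below a weight
threshold (survivors' weights restored), optional splitting above a
threshold; the pair is unbiased (verified against an analog run).
Tallies are batched (default 20 batches) and the per-organ 1σ
relative standard error is the batch-mean SE; organs with fewer than
two nonzero batch means are flagged as undefined rather than
reported. A fixed seed reproduces tallies bit-for-bit. An optional
majorant floor forces extra virtual collisions to densify track-length
scoring in thin regions (used by the CF calibration, where the 1 cm
scoring slab is much thinner than the MV mean free path).

Absolute dose: a conversion factor CF maps per-particle tallies to
mGy/MU, calibrated under reference conditions — 10 × 10 cm field, MLC
retracted, SSD 100 cm water phantom — by assigning 10 mGy/MU to the
mean dose of the central in-field 8 × 8 × 1 cm region at 10 cm depth.
The reference geometry is standard; the depth, region and dose level
are explicit configuration (the source does not state them). Course
organ dose is Σ_jobs tally × CF × job MU × 30 fractions, with the
per-job batch errors propagated in quadrature.

## TLD chain

`K_air = RD · Ecc · f(Q) · f(fad) · f(E) · f(α) / RCF`, then
`D_tissue = K_air · (μen/ρ)_tissue / (μen/ρ)_air` with both
coefficients at 6 MeV. Fading and angular corrections default to 1
(immediate readout; no angular dependence at these energies). Using a
single 6 MeV conversion energy for a 6 MV beam (mean energy ≈ 2 MeV)
follows the measurement protocol being emulated; because the
synthetic generator inverts the same chain, round trips are exact
regardless of this choice.

The budget combines four components in quadrature at k = 1: element
correction coefficient 3.0 %, reader stability 3.8 %, reader
calibration factor 15.0 %, energy dependence 1.4 % (a
rectangular-distribution component stored already standardized, i.e.
divided by √3; its tag is documentation only) → 15.824 %, reported as
15.8 %. The per-organ "SD" is `mean × 0.158` — the combined
uncertainty at reporting precision — because that is the convention
the reference campaign's summary table follows (every printed cell
equals it exactly; a per-dosimeter spread is not available for
single-dosimeter organs).

## Synthetic data

The TLD generator inverts the reduction chain:
`RD = D_true · (μen_air/μen_tissue) · RCF / (Ecc · f_Q · f_E)`, with
per-dosimeter Ecc drawn around 1 (2 % spread) and recorded, so
noiseless round trips are exact to numerical precision. Noise is a
mean-one multiplicative log-normal factor on RD at the combined
budget σ (doses stay positive; the budget is stated in relative
terms); a decomposed mode instead perturbs Ecc, f(Q) and RCF
individually at their component σ, and reproduces the same combined
spread. All dosimeters of an organ sample the same true mean dose —
within-organ placement is not specified beyond the counts (1, 1, 2,
4, 2, 12, 16 = 38 per technique).

The MLC generator produces a sliding-window delivery: a leaf-gap
window sweeps from the X1 to the X2 jaw over ~100 control points;
only pairs 27–34 move (their 0.5 cm widths cover the fields' ±1.8 cm
Y extent), all other pairs stay parked beyond the X1 jaw. The default
gap fraction (0.65 of the field X width, mildly modulated per pair)
was chosen once so that the fluence delivered per field is clinically
comparable to the open static fields at the tabulated MU values —
strongly modulated windows would deliver an unrealistically low
target dose for the given MU. Cumulative MU fractions are strictly
increasing with random increments; output is byte-identical per seed.

## What the synthetic conditions do and do not show

The generator emulates the *structure* of the study inputs — field
geometry, MU, control-point counts, moving-pair restriction,
dosimeter layout, noise budget — not the clinical fluence maps or the
segmented anatomy. Consequently the measurement-chain results (budget
quadrature, SD convention, round-trip recovery) carry over to real
data directly, while the transport results are qualitative: the
simulated doses reproduce physical orderings (PTV ≫ out-of-field,
dose falling with PTV distance, modulated delivery raising near-field
out-of-field dose) but not the measured organ doses of the reference
campaign, which reflect a real treatment head and real leaf
sequences. The headline measured values (e.g. right eye 13 040.6 vs
593.0 mGy) enter only as generator ground truths and comparison
inputs, never as simulator outputs.

## Numerical choices and problem sizes

Coefficient lookups: log-log interpolation, hard error outside
[0.01, 7] MeV. Transport lookup tables: 256-point log-energy grid.
Ties in dose-vs-distance tables keep input order. Degenerate inputs
(empty organ, zero MU, zero reference tally, crossed leaves,
non-monotone MU fractions, non-finite photon states) raise explicit
errors. Default problem sizes: 2 × 10⁶ histories for the
high-statistics single-field run (≈ 3 % relative SE on the nearest
out-of-field organ), 1.4 × 10⁶ over 140 jobs for the IMRT plan,
6 × 10⁵ over 6 jobs for 3DCRT, 2 × 10⁵ for CF calibration (≈ 1.5 %);
200 replicates for TLD round trips. These sizes were chosen as the
smallest that leave the acceptance margins dominated by physics, not
statistics.

## Known limitations

- No electron/positron transport: near-interface and build-up doses
  are kerma approximations; fine for out-of-field organs, coarse
  inside the beam.
- The treatment head is three numbers (MLC/jaw transmission, leakage)
  plus an aperture; tongue-and-groove, rounded leaf ends and
  collimator scatter source structure are absent.
- Surrogate anatomy: organ shapes/directions are parametric; only the
  PTV-to-organ center distances are faithful.
- Coefficient tables are package-internal surrogates; they are
  self-consistent (the same tables drive transport and its
  closed-form tests) but not a metrological reference.
- VMAT arcs, DICOM-RT import, TPS dose calculation and second-cancer
  risk models are out of scope.
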