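# Methods

## Problem

[177Lu]Lu-PSMA radioligand therapy is studied in vitro in two culture
formats: cell monolayers under 1 mL of activity-loaded medium in a
flat-bottom well, and multicellular tumour spheroids under 100 µL in a
U-bottom 96-well. Because the mean beta range of Lu-177 in water
(~0.4–1.8 mm for its dominant electron emissions) is comparable to the
dimensions of the medium column, the absorbed dose delivered to the cells
at equal applied activity differs strongly between the two formats. This
package computes that dose by Monte Carlo electron transport and provides
the assay arithmetic (clonogenic survival, spheroid growth, 2D/3D
viability folds) that the dose feeds into.

## Source model

Lu-177 decay is represented by three monoenergetic electron lines — the
mean energies of the dominant beta branches — at 497 keV (78.6%/decay),
384 keV (9.1%) and 176 keV (12.2%). Yields are not renormalised; the 0.1%
remainder is a no-emission decay, handled analytically (the transport
engine simulates emitted electrons and the dose conversion multiplies by
the 0.999 yield). Gamma emissions, daughter products and the full beta
spectral shapes are out of scope. Activity is uniform over the medium;
emission directions are isotropic. The expected decay number over a
treatment is activity × duration (default), or the decay integral
A₀(1−e^(−λt))/λ when decay correction is enabled (half-life 6.647 d; the
correction is ≈1.3% for 3 h and is off by default because the treatment is
scored as a fixed 3 h bath).

## Geometry

Lengths in mm, origin at the centre of the medium/wall bottom interface,
z up. Both vessels have 1 mm polystyrene walls; the space above the medium
surface is treated as vacuum (electrons leaving upward are discarded —
air backscatter of ≤2 MeV electrons is negligible).

* **2D well**: flat-bottom cylinder, inner diameter 34.8 mm (a standard
  6-well plate; the vessel drawing is not public, so this is a declared
  assumption, exposed in the configuration because the 2D dose is
  sensitive to it — see Limitations). 1 mL fills it to 1.051 mm. Scoring
  region: a 12 mm diameter × 0.01 mm cylinder seated on the bottom — the
  cell monolayer. Tally voxels 0.1 × 0.1 × 0.01 mm.
* **3D well**: U-bottom well, hemispherical cap of radius 3.2 mm continued
  by a cylinder; 100 µL fills the cap (68.6 µL) plus 0.98 mm of cylinder,
  4.18 mm total. Scoring region: a 0.6 mm diameter sphere resting on the
  bottom apex — the spheroid. The agarose coating used in spheroid culture
  is modelled as water. Tally voxels 0.01 mm isotropic.
* **Bath**: a 30 mm radius water ball with a central 0.6 mm scoring
  sphere, used only for the equilibrium-limit validation.

`locate` labels every point as exactly one of outside / medium / scoring /
wall (scoring points are medium points with the more specific label);
voxels follow the half-open convention [lower, upper).

## Transport physics

Condensed-history transport in the continuous-slowing-down approximation:

* **Stopping powers.** 24 reference nodes (1–2500 keV) of collision and
  radiative mass stopping power for liquid water, log-log interpolated
  (exact at the nodes). CSDA ranges are the numerical integral of the
  inverse total stopping power from the 1 keV table floor (the missing
  sub-keV tail is < 5×10⁻⁵ mm); they agree with published range anchors
  to ~1%. The radiative nodes are approximate — the radiative loss is
  removed from the electron but discarded (no photon transport), a ~1–2%
  energy effect below 600 keV. Polystyrene is density-scaled water
  (linear stopping power × 1.05 × 0.97).
* **Stepping.** Step length = min(geometric cap, length losing 5% of the
  current energy). The geometric cap is 0.01 mm inside an envelope of the
  scoring region (its bounding box inflated by 1.2 coarse steps, so no
  coarse step can cross into the scoring region) and 0.1 mm elsewhere.
  Collision loss × step length is deposited at the step midpoint (steps
  never exceed the voxel size where it matters, so midpoint attribution
  is adequate); the destination region is the midpoint's label.
* **Multiple scattering.** Gaussian deflection per step with Highland's
  width; the logarithmic correction term is evaluated on the electron's
  residual CSDA range rather than the sub-step length (applying the log
  per sub-step is a known underscattering bias). No single-scattering
  tail, no delta-ray production: secondary-particle transport moves
  energy on the sub-voxel scale and largely cancels under lateral
  quasi-equilibrium, so region-averaged doses at the 0.6–12 mm scale are
  insensitive to it; this is the main fidelity caveat.
* **Termination.** An electron is killed, depositing its residual energy
  locally, when the residual CSDA range falls below the 0.01 mm range
  cut (≈22 keV in water); it is discarded (energy booked as escaped) when
  it enters vacuum. Wall transport continues with scaled stopping power;
  wall deposits are tallied outside the dose grid but inside the energy
  balance, and wall backscatter into the medium is included (within the
  limits of Gaussian scattering).
* **Range rejection** (default on): an electron whose straight-line
  distance to the scoring region exceeds its residual CSDA range plus a
  0.05 mm margin can never reach it and is killed with a local deposit.
  This is exact for the scoring-region dose and for the energy balance
  (path length bounds crow-flight distance), wrong only for the remote
  voxel map; depth-profile runs switch it off.

Energy is conserved identically: scoring + medium + wall + escaped +
radiative deposits equal the emitted energy to machine precision, and the
test suite asserts this in both rejection modes.

## Tallies, uncertainty, dose

Histories are split into 20 batches. The relative standard error of the
mean scoring-region energy uses the weighted batch-means estimator
s² = Σ nᵢ(eᵢ−ē)²/(B−1), SE = √(s²/Σnᵢ) — for equal batches the familiar
sd/√B. The adaptive mode doubles the history count until the relative SE
beats a target (default 1.5%) and records the achieved value.

Absorbed dose: D = (E_scoring/N) × N_decays × yield / m_scoring with
1.602176634×10⁻¹⁶ J/keV and unit-density water masses. Dose is exactly
linear in activity, so the activity→dose conversion table rescales a
single per-history tally per geometry. The closed-form equilibrium dose
(every emitted keV absorbed in the medium: N_decays × 447.06 keV / mass,
7.74 Gy per 1 MBq × 3 h in 100 µL, 0.774 Gy in 1 mL) is a strict upper
bound for any finite geometry and doubles as a validation oracle: a
uniform source in a water ball much larger than the electron range must
score the equilibrium dose at its centre, which the engine reproduces
within Monte Carlo error (the source is importance-restricted to a 2.6 mm
core around the scoring sphere — electrons born farther can never reach
it — with the decay count scaled by the core volume).

### Problem sizes

The reproduction script (`scripts/acceptance.py`) runs 10⁷ histories per
geometry (relative SE 0.3% in 2D, 0.6% in 3D; ~1–2 minutes together). The
test suite uses adaptive runs to 1.5% SE for the dose checks and
1e5-scale runs for the statistical invariants.

## Assay arithmetic

* **Plating efficiency**: mean control colonies / seeded cells; values
  above 1 warn (counting anomaly) rather than fail.
* **Surviving fraction**: mean treated colonies / (seeded × PE), the
  standard normalisation in which the control is exactly 1. The raw
  protocol sentence ("PE multiplied by colony count"), read literally,
  yields a non-normalised quantity that cannot give control SF = 1; it is
  available behind `literal=True` for audit but is not the default.
* **Spheroid growth**: one diameter per spheroid = mean of its three
  measurements; curves aggregate experiments as mean ± sd per
  (activity, day). Growth is read on days 0/7/14/20, viability on days
  7/15/21 — both schedules are kept as distinct timelines.
* **Viability fold (2D/3D)**: each arm's mean luminescence is first
  normalised by its own same-day 0-activity control (default), making the
  fold comparable across models seeded with different cell numbers; a
  raw-means mode is provided. fold(2D/3D) × fold(3D/2D) = 1 by
  construction.
* **Significance**: Welch's unpaired two-sample t-test, two-sided,
  significant at p < 0.01. Zero-variance degenerate pairs return p = 1
  (equal means) or the p → 0 limit, flagged.
* **LQ fit**: least squares of −ln SF on αD + βD² with β ≥ 0 and no
  intercept (SF(0) = 1 forced). Standard errors from the residual-based
  covariance s²(AᵀA)⁻¹. At monolayer doses ≤ 0.8 Gy the two parameters
  are nearly collinear, so single-experiment SEs are wide — visible in
  the worked example and in the coverage tests.

## Synthetic-assay generator

The generator produces schema-identical datasets with known ground truth,
driven by the simulated conversion table: colony counts are Poisson about
seeded × PE × exp(−αD−βD²) at the 2D dose; spheroid diameters follow
d₀·exp(r(1−I(D))t) with saturating inhibition I(D) = D/(D+D₅₀) at the 3D
dose and three lognormal measurements per spheroid; viability
luminescence is proportional to viable cell number, with LQ survival
compounded over elapsed time (exponent 1 + c·day, so the 2D/3D fold grows
with observation day) times lognormal noise. The target-negative line
receives zero specific dose everywhere (no radioligand binding;
medium-bath crossfire is deliberately ignored because the negative-line
arms show no effect at these activities).

Defaults (the study conditions of every test): α = 0.2 Gy⁻¹,
β = 0.05 Gy⁻² (typical low-dose-rate values for a radiosensitive prostate
line), PE 0.20/0.40 with 1000/250 seeded cells for the target-positive /
negative lines, clonogenic activities 0–2 MBq, spheroid activities
0–0.4 MBq, d₀ = 400 µm, growth 0.04/day, D₅₀ = 0.005 Gy (every treated 3D
dose sits deep in the inhibition plateau, so treated growth curves
collapse together while staying clearly below control), 3% diameter CV,
10% luminescence CV, fold-compounding c = 0.05/day, 3 replicates ×
3 experiments.

What it does *not* emulate: uptake/retention kinetics, bystander
signalling, Gompertzian growth saturation, spheroid core necrosis,
plate-position effects. Passing round-trip tests therefore demonstrate
that the analysis chain is unbiased and correctly calibrated on its own
model class — not that the model class captures every feature of real
assay data.

## Design choices and limitations

* The 2D vessel diameter is the dominant systematic in the monolayer
  dose. With 1 MBq uniformly in 1 mL, the dose on the floor of the medium
  column obeys a reciprocity bound D = ½·D_eq·f(t), where f(t) ≤ 1 is the
  fraction of a plane source's energy absorbed within the column height
  t; for the default 34.8 mm well (t = 1.05 mm) f ≈ 0.9, giving ~0.37 Gy,
  and no transport refinement can push it far below that for this
  geometry — thinner columns (wider vessels) reduce it, deeper columns
  raise it toward ½·D_eq. The diameter is therefore a first-class
  configuration knob.
* Wall backscatter is carried by Gaussian multiple scattering only, which
  under-represents large-angle single scattering; the polystyrene
  stopping-power ratio (0.97) is an approximation. Both matter only near
  walls.
* One well is simulated in isolation: no plate-neighbour crossfire, no
  meniscus.
* Doses are dose-to-water everywhere (the scoring regions are water
  proxies for the biology; no cellular composition is modelled), and no
  micro/nanodosimetric structure below the voxel scale is attempted.
* Uptake and retention into the cell structures are not modelled; the
  scoring regions see only the medium bath source.
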