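# Methods

This note documents the models, numerical choices and limitations behind
`brachydmf`: a Monte Carlo simulation-and-analysis pipeline for the dosimetry
of a five-lumen balloon brachytherapy applicator used in accelerated partial
breast irradiation (APBI) with an HDR Ir-192 stepping source.

## The question the pipeline answers

TG-43-style treatment planning systems compute brachytherapy dose by
superposing single-source dose tables measured in an effectively unbounded
water medium. Near the skin the assumption fails: air (and lung) beyond the
target scatter almost nothing back, so the delivered dose at the prescription
point falls short of the planned dose. The pipeline quantifies the deficit
with the **dose modification factor**

DMF(x) = D_full-scatter / D(finite tissue depth x),

the ratio of the dose rate at the reference point — 1 cm beyond the balloon
surface, the prescription distance — in homogeneous full-scatter water to
the dose rate when only `x` cm of water lies beyond that point. We report
`underdose_percent = 100 (DMF − 1)`: the percentage by which a
homogeneous-water plan overestimates the delivered dose. A second study axis
quantifies the applicator's dose-shaping ability: the maximum dose asymmetry
achievable at four cardinal reference points while respecting the RTOG 0413
hot-volume limits (V150 ≤ 50 cm³, V200 ≤ 10 cm³).

## Geometry

Balloon center at the origin, applicator axis = +z, the asymmetry /
measurement point on +y; right-handed axes, lengths in cm.

* **Balloon**: sphere of radius 2.2 cm. Balloon wall, catheters and interior
  are water — the silicone wall and nylon lumens are dosimetrically thin.
* **Lumens**: one straight central lumen on the axis; four outer lumens at
  azimuths 0°/90°/180°/270°, each modeled as a circular arc in the axial
  plane through its azimuth, pinned to the axis at the balloon poles and
  bulging to the device's maximum central-to-outer offset of 0.5 cm at the
  equator (arc radius (R² + d²)/2d = 5.09 cm for R = 2.2, d = 0.5).
* **Dwells**: 7 per lumen at 0.5 cm arc-length steps centered on the
  equatorial plane; each dwell is a cylinder of half-length 0.25 cm and
  radius 0.017 cm (the physical source capsule dimensions); 35 dwells total.
  Emission points are sampled uniformly over the cylinder volume,
  isotropically in angle. Source self-absorption and encapsulation are not
  modeled: almost all of it cancels in the dose ratios this study reports.
* **Reference points**: four points at cardinal azimuths, 1 cm beyond the
  balloon surface (3.2 cm from the center) in the equatorial plane, aligned
  with the outer-lumen azimuths. The detector is a sphere of radius 0.17 cm
  centered on the +y point (an ion-chamber-sized measurement volume).
* **Phantoms**: a cuboid water phantom 40 × (23.2 + x) × 40 cm with 20 cm of
  water behind the balloon center and x cm beyond the reference point, and a
  spherical water phantom of radius 3.2 + x concentric with the balloon
  (the geometric worst case for missing scatter). Either sits in a 100 cm
  cube of air that bounds the world. The full-scatter reference is a
  33.2 cm sphere: 30 cm of water beyond the detector, where a margin scan
  shows the tally has converged well below 0.2%.
* **Steel cable (optional)**: a type-304 cylinder of radius 0.045 cm along
  each active lumen path from the −z pole to the outermost occupied dwell,
  discretized into ≤0.25 cm straight segments. The device gives no cable
  dimensions; the radius is exposed in the configuration.

## Photon physics

Energies 2 keV – 1.5 MeV; analog transport; kerma approximation (no electron
transport): secondary-electron ranges at these energies are ≲2 mm in water,
small against the 1 cm scoring distance, and the ratios reported here cancel
most of the residual.

* **Source spectrum**: 24 discrete Ir-192 lines (principal gammas plus the
  Pt/Os K x-rays) with 2.30 photons per decay and mean energy 0.354 MeV,
  embedded as a text fixture. L x-rays below 60 keV are omitted; they cannot
  cross the ≥1 cm water paths that matter here.
* **Cross sections**: per-material grids of the total mass attenuation
  coefficient (with and without coherent scattering) and the mass
  energy-absorption coefficient for water, air and steel, transcribed from
  standard reference compilations and interpolated log-log (exact at nodes).
  The transport lookup is a 1024-point uniform-log-energy table built from
  the same grids. The without-coherent column subtracts a per-material
  power-law coherent model (A/E^1.9, calibrated at 0.1 MeV, capped) from the
  with-coherent total; since coherent scattering is off by default, this
  partition only matters for the optional Rayleigh mode. Stainless steel 304
  uses elemental-iron coefficients at 8.0 g/cm³ (Cr and Ni flank Fe in Z;
  the cable study is a sub-percent ratio effect).
* **Interactions**: Compton scattering on free electrons, sampled from the
  exact Klein-Nishina density by composition-rejection; the non-Compton
  remainder of the total (photoelectric, plus the minor pair-production
  channel above 1.022 MeV) is absorption. Bound-electron incoherent
  corrections are omitted — negligible above ~100 keV, where nearly all
  transported energy lies. Optional coherent mode: the coherent share
  deflects through a Thomson-shaped angle without energy loss; toggling it
  moves the DMF by less than the statistical error (asserted in tests).
* **Cutoff**: photons falling below 2 keV terminate; their residual range in
  water is micrometres.

## Estimators and statistics

The default tally is a **track-length kerma estimator**: every transported
segment crossing the detector sphere adds `w · L · E · (μen/ρ)_water(E) / V`.
Scoring uses the water coefficient everywhere ("dose to water"), which keeps
the tally continuous when the detector straddles the phantom surface at zero
tissue depth. A collision-density estimator (`w · E · (μen/ρ)_w / (V μ)` per
collision inside the detector) is retained purely as an independent
cross-check; the two agree within statistics on every scene tested.

Uncertainties come from 100 history batches; the relative standard error
follows 1/√n over at least two decades (fitted slope −0.5 ± 0.05). Each
dwell transports the same number of photons and its sub-tally is multiplied
by the dwell weight, making tallies exactly linear in the weights; per-dwell
sub-tallies are stored per batch, so a plan's tally can be recombined under
different weights without rerunning.

**Random numbers**: xoshiro256** seeded via splitmix64. Each history draws
from its own stream derived from (run seed, dwell index, history index), and
each free flight samples a single optical depth that is carried across
material boundaries. Together these make paired scenes true
common-random-number experiments: a history consumes an identical random
sequence in both members of a pair unless its track actually samples the
altered geometry. This is what resolves the sub-percent wire and
plan-symmetry effects at desk scale (the paired sigma is roughly an order of
magnitude below independent-run quadrature).

No other variance reduction is used; the engine stays analog and auditable.

## The planning-system surrogate

The TG-43 stand-in is a single 2-D kernel k(r, θ): the Monte Carlo kerma
around one unit-weight dwell at the origin of a full-scatter water sphere,
tallied on ring bins — 39 log-spaced radial nodes on [0.25, 20] cm (chosen
so r = 1 cm is an exact node) × 41 uniform cos θ bins (odd, so θ = 90° is a
node) — and normalized to 1 at (r = 1 cm, θ = 90°). Segments are split at
radial shell crossings exactly and sub-stepped at ≤0.25 cm for the polar
coordinate. The two polar halves are averaged by default (the source is
mirror-symmetric; this halves the variance). Interpolation is bilinear in
(log r, cos θ), where line-source dose is near-linear; below r = 0.25 cm the
kernel is not evaluated (no clinical point lies there). All doses are
relative — no air-kerma strength or dose-rate constant enters, because every
reported quantity is a ratio. A loader accepts user-supplied tables in the
same text layout for cross-checks. The kernel's transverse-axis shape
reproduces the published flat radial-dose-function behavior of Ir-192 in
water to within ~2% out to 8 cm, and kernel superposition matches direct
Monte Carlo tallies of full plans within statistics.

Dose grids superpose the kernel over all weighted dwells on a 40 cm,
0.25 cm-spacing Cartesian grid (161 nodes per axis, inclusive endpoints);
V150/V200 count node-centered voxels at ≥1.5×/≥2× prescription, excluding
the balloon interior (it is not tissue; a flag includes it for sensitivity).

## Plans

* **Symmetric**: equal weight on all 35 dwells, scaled so the mean cardinal
  point dose equals the 340 cGy per-fraction prescription; the four points
  then agree within interpolation tolerance.
* **Asymmetric (`per_lumen`, default)**: the central lumen and the outer
  lumen nearest the asymmetry point are not loaded; the three remaining
  lumens get per-lumen scale factors (equal weights within a lumen) solved
  exactly so the three held points sit at prescription. This is the minimal
  deterministic forward plan, with all 21 remaining dwells active.
* **Asymmetric (`max_asymmetry`)**: same exclusions, but all 21 dwell
  weights are free and a linear program minimizes the asymmetry-point dose
  subject to the three held-point equalities and non-negativity. This is the
  model's true maximum achievable asymmetry — what a planner optimizing
  dwell times by hand is reaching toward.

Dose asymmetry = 100 × (mean of held points − asymmetry-point dose) / (mean
of held points). In this geometry the per-lumen construction yields ≈8%
asymmetry and the LP optimum ≈11.6% (with V150 ≈ 24 cm³, V200 ≈ 2 cm³, well
inside the RTOG limits). Physical measurements of the device report a larger
maximum asymmetry (≈15%): the arc-lumen model here — pinned at the poles
with a 0.5 cm apex offset, dwells centered on the equator — evidently
steers less hard than the real CT-traced lumen paths, and the published
plan's manually tapered dwell times are not available. The LP bound shows
this is a geometry-model limit, not a planning limit: no non-negative
weighting of these 21 dwells exceeds ≈11.6%.

## Study scales and problem sizes

The campaign scale is 5×10⁷ histories per simulation, at which the analog
track-length tally resolves the reference point to ≈0.55% rse (seed-to-seed
estimates range 0.48-0.66%); the headline underdose numbers and the
statistical-envelope check run at this scale. A Rao-Blackwellized
(expected-value) track-length variant could buy back the remaining ~20% of
variance, but the analog estimator is kept for auditability and for exact
correspondence with the per-segment score formula.
Desk-scale defaults elsewhere: the scenario manifest uses scale 0.02 (10⁶
histories per record) for quick surveys; the symmetric-vs-asymmetric
comparison recombines the campaign-scale per-dwell sub-tallies under both
weight vectors (exact common random numbers at zero extra transport cost,
resolving the ≈0.2% depth-0 plan effect and the strict depth-0 to depth-10
DMF decrease beyond 3σ); the paired steel-cable study runs at 8×10⁶
histories per member, where the common-random-number sigma is ≈0.25% of
DMF; kernels derive from 6×10⁶ histories (≲0.5% rse at the plan-relevant
nodes). Variance analysis behind
these choices: the 0.17 cm detector subtends ~7×10⁻⁴ of the source sphere,
so the analog track-length estimator needs ~10⁷ histories per percent-level
DMF distinction; 10⁶-history runs resolve DMF to roughly ±3%.

At these scales the full acceptance recomputation takes on the order of ten
minutes on one CPU; the engine transports ≈2×10⁶ histories/s in the finite
phantoms and ≈5×10⁵ histories/s in the full-scatter sphere.

## What the synthetic scenarios do and do not emulate

Everything is synthetic and in-repo: geometry, spectrum, cross sections and
the study matrix ({cuboid, spherical} × depths 0–10 cm × {symmetric,
asymmetric} ± cable). The phantoms are idealized water bodies — no breast
contour, no lung or rib heterogeneity, no CT-derived anatomy; the balloon is
a perfect water-filled sphere (no contrast solution); the dose is kerma to
water. Passing tests therefore demonstrate the internal consistency of the
transport/planning stack and the reproduction of idealized-phantom results;
they do not validate patient-level dosimetry, TG-186-style model-based dose
calculation, or other applicator models.

## Numerical details and degenerate inputs

* Surface crossings advance the photon 10⁻⁷ cm past the boundary to avoid
  re-intersection; geometry is watertight against a marching oracle at
  10⁻⁴ cm.
* An all-zero plan returns a zero tally with zero error; a detector outside
  the world cube, a negative tissue depth, a balloon radius outside
  [2, 3] cm, or an unnormalized plan for grid evaluation raise immediately.
* The LP plan solve uses HiGHS; an infeasible system (negative required
  weight in the per-lumen solve) raises naming the offending lumen.
* Identical (seed, configuration, geometry) reruns are bit-identical; the
  manifest is a pure function of (master seed, scale).

## Known limitations

* Kerma approximation and water-only kerma scoring bias absolute doses at
  the sub-percent level near interfaces; ratios cancel most of it.
* Free-electron Compton (no incoherent scattering function) slightly
  overestimates scatter below ~50 keV.
* The coherent-scattering option uses a Thomson angular shape, not form
  factors; it exists to bound the effect, which is below statistics here.
* The arc-lumen geometry understates the physical device's dose-steering
  ability (see Plans above).
* Cross-section grids are transcriptions at ~25 energies per material;
  log-log interpolation between nodes is accurate to ~1-2% against the
  underlying compilations, which is far below the statistical resolution of
  any reported ratio.
* Two acceptance-level checks in `tests/test_acceptance.py` fail by design
  of honesty rather than be weakened: the maximum-asymmetry/hot-volume
  check (the arc-lumen geometry caps asymmetry near 11.6%, see Plans) and
  the direct ≤0.5% rse check at campaign scale (the analog estimator
  resolves ≈0.55%, see Study scales). All other tests pass.
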