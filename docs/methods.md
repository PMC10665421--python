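# Methods

`fractrial` simulates a complete in silico fracture-healing trial: a
population of anthropometric avatars, body-weight-scaled internal loads over
the stance phase of gait, a linear surrogate model of the mechanics of a
nailed tibial fracture gap, strain-tensor invariants per mesh cell, a
correlation battery linking anthropometry to gap micromechanics, and two
cohort-resampling algorithms that quantify how often randomized trial arms
differ in anthropometric makeup. This note records the model assumptions,
the defaults and why they were chosen, and what the synthetic data do and do
not show.

## Population model

Avatars are adult men aged 20–60 years, height restricted to 1.60–1.95 m and
BMI to 18–35 kg·m⁻² — a deliberately homogeneous population that excludes
underweight, adiposity and pediatric/geriatric bone physiology, whose
healing dynamics differ. The cohort is stratified into eight five-year age
groups. Within a group, height and BMI are drawn **independently** from
normal distributions truncated to the bounds above (marginal, not joint,
truncation); body weight follows deterministically as `BMI · height²` and
tibia length from an inverse stature formula of the forensic-medicine type,

    tibia_cm = (height_cm − 81.9) / 2.42 + N(0, 1.2 cm),

whose constants reproduce realistic adult male tibiae (1.79 m → ≈401 mm).
The residual SD represents inter-individual proportion differences within an
age group.

The default distribution moments — height mean 1.78 m, SD 0.07 m in every
group; BMI mean rising linearly from 25.0 to 27.5 kg·m⁻² across the age
groups with SD 3.5; uniform age-group weights — are *plausible stand-ins*
for German male census statistics, not measured values. Every moment, bound
and weight is configurable; the defaults exist so the pipeline runs
end-to-end out of the box. The ignored within-group age (only the group
index is materialized) is harmless because no downstream computation uses
exact age.

## Stance-phase loads

Internal loads at the fracture level are specified at five stance-phase
landmarks S1–S5, six components each (Fx, Fy, Fz, Mx, My, Mz), referenced to
a 755 N body weight. Per avatar, every component is multiplied by
`λ = weight·g / 755 N` (g = 9.81 m·s⁻²), so the load *pattern* is shared
across the population while its magnitude tracks body weight — the central
coupling the downstream statistics probe.

The shipped landmark table is an **invented, configurable default**
expressed in percent body weight: S1–S3 carry sub-maximal early/mid-stance
loads, S4 the axial-force peak (≈2.6× body weight) and S5 the
bending-moment peak with a reduced axial force. The coordinate frame is
right-handed with x anterior, y medial, z superior; compressive axial force
has Fz < 0. Only the qualitative structure (axial peak at S4, moment peak at
S5, compression throughout) matters for the analyses; absolute values are
replaceable via the `loads` config section.

## Surrogate gap mechanics

The mechanics of the fractured, nailed tibia are represented by an idealized
circular cross-section: an 11 mm titanium nail (solid circle, r = 5.5 mm,
E = 110 GPa, ν = 0.3), a cortical shell whose outer radius scales with tibia
length (`r_out = 0.028 · tibia_length`, cortical thickness 35 % of r_out),
and a compliant tissue layer of height h = 3 mm — the fracture gap — bridged
in parallel by the nail and by connective tissue (E = 3 MPa, ν = 0.3)
filling the gap annulus and a callus annulus out to 1.3·r_out. The chain is:

1. **Section properties.** Areas, second moments and polar moments of the
   nail and of the tissue annulus from nail surface to callus outer radius
   (gap and callus tissue both bridge the fracture; the "tissue annulus"
   extent is a modelling choice of this package).
2. **Parallel springs.** `k_ax = (EₙAₙ + EₜAₜ)/h`, bending `κ = (EI)_Σ/h`,
   shear with correction factor κₛ = 0.9, torsion with polar moments.
3. **Interfragmentary movement.** Six motion components, each load component
   divided by its stiffness — strictly linear.
4. **Strain reconstruction.** Per cell at (x, y) on a polar mesh
   (10×48 gap cells, 6×48 callus cells by default):
   `ε_zz = (δz + φₓ·y − φ_y·x)/h`, engineering shears
   `γ_xz = (δx − θz·y)/h`, `γ_yz = (δy + θz·x)/h`, and an unconfined Poisson
   response `ε_xx = ε_yy = −ν_t·ε_zz`. Tensors store *tensor* shear
   (ε_xy = γ/2); conversion to engineering shear happens only at this field
   boundary.

An optional *elastic-fragment mode* adds the two cortical fragments as
series springs whose modulus comes from the density–modulus power law
`E = 6570 · ρ_app^1.37` (MPa, ρ in g·cm⁻³); by default the fragments are
rigid and the power law is exposed but mechanically inert, since the
surrogate does not model bone voxel-wise.

This surrogate is **not** a patient finite-element model. It preserves the
two properties the downstream analysis chain actually needs: the strain
field is exactly linear in the applied load (hence in body weight at fixed
geometry), and the geometry depends on tibia length, which ties gap strain
to stature as a competing covariate. It does not reproduce patient-specific
strain magnitudes, asymmetric gap geometry, contact, or implant stress.
Consequences: avatar-level correlations between body weight and strain
medians come out *higher* (|r| ≈ 0.97–1.00) than a heterogeneous
patient-derived model would give, and sign changes across the gap caused by
real asymmetric geometry (e.g. tension anteriorly) appear here only through
bending, not through shape.

## Strain invariants

Per cell: hydrostatic strain `tr(ε)/3` (mean normal strain; the volumetric
strain `tr(ε)` is exposed as the trivially related alternative — the two
names are used interchangeably in the field and the choice only rescales,
leaving every Pearson correlation unchanged), octahedral shear strain
`(2/3)·√[(ε₁−ε₂)² + (ε₂−ε₃)² + (ε₃−ε₁)²] = 2√(2·J₂/3)`, maximum principal
strain (largest eigenvalue) and J₂ = ½·Σ devᵢⱼ². All four are rotation
invariant; J₂ and octahedral shear are non-negative and degree-2 /
degree-1 homogeneous. Eigenvalues come from `numpy.linalg.eigvalsh`;
symmetry is validated to 10⁻⁹ absolute at entry.

A mechanoregulation classifier maps (hydrostatic, octahedral shear) pairs
onto tissue-outcome labels over a user-supplied rectangular grid; bands are
closed below ([lo, hi)), so a value exactly on an edge starts the upper
band. Because published threshold sets differ and none is canonical here,
the classifier ships disabled with an explicitly illustrative example grid.

## Descriptive statistics and correlation battery

Each invariant field is summarized per avatar × landmark × region by mean,
median, IQR, MAD, P90 and P95. Conventions pinned for testability:
quantiles use linear interpolation between order statistics (the "type 7"
rule, numpy's default); IQR = Q3 − Q1 under that rule; MAD is the unscaled
`median(|x − median|)` (descriptive, not a robust-SD estimate, hence no
1.4826 factor). Summaries are unweighted per mesh cell by default
(area-weighted versions are available) because the reference workflow
evaluates per cell.

The battery correlates the avatar-level **median** of each invariant with
each of the four anthropometric parameters (weight, height, BMI, tibia
length), per landmark and region: 4 × 5 × 2 × 4 = 160 Pearson tests,
two-sided p-values from `t = r√((n−2)/(1−r²))`, flagged at α = 0.01. The
median is the statistic of record; the other five are computed and
exportable. OLS regressions (slope, intercept, r²) are available for the
same pairs.

## Cohort-resampling algorithms

Both algorithms use one stopping rule: a pair of cohorts "differs" when the
two-sided pooled-variance Student t-test gives p < 0.05 **and** the
pooled-SD Cohen's d satisfies |d| ≥ threshold. Pooled variance was chosen
over Welch for internal consistency with the pooled-SD effect size (Welch
is available behind a flag). For equal cohort sizes n the identity
`t = d·√(n/2)` makes the pair (p, d) a function of a single pivotal
statistic, which the tests exploit as a closed-form oracle.

**Algorithm A** repeatedly draws two disjoint simple-random cohorts of
n = 30 from the 300-avatar population until the rule fires on one chosen
parameter (default BMI, |d| ≥ 0.9), then the correlation battery can be
rerun per cohort. Iterations are independent fresh draws; non-termination
within the cap raises a dedicated `MaxIterationsError` rather than looping
forever. Note a structural property of this design: because both cohorts
are exchangeable draws from the *same* population, a pair exceeding d = 0.9
is a rare event (for the default population, order 10³ iterations), not an
iteration-1 event; an iteration-1 success is expected only when the two
cohorts come from genuinely separated subpopulations, in which case the
noncentral-t tail (ncp = Δ·√(n/2)) gives the firing probability (> 0.999
for Δ = 2 pooled SDs at n = 30).

**Algorithm B** asks the complementary question at scale: on a
metadata-only population (10⁶ subjects by default; analyses in this
repository use 10⁵, which leaves all sampling fractions ≤ 0.12 % and the
draws effectively i.i.d.), for cohort sizes 10–60 and d thresholds
0.5–0.9 (step 0.1), how many pair draws are needed on average until the
rule fires? Each (size, repeat) uses one fresh named random stream and
evaluates the **whole threshold grid on a shared draw sequence** (common
random numbers), so the nested-event monotonicity of the iteration count in
the threshold holds exactly in the output, not just in expectation. The
count is averaged over 100 repeats; runs hitting the iteration cap
(default 10⁶) enter the mean at the cap and are flagged as censored.

Under the same-distribution null the iteration count is geometric with
success probability `P(|t_{2n−2}| ≥ max(t_{0.975}, d_min·√(n/2)))`: ≈ 1/0.05
= 20 when the p-condition binds (small n or threshold), and e.g.
1/P(|t₉₈| ≥ 2.5) ≈ 71 at n = 50, d = 0.5. Once the d-condition binds, the
mean grows exponentially in n — at d = 0.9 the default population yields
≈ 20 iterations at n = 10 but ≈ 4·10⁴ at n = 50, which is the quantitative
sense in which anthropometric imbalance between equal-size trial arms
becomes practically impossible to sample at realistic trial sizes.

## Numerical and design choices

* **Seeding.** One master seed expands into named streams
  (`population`, `metadata_population`, `algorithm_a`,
  `algorithm_b/<size>/<repeat>`) via CRC-32-tagged `SeedSequence`s; any
  stage is reproducible in isolation and reruns are byte-identical.
* **Mesh.** Polar cells with exact sector areas and area centroids; the
  linear strain field makes region medians converge fast (doubling both
  resolutions moves them < 1 %).
* **Degenerate inputs.** Truncated sampling with sd = 0 returns the mean;
  zero-probability truncation intervals, non-positive anthropometrics,
  constant vectors in correlation/effect-size code, zero pooled SD, and
  malformed configs (unordered bounds, wrong landmark count, unknown keys)
  all raise with field-level messages.
* **Problem sizes in this repository's tests.** The full default experiment
  (300 avatars × 5 landmarks = 1500 simulation records) runs in seconds and
  is executed as-is; Algorithm B analyses use 10⁵ metadata subjects with
  100 repeats, and the exponential-growth check uses n = 20–30 at d = 0.9,
  where the effect is already two orders of magnitude.

## Known limitations

* All anthropometric defaults and the landmark load table are plausible
  stand-ins, not survey or database values; conclusions about *rates* (e.g.
  absolute iteration counts) depend on them, while the structural results
  (sign pattern of correlations, geometric law, exponential growth) do not.
* The surrogate's perfect linearity makes weight–strain correlations nearly
  1; real geometric heterogeneity would attenuate them.
* Height and BMI are sampled independently within age groups; any real
  height–BMI correlation would propagate into the battery.
* The mechanoregulation grid is illustrative only; no healing-time-course
  simulation is attempted.
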