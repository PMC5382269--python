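# Methods

This document records the model definitions, parameter conventions and
numerical choices behind `hydramem`. Units are nm, kJ/mol, bar and degrees
unless stated otherwise; coordinates live in orthorhombic periodic boxes
with the z axis along the membrane normal and the origin of all z-resolved
analyses at the midplane of the water layer.

## Physical constants and defaults

`hydramem.constants.Constants` collects the tunable physical parameters;
`DEFAULT_CONSTANTS` holds the defaults:

| parameter   | default | meaning |
|-------------|---------|---------|
| `T`         | 300 K   | temperature; `kT` = 2.4943 kJ/mol |
| `v_w0`      | 0.030 nm³ | molecular volume of bulk water |
| `hb_bulk`   | 1.796   | hydrogen bonds donated+accepted per bulk water, per molecule, under the same geometric criterion |
| `r_hb`      | 0.35 nm | donor–acceptor distance cutoff |
| `theta_hb`  | 30°     | hydrogen–donor–acceptor angle cutoff |
| `r_lj`      | 0.9 nm  | Lennard-Jones / Coulomb cutoff for insertion energetics |

Unit conversions use CODATA values: 1 kJ mol⁻¹ nm⁻³ = 16.6054 bar;
the Coulomb prefactor is 138.9355 kJ mol⁻¹ nm e⁻².

## Configurations and annotations

A `Frame` holds positions, the box and per-atom `AtomRecord` annotations:
molecule id, molecule class (`lipid`/`water`), leaflet, hydrogen-bond roles
(`donor`, `acceptor`, `hydrogen` — a hydroxyl oxygen is typically both
donor and acceptor), the parent heavy atom of each hydrogen, and partial
charge / LJ parameters for insertion energetics.

GRO files carry none of this chemistry, so it lives in a sidecar TSV keyed
on (resname, atomname); `merge_annotations` joins it onto a frame, resolves
hydrogen→parent indices from relative offsets, and assigns leaflets by the
sign of each lipid's midplane-relative z. Coordinates are written with six
decimals so frames round-trip to 10⁻⁶ nm; standard three-decimal GRO files
parse identically. Only orthorhombic boxes are supported; triclinic box
lines are rejected.

The water-layer midplane is located as the *circular* (periodic) mean of
the water-oxygen z coordinates, which is well defined even when the water
slab straddles the box boundary.

## Hydrogen-bond balance

A bond exists for a donor D (with covalent hydrogen H) and acceptor A when
r(D,A) < 0.35 nm **and** the H–D–A angle at the donor is < 30°. Both
inequalities are strict; pairs exactly at either cutoff are not bonds.
Candidate pairs come from a periodic k-d tree; every (D, H, A) triple is
recorded, so one donor can bond several acceptors. Intramolecular pairs
are excluded.

Bonds are classed ll (lipid–lipid), lw (lipid–water, either donation
direction, sub-tagged) and ww. The per-lipid balance at a hydration of
n_w waters per lipid is

    N_tot = N_ll + N_lw + N_ww,excess,
    N_ww,excess = N_ww,raw − n_w · 1.796,

so an unperturbed bulk-like slab contributes zero to N_tot. The change of
N_tot relative to the most hydrated state (`delta_hb_curve`) is the
quantity regressed against the interaction free energy. `bridging_hbonds`
counts, per headgroup, the waters hydrogen-bonded simultaneously to it and
to at least one other headgroup of the same leaflet.

## Chemical potential and equivalent pressure

μ(z) = μ_id(z) + μ_ex(z). The ideal part is kT ln(ρ(z)/ρ_ref) from the
water density profile; the thermal-wavelength constant is omitted since it
cancels in differences taken with the same convention. The excess part is
Widom insertion: per z bin and frame, `n_insertions` ghost particles are
inserted at uniform lateral positions and random rigid orientations, and

    μ_ex = −kT ln ⟨exp(−ΔU/kT)⟩.

Insertion energetics are pairwise Lennard-Jones, shifted to zero at the
cutoff, plus truncated-and-shifted Coulomb at the same cutoff (0.9 nm),
with Lorentz–Berthelot combining and minimum image. This truncated
electrostatics is a deliberate approximation adequate for the synthetic
test systems; the energy routine is isolated so an Ewald-based adapter
could replace it. Hard-sphere sites mark overlapping insertions as
infinite energy (zero Boltzmann weight).

Errors on μ_ex come from a bootstrap over contiguous insertion blocks
(default 10 blocks, 200 resamples). Bins whose Boltzmann factors all
underflow to zero are flagged unreliable and excluded rather than averaged.
Because μ_id and μ_ex vary strongly across the normal while their sum is
flat in equilibrium, `combine_mu` adds them on the same bin grid and then
averages over a central window, weighting by acceptance × insertions; the
reported error is the larger of the propagated statistical error and the
RMS deviation of μ(z) from flatness (a systematic-error floor).

The bulk reference μ0 is obtained by running the *same* estimator on a
bulk-water frame (single bin), so all conventions cancel in μ − μ0. The
equivalent interaction pressure is Π = −(μ − μ0)/v̄_w0 (positive =
repulsive, the stack still takes up water).

## Pressure–distance analysis

- **Exponential fits** are weighted least squares of ln Π versus D_w
  (σ_lnΠ = σ_Π/Π), via statsmodels; non-positive pressures are excluded
  with a warning.
- **Free energy per lipid**: G/N_l(D) = f·A_l·[∫_D^{Dmax} Π dD′ +
  Π0 λ e^(−Dmax/λ)], trapezoidal integration plus the analytic exponential
  tail. The default prefactor f = ½ assigns each shared water layer half
  to each adjacent leaflet; `per_lipid_factor=1` assigns it fully.
- **Bond-balance regression**: ordinary least squares of G/N_l against
  ΔN_HB, reporting slope, intercept, their standard errors, R², and
  whether the intercept is consistent with zero (|t| < 2).
- **Equilibrium separation**: the exponential repulsion is balanced
  against half-space van der Waals attraction −H/(12πD²); the minimum of
  g(D) is bracketed on a geometric grid and refined with Brent's method.
  The adhesion energy is approximated by the van der Waals part at D_eq
  (the exponential tail there is negligible), giving the D⁻² scaling used
  by `adhesion_ratio`.

## Thermo/elastic estimators

- D_w = 2 n_w v̄_w0 / A_l converts waters-per-lipid to a water-layer
  thickness (two leaflets share one layer); `hydration_from_dw` inverts it.
- Partial water volume v_w = dV/dN_w by a sliding centered quadratic fit
  (default window 5 points), exact for volumes quadratic in N_w, with
  parameter-covariance errors.
- K_A = k_B T ⟨A⟩ / var(A), errors from the SD of estimates over 8
  contiguous blocks; requires ≥ 10 samples per block.
- α_A = (1/⟨A⟩)·dA/dT from a linear fit.
- Π = −(kT/v̄_w0) ln(h_rel) converts relative humidity to an equivalent
  osmotic pressure; its uncertainty from a sensor accuracy δh is
  δΠ = (kT/v̄_w0)·δh·exp(Π v̄_w0/kT), growing exponentially toward strong
  dehydration.

## Diffraction reduction

Each lamellar reflection is fitted by a Gaussian on a constant background
(scipy `curve_fit`; windows need ≥ 7 points; two comparable maxima in one
window trigger a warning). The repeat distance follows from a straight-line
fit of peak position q versus order h: D = 2π/slope, with the slope error
propagated. The **free intercept** (default) absorbs a constant
instrumental q offset; `intercept="zero"` enforces strict Bragg behaviour.
The packaged DGDG measurement (`hydramem.datasets`) gives D = 54.03 ±
0.05 Å with the free intercept and, with a bilayer thickness of 41.7 Å,
a bilayer separation of 12.3 Å.

## Synthetic data: what is and is not emulated

The generators produce *geometric test fixtures with exactly known ground
truth*, not physical ensembles:

- `gen_lamellar_frame` builds two headgroup slabs flanking a water slab.
  Planted hydrogen bonds are placed at donor–acceptor distance 0.29 nm and
  angle 10° (safely inside the criterion); **every other** donor–acceptor
  pair is kept beyond 0.36 nm, so detection must recover the planted set
  exactly — a guarantee real simulation data cannot give. Maintaining that
  exclusion caps the water packing at ≈18 nm⁻³ (≈55% of bulk density), so
  the geometric water slab is thicker than the nominal D_w implied by
  (n_w, A_l, v̄_w0); the nominal value is carried as bookkeeping. Water
  dipoles are drawn so that ⟨cos θ_w⟩(z) follows a planted antisymmetric
  amplitude·tanh(z/ζ) profile exactly in the mean.
- `gen_bulk_water_frame` packs non-overlapping three-site waters at a
  requested density (feasible up to ≈43 nm⁻³) with random orientations.
  Its energetics are not those of liquid water; it serves as a geometric
  and statistical reference (e.g. bulk Widom runs are compared against a
  direct-summation oracle, not experiment).
- Fluctuation series (areas, volume-vs-N_w, area-vs-T), pressure–distance
  curves and diffraction patterns are drawn from the stated parametric
  models with planted parameters and additive/multiplicative Gaussian
  noise, for recovery tests.

Defaults mirror the physical study conditions: 50 lipids per leaflet,
A_l = 0.78 nm², up to 8 hydroxyls per headgroup, n_w = 20 waters per
lipid.

## Numerical choices

- Both hydrogen-bond inequalities strict; the angle test is evaluated on
  cosines to avoid an arccos per candidate.
- Periodic neighbor searches use `scipy.spatial.cKDTree(boxsize=...)`,
  with positions nudged below the box edge to satisfy its half-open
  interval requirement.
- Boltzmann exponents are clipped at ±700 before exponentiation; hard-core
  overlaps contribute exact zeros.
- Exponential pressure fits operate in log space (WLS/OLS); diffraction
  peak fits in linear space (nonlinear least squares).
- The equilibrium-separation search brackets the derivative's sign change
  on a geometric grid over 0.02–50 nm before Brent refinement.
- Random numbers come from `numpy.random.default_rng`; every generator and
  estimator that samples takes an explicit seed.

## Limitations

- Orthorhombic boxes only; no triclinic support.
- Truncated-and-shifted electrostatics (no Ewald); adequate for the
  synthetic fixtures, not for production force-field energetics.
- Single-configuration inputs are treated as independent frames; no
  autocorrelation analysis beyond block averaging/bootstrap.
- The synthetic lamellar water slab is sub-bulk density by construction
  (see above), so density-derived quantities from these fixtures are
  internally consistent but not bulk-calibrated.
- The adhesion energy neglects the exponential-tail contribution at D_eq
  and assumes equal Hamaker constants when ratios are formed.
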