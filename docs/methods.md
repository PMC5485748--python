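# Methods

`mealf` simulates electric bioimpedance measurements of single biological
cells on planar microelectrode arrays (MEAs) and analyses the sensitivity
of measurement constellations with lead-field (reciprocity) theory.  This
note records the physical model, the numerical scheme, the defaults and
the design decisions a user or maintainer needs to interpret results.

## Physical model

**Field problem.** The bath and cell interior are quasi-static volume
conductors with complex conductivity σ* = σ + jωε₀εr; the potential obeys
∇·(σ*∇φ) = 0.  No wave propagation or magnetic induction is modelled: at
the ≤1 MHz, sub-millimetre scales of MEA impedance spectroscopy the
electro-quasistatic approximation is excellent.  Default materials:
phosphate-buffered saline bath (σ = 1.57 S/m, εr = 77) and cytoplasm
(σ = 3 S/m, εr = 80).  The source text is ambiguous about whether
"3 S/m and 80" describes the bath or the cell interior; we assign it to
the cytoplasm and keep both overridable.

**Electrodes.** 30 µm diameter discs on the insulating substrate plane
y = 0 — a bipolar pair at x = ±50 µm, plus an outer drive pair at
x = ±150 µm in the tetrapolar layout.  Each disc is an equipotential
metal terminal behind a distributed contact film whose specific impedance
derives from the measured titanium-nitride interface circuit

    Z_el(ω) = R/(1 + jωRC) + 1/(CPE_T (jω)^CPE_P),

with fitted values CPE_T = 2.819·10⁻⁸ S·s^P, CPE_P = 0.595,
R = 46.26 MΩ, C = 2.59 nF.  The bulk series resistance R_B = 3.789 kΩ of
the measured circuit is *not* part of the film — the resistive bath is
modelled explicitly.  Note the CPE coefficient: the magnitude 2.819·10⁸
sometimes quoted for this fit is dimensionally inconsistent with the
MΩ-scale measured spectrum under the admittance convention used here; the
10⁻⁸ coefficient reproduces the measured magnitudes and is the default
(`cpe_t_convention="literal"` restores the other reading).

**Surface-roughness scaling.** Sputtered TiN electrodes have an
effective surface area roughly 10× their geometric footprint.  The
reference COMSOL model represented this by inflating the geometry 10×
while keeping the measured lumped Z_el on each (enlarged) disc.  Surface
films transform as z_s → L·z_s under a length scaling L, so the
scale-free equivalent on the true 30 µm disc is

    z_s(ω) = Z_el(ω) · A_disc · area_scale,   area_scale = 10.

Every normalized (ratio) quantity is invariant under this equivalence;
raw spectra carry the overall factor 10 of the scale transformation.
This convention is what makes the film co-dominate the disc current
distribution at sweep frequencies — with a 10× *weaker* film the disc rim
singularity dominates and the bipolar sensitivity profile peaks 10 µm off
the electrode centre, contradicting the reference behaviour.

**Cells.** A non-adherent cell is a sphere of radius r₀ = 10 µm; an
adherent cell is a spherical cap of height h = r₀ + y₀ and cap radius
r = 4r₀³/(3h²) + h/3, which conserves the free-sphere volume exactly
(at y₀ = r₀ the cap degenerates to the sphere).  The cap is lifted
500 nm off the substrate by the cell–surface gap, which is meshed as
medium-filled space and excluded from the radius computation.  The
membrane is a thin-film boundary with specific impedance
z_m = 1/(g_m + jωc_m), defaults g_m = 1 mS/cm², c_m = 1 µF/cm².
Mapping the scaled reference model back to true size leaves these printed
values unchanged if (as stated there) the cell impedance was re-scaled
with the geometry; had the films been entered unscaled, the equivalent
would be 10× the admittance, moving the membrane corner into the band
and the normalized-spectrum maximum from ~500 kHz toward ~100 kHz.  We
take the statement at face value and use the printed values.

**Lead fields.** For a measurement with current-feeding pair LI and
voltage-sensing pair LE, the sensitivity field is S = J_LE · J_LI of the
two unit-current lead fields; a local impedivity change shifts the
transfer impedance by ΔZ = ∫ S Δρ dV with Δρ = 1/(σ+Δσ) − 1/σ (the form
sometimes printed with a division by Δσ is dimensionally inconsistent
with the underlying theorem; the first-order Δρ form is implemented).
For complex fields, S is visualized with the real dot-product convention
Re·Re + Im·Im; the unconjugated complex product enters ΔZ.  The
volume-averaged normalized sensitivity of a cell at (x₀, y₀) is the
volume-weighted mean of S over elements whose centroid lies in the cell
shape, divided by the maximum of the same quantity over the scanned
positions at the lowest height (so the scan maxima read 100%);
normalization by the elementwise field peak is available instead.  Lead
fields default to 100 kHz — the profiles are conduction-dominated and
move by < 0.5 points between 1 kHz and 100 kHz.

## Numerics

**Mesh.** A deterministic structured tetrahedral mesh: each axis is
subdivided with uniform fine spacing (default h = 2.5 µm) inside
refinement windows around electrodes and scanned cell positions, and
geometric coarsening (factor 1.35, cap 40 µm) elsewhere; each hexahedral
cell splits into six tetrahedra (Kuhn subdivision, conforming).  An
explicit grid plane at y = 0.5 µm resolves the cell–substrate gap with
one element layer.  Elements are labeled cytoplasm/medium by centroid
membership; membrane nodes are duplicated so the film can couple the two
sides; rim facets of each electrode disc carry fractional coverage
weights (16-point subdivision) so the represented disc area is accurate
to O(h²).  The bath defaults to an 800 × 400 × 400 µm box (the reference
does not state one; doubling it moves scan percentages by < 0.1 point).
All reference configurations are symmetric about z = 0, so the default
mesh models the half-space z ≥ 0 with an insulating symmetry plane and
the solver feeds I_T/2; set `symmetry="none"` for off-plane cells.

**Assembly and solve.** P1 tetrahedra; electrode films enter as facet
mass matrices coupling surface nodes to one terminal unknown per
electrode, with net-current constraints (I_T on the drive pair, zero on
floating recording electrodes — an ideal infinite-impedance amplifier
reads the terminal voltage behind the film).  The membrane adds a
(φ_med − φ_cyt)/z_m jump coupling.  The gauge is fixed at a far-corner
node, which is exact for balanced terminal currents and lets a single
sparse LU factorization serve every drive at one frequency.  The complex
system is ordered by geometric nested dissection with grid-plane
separators (an order of magnitude faster than the generic orderings
shipped with SuperLU on these meshes) and factorized by SuperLU;
iterative refinement pushes the relative residual to ≤ 1e-10.  Ideal
contacts (verification runs) are films at 10⁻⁵ of the patch's
spreading-resistance scale — negligible physically, benign numerically.

**Verification.** The plate-terminal box reproduces L/(σA) to the film
drop (~10⁻⁵); discrete reciprocity holds to machine precision; terminal
currents balance to solver precision.  The ideal-disc spreading
resistance converges to 1/(4σa) with an O(h) error from the rim
singularity (the equipotential patch effectively extends one node-support
beyond the rim); two refinement levels bracket the closed form and their
linear Richardson extrapolation lands within 0.5%.  The first-order
perturbation integral agrees with direct two-solve differences within
10% for ≤10% conductivity perturbations.

**Position sweeps.** One mesh and solve per cell position at the sweep
frequency (default 100 kHz, the figure-caption convention; the
conflicting 100 Hz reading of the reference's results text is available
through the sweep configuration).  The background grid is identical for
the baseline and every position — the refinement window spans all
scanned positions — so baseline discretization error cancels in the
normalized difference (|Z|−|Z₀|)/|Z₀|.

**Resolutions used for reported numbers.** The acceptance script runs
the two-electrode sensitivity scan at h = 2.0 µm (scan percentages move
< 2 points from h = 2.5 to 2.0 and < 2 further on extrapolation), the
two-electrode sweep at h = 2.5 µm and the four-electrode model at
h = 3.0 µm; the test suite uses h = 4–5 µm, where the same ratios are
stable to a couple of points.  Meshes range from ~2·10⁴ to ~10⁵ nodes.

## Known limitations and discrepancies

- The four-electrode sensitivity field crosses zero over each
  recording-disc centre; the signed cell-volume average there is ~10% of
  the scan maximum, not the ~50% reported for the reference model.  The
  reference is internally inconsistent on this point — its own direct
  simulations leave the spectrum "almost equal to the baseline" for a
  cell on the electrode centre, and its "almost zero at the excitation
  centres" claim relies on the same lobe cancellation.  All neighbouring
  features (edge maxima at x₀ = 35/65 µm, near-zero excitation centres,
  ~30% between electrodes, y₀ = 15 at 40–50% of the y₀ = 5 curve,
  rank-correlated sweep and scan trends) are reproduced.
- Our four-electrode sweep gives an asymmetric pair of excitation-edge
  deviations (~60% inner, ~36% outer edge of the sweep maximum); the
  reference quotes a single "approximately 40%".
- The mirror symmetry of profiles holds to discretization error only
  (the Kuhn split is not mirror-symmetric); at test resolution the
  asymmetry reaches a few percent off-peak.
- Cells are passive, homogeneous, and single; electrode kinetics are
  linear; the medium is spatially uniform.  Synthetic electrode spectra
  used by the circuit-fit tests share the model's functional form —
  recovery results say nothing about model mismatch on real electrodes
  beyond the residual levels reported by the fit itself.
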