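# Methods

## Scope and model

`hydrashell` predicts solution small-angle X-ray scattering (SAXS) from
explicit-solvent configurations and extracts two footprints of the
hydration shell:

1. the **shell contrast** ΔNe_hs — the excess electrons the shell carries
   relative to an equal volume of bulk water, reported in water-molecule
   equivalents ΔNe_hs/10;
2. the **hydration-induced Rg shift** ΔRg = Rg_SAXS − Rg_prot, where
   Rg_SAXS comes from Guinier analysis of the computed curve (and thus
   includes the shell) and Rg_prot is the electron-weighted radius of
   gyration of the bare solute coordinates.

The forward scattering obeys I(0) = (ΔNe)², with

    ΔNe = ΔNe_prot + ΔNe_hs = (Ne_prot − ρ_solv·V_prot) + ΔNe_hs,

ρ_solv = 334 e/nm³. Ne_prot is the sum of zero-angle Cromer–Mann form
factors of the solute atoms; V_prot is the probe-excluded (cavity)
volume. The sign of ΔNe is taken from the signed zero-angle amplitude
difference Re[⟨A(0)⟩ − ⟨B(0)⟩] that the explicit-solvent calculation
provides directly, so the ± ambiguity of √I(0) never arises.

## Scattering estimator

Per scattering vector, the instantaneous amplitude of a frame is
A(q) = Σ_j f_j(|q|) exp(iq·r_j) over the solute plus all water molecules
whose oxygen lies inside the envelope (a whole-molecule rule keeping
10-electron units intact). The envelope is the distance-d dilation
(d = 9 Å default) of the union of solute coordinates over all frames;
the identical envelope filters the matched pure-water buffer ensemble,
whose frames are first recentered onto the envelope. The
buffer-subtracted intensity per direction is

    I = |⟨A⟩−⟨B⟩|² + (⟨|A|²⟩−|⟨A⟩|²) − (⟨|B|²⟩−|⟨B⟩|²),

the unique quadratic estimator consistent with I(0) = (ΔNe)² for
independent system/buffer ensembles: at q = 0 the fluctuation terms of
system and buffer cancel in expectation (for Poisson particle numbers
they cancel within the quoted statistical error, which is how the
forward-scattering contract is tested). Orientational averaging uses a
deterministic Fibonacci point set of J directions per |q| (J = 200
default); errors come from contiguous block resampling (10 blocks
default). An optional solvent-density correction rescales buffer
amplitudes by γ = ρ_target/ρ_measured, with ρ_measured the mean buffer
electron density inside the envelope (Monte-Carlo envelope volume).

Units: q in nm⁻¹ everywhere at the API; the conversion to the Å⁻¹
s-convention of the Cromer–Mann fit happens inside `formfactors` only.
Lengths are Å internally; GRO input (nm) is converted at the boundary.

## Guinier analysis

Weighted least squares of ln I against q² with variance (σ/I)², windowed
iteratively until q_hi·Rg ≤ qRg_limit is self-consistent (limit 1.3 by
default, the community standard; non-positive intensities are skipped).
For sharp-interface globular bodies the quartic term of ln I biases the
fitted Rg upward by ≈1.7% at the 1.3 window (computable exactly on the
ideal sphere form factor); analyses of such bodies should use a tighter
window — the validation suite uses qRg ≤ 0.8 for the uniform ball, where
the bias is ≈0.7%.

## Cavity volume

V_prot is the volume enclosed by the probe-rolled surface: a point is
excluded iff no allowed probe center (≥ probe radius from every atom
surface; Bondi radii, hydrogens included) lies within the probe radius.
The implementation evaluates the exact signed distance
D(x) = min_j(|x−c_j|−r_j) at the centers of a 0.16 Å grid and then uses
the 1-Lipschitz property of D: every grid point v with D(v) ≥ p
certifies accessibility of all points within |x−v| ≤ D(v). Exclusion is
therefore a power-distance (Laguerre) test min_v(|x−v|² − D(v)²) > 0,
computed in O(N) with a separable lower-envelope transform. This keeps
the boundary sharp well below the voxel size: a single Bondi sphere
evaluates to its analytic volume within ~0.5%. The grid origin receives
a random sub-voxel offset per draw so that voxel counting is unbiased in
expectation, and the result is averaged over 20 randomly rotated frames
(1 SE over the draws quoted). probe = 0 reduces exactly to the van der
Waals union; interior voids too small for the probe count as excluded.

## Synthetic data: what it emulates and what it does not

The generator stands in for restrained MD of a hydrated solute:

- **Solute**: a rigid bead model (sphere/rod/chain) of point scatterers
  with a flat form factor. The default sphere study uses 500 beads of
  6 e in a 10 Å ball — electron density ≈ 440 e/nm³ and bead spacing
  ≈ 2 Å, protein-like in both respects.
- **Water**: ideal-gas placement — Poisson counts at 33.4 molecules/nm³
  (334 e/nm³ at 10 e per molecule), uniform positions, rigid
  O + 2H geometry (0.96 Å, 104.5°) with random orientation. A
  `hard_core` mode (O–O ≥ 2.6 Å) exists to exercise RDF structure.
- **Exclusion**: no water oxygen within 2.8 Å of a bead center. Beads
  carry vdW radius 2.8 Å so that the cavity volume matches the region
  actually unavailable to water — the property that closes the contrast
  bookkeeping. The probe-rolled surface still slightly exceeds the exact
  exclusion union (probe-inaccessible crevices between beads), a
  systematic ≈0.1 nm³ (≈3 waters) for the default sphere; it is common
  to all variants of a series and cancels exactly in relative scores.
- **Shell signal**: exactly ΔN molecules added to (or removed from) the
  band [shell_inner, shell_outer] of distance to the nearest bead,
  per frame. Variant series share the base-water realization per frame
  (common random numbers), so inter-variant differences carry almost no
  sampling noise — the intended analogue of mutants sharing a backbone.

What passing tests therefore show: the estimator, envelope bookkeeping,
volume definition and decomposition recover known ground truth under
ideal-gas water. What they do not show: water–water structure factors,
force-field-specific shell densities, conformational flexibility — those
require MD input, which the pipeline accepts as PDB/GRO frame
directories but cannot generate.

## Study conditions used in the validation suite

- Sphere recovery: R = 10 Å, 500 beads × 6 e, box 54 Å, 100 frames per
  ensemble (60 in the acceptance script), envelope d = 9 Å, shell band
  2.8–6 Å, injected ΔN ∈ {−10, 0, +15} and a 6-variant per-site series
  {0, +1.5, −0.3, +0.5, +1.0, −1.0} waters/site on 10 labeled sites.
- Rg-shift study: rod of 60 beads × 12 e over 30 Å (net positive
  contrast ≈ +440 e, as for electron-dense proteins), shell band 4–8 Å,
  ΔN = +25 (excess) and −10 (deficit), 150–200 frames. The deficit must
  not exceed the net solute contrast: a larger deficit drives the
  contrast-weighted Rg² negative and the Guinier regime disappears —
  a real feature of mixed-sign contrast densities, not an artifact. Both
  cases are checked against a direct Monte-Carlo quadrature of the
  contrast-density Rg integral on the known synthetic density.

## Numerical choices

- Double precision throughout; amplitudes are streamed (mean and
  mean-square accumulators), never stored per frame.
- Block errors: contiguous equal blocks, remainder to the last block;
  SE = SD(block means)/√n_blocks. Ensembles of independent
  conformations use SD/√n directly.
- Monte-Carlo envelope volumes: binomial SE; ≥10⁴ samples enforced.
- Degenerate inputs: empty solvent selections are valid (buffer frames
  far from the envelope); single-frame ensembles get zero SE; Guinier
  windows shrink to a 5-point minimum before erroring.
- Determinism: every stochastic step derives its generator from
  (seed, fixed stage offset, frame index) via `SeedSequence`, so outputs
  are pure functions of the config seed; the pipeline writes tables with
  fixed formatting and is byte-reproducible.

## Known limitations

- Ideal-gas water has no structure factor; finite-q fluctuation terms of
  the estimator are validated only for contracts that do not depend on
  water–water correlations.
- The estimator's fluctuation treatment at finite q is the variance
  difference form; other explicit-solvent codes may treat the
  solvent-density correction term differently at finite q.
- Orthorhombic boxes only; no trajectory binary formats (frames are
  coordinate files); no WAXS corrections, neutron contrasts, or
  experimental-curve fitting.
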