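# Methods

## The model

`micellekin` integrates a closed, size-structured reaction network for
in vitro prion amyloid formation.  Four populations are tracked: native
monomer PrP^C (`c`), micelle-like clusters of `i` monomers (`m_i`,
`i = 2..I_max`), the amyloid-competent monomer isoform PrP\* (`v`), and
PrP\* aggregates of `j` monomers (`u_j`, `j = 2..N_max`) — unstable
oligomers below the nucleus size `n`, stable PrP^Sc polymers at and
above it.

Assumptions, in order of appearance along the pathway:

1. **Micelle ladder (Becker–Döring).**  Clusters change size by single
   monomer steps.  Association is size-independent (`a_mic`) and equal
   for both isoforms.  The smallest cluster is a dimer formed from two
   free monomers; the dimer-formation flux consumes two monomers.
2. **Conversion inside micelles.**  A micelle can release either isoform.
   Release partitions by size through the default `surface_power` law:
   PrP^C at `q_C·i^(-1/3)` (dominant for small clusters, where the
   curvature-dependent chemical potential dominates) and PrP\* at
   `q_S·(1 − i^(-1/3))` (dominant at large size; effectively zero for
   the smallest clusters, which do not transconform).  Alternative laws
   with the same asymptotics can be registered
   (`micellekin.rates.register_depletion_law`).
3. **Nucleation.**  Only PrP\* oligomerizes; PrP^C cannot reach the
   nucleation barrier directly.  Sub-nucleus steps are reversible with
   off-rate `d_off`; beyond the nucleus, polymerization is irreversible
   (`depolym_j = d_off` for `j ≤ n`, `0` for `j > n`).
4. **Fragmentation.**  All aggregates (oligomers included) split
   binarily at rate `beta·j` with the uniform probability kernel
   `kappa(k, j) = 1/(j−1)`; each split yields two fragments, and size-1
   fragments return to the PrP\* pool (to the PrP^C pool in the
   comparator).
5. **Mass conservation.**  The vector field conserves
   `c + Σ i·m_i + v + Σ j·u_j` identically; both ladders end in no-flux
   boundaries so the truncated system conserves mass exactly, not just
   asymptotically.

The nucleation-dependent comparator (`baseline`) removes the micelle
and conversion steps: PrP^C nucleates and elongates polymers directly.
It is a configuration of the same engine (micelle rates zeroed, the
elongating pool switched), so the fragmentation bookkeeping and
conservation structure are shared rather than reimplemented.

## Default parameters

Concentrations are in mg/ml and times in hours throughout.  No rate
constants for this system are available as published tables, so the
defaults are the package's own calibration, chosen once to place the
model in the regime the in vitro phenomenology demands — sigmoidal
conversion on the ~10 h scale at 1 mg/ml, a micelle population that
rises and decays ahead of polymerization, seeding responses limited by
conversion rather than nucleation — and kept fixed thereafter.

| parameter | default | units | role |
|---|---|---|---|
| `a_mic` | 0.1 | (mg/ml)⁻¹ h⁻¹ | micelle association, both isoforms |
| `q_C`   | 0.06 | h⁻¹ | PrP^C release prefactor (small-size dominant) |
| `q_S`   | 2.0 | h⁻¹ | PrP\* release prefactor (large-size dominant) |
| `tau`   | 6.0 | (mg/ml)⁻¹ h⁻¹ | elongation by PrP\* |
| `d_off` | 0.2 | h⁻¹ | sub-nucleus off-rate |
| `n_nucleus` | 4 | — | nucleus size |
| `beta`  | 0.004 | h⁻¹ | fragmentation per size unit |
| `I_max`, `N_max` | 3000, 5000 | — | ladder truncations |

Two structural features of this default regime matter for
interpretation:

* **Sub-critical conveyor.**  With `a_mic·c0 < deplete(2)`, micelles
  form as a transient population of small clusters whose quasi-steady
  occupancy scales superlinearly with `c`.  Conversion throughput
  therefore *rises* with concentration, giving the weak negative
  log-log dependence of t½ on `c0` (slope ≈ −0.43, apparent nucleus
  size ≈ 0.85) that is the model's signature — and giving it
  identically for every nucleus size, because the lag reflects
  conversion, not a nucleation barrier.
* **Thermodynamic ordering of the oligomer regime.**  Sub-nucleus
  elongation is unfavourable at the PrP\* concentrations where the
  system spends most of its time: `tau·v < d_off` for
  `v ≲ 0.03 mg/ml`, which covers the late stage (v ≈ 0.01).  During
  the early conversion burst v transiently exceeds this level — that
  transient is exactly what lets nucleation proceed regardless of `n`.

The comparator's defaults (`tau = 6`, `d_off = 200`, `beta = 0.001`,
`n = 4`) put it in the classical strongly-unfavourable nucleation
regime: a pronounced lag that collapses under seeding, postponed
seeding delays t½ by the full delay, and a concentration scaling that
steepens with nucleus size.

## Experiment designs

`micellekin.experiments` fixes the study conditions used by the tests,
the acceptance script and the CLI examples:

* **Default unseeded run** — `c0 = 1 mg/ml`, 100 h, full truncation
  (3000/5000).
* **Concentration scans** — one decade, `c0 ∈ geomspace(1, 10, 5)`,
  unseeded, for nucleus sizes {2, 4, 6} in both models.
* **Seed scans** — three decades of seed mass,
  `geomspace(1.5e-4, 0.15, 7) mg/ml` as monodisperse 50-mers, at
  `c0 = 0.5 mg/ml`.  Seeding protocols run at lower monomer
  concentration than the unseeded scans so that spontaneous nucleation
  in the comparator stays negligible against the smallest seed, and the
  largest seed stays below half of the final plateau.
* **Postponed seeding** — seed mass 0.15 mg/ml injected after delays of
  1, 2 and 3 h, against the zero-delay control.
* **Scan truncation** — scans use `I_max = 300`, `N_max = 600` (and the
  recovery harness 100/300).  In the default regime micelle occupancy
  is confined to small sizes and the polymer distribution stays two
  orders of magnitude below these boundaries (the boundary-mass
  diagnostic warns if more than 1% of mass sits within 5 sizes of a
  boundary), so scan-truncated and full-truncation results agree to
  solver accuracy.
* **Parameter recovery** — the calibration layer refits `a_mic` and
  `q_S` (the micelle-rate constants; polymerization constants frozen)
  to half-time curves generated by the model itself, from starts
  perturbed ±18%, noiseless and with 5% multiplicative noise on the
  observed half-times.  Residuals are log half-time differences, since
  half-times span orders of magnitude across seed scans.  Fits are
  bounded local least squares in log-parameter space with optional
  seeded multi-start; a finite-difference sensitivity matrix flags
  unconstrained parameters instead of reporting them silently.

## Numerics

* `scipy.integrate.solve_ivp` with LSODA (stiffness-switching) by
  default, `rtol = 1e-8`, `atol = 1e-12`; the right-hand side is fully
  vectorized (the fragmentation gain is a suffix sum, O(N) per
  evaluation).  Relative mass drift on the default run is ~1e-15,
  far inside the 1e-6 requirement.
* Comparator runs use `atol = 1e-18`: spontaneous nucleation passes
  through sub-nucleus concentrations near 1e-10 mg/ml that a looser
  absolute tolerance would silently truncate to zero, leaving the
  system stuck at the oligomer quasi-equilibrium.
* Postponed seeding is integrate–stop–inject–reintegrate with state
  continuity; the conserved total jumps by exactly the seed mass at the
  seed time, and the mass residual is checked against that step
  profile.
* Negative excursions within 10× the solver tolerance are clipped to
  zero in the reported trajectories; anything larger raises an
  integration error rather than being masked.
* Half-times interpolate the first crossing of half the plateau, where
  the plateau is the mean of the final 10% of points, required to vary
  by < 1% (both fractions tunable).  Slopes use a Savitzky–Golay cubic
  local fit with a window of 5% of the trace (≥ 5 points); non-uniform
  grids are resampled.  Halving the solver tolerances moves t½ by
  < 0.1%.

## Conventions adopted where the literature varies

* **Lag time** — tangent at the inflexion: `lag = t½ − plateau/(2·k_max)`,
  floored at zero; exact for curves symmetric about t½.
* **Apparent nucleus size** — `n_app = 2·|slope|` from the scaling
  `t½ ∝ c0^(−n/2)`; the `2·|slope| − 1` convention is available.
* **Sigmoid family** — Boltzmann (logistic) four-parameter fits;
  `k_max = amplitude/(4·width)`.
* **Seed geometry** — monodisperse 50-mers; the seed length
  distribution is not constrained by the data this emulates.
* **Unit conversion** — mg/ml ↔ molar helpers assume 16.1 kDa
  (rPrP 90–231) unless overridden; this is a package default, not a
  measured input.

## The synthetic-data generators

The generators emulate the *structure* of the three measurement types,
not any particular instrument: ThT traces are logistic sigmoids
(parameterized by plateau, t½, k_max) sampled in triplicate with
multiplicative Gaussian noise; micelle diameters are log-normal with
the log-mean set so the distribution mean hits the target (30 nm,
σ = 0.35 by default); micelle counts are Poisson (optionally negative
binomial) with mean proportional to the simulated micelle number —
count data, as on arbitrarily selected microscope grids.  The
surface-geometry helper `micelle_protein_count` is the plain area
ratio `floor(4·(D/d)²)` — about 10³ proteins of 1.9 nm on a 30 nm
sphere — with an optional packing-fraction correction (0.9069).

Passing the recovery and analysis tests on these synthetics shows that
the pipeline is self-consistent under the stated noise models; it does
not show robustness to instrument drift, baseline fluorescence decay,
biphasic kinetics or non-log-normal size mixtures, none of which the
generators produce.

## Known limitations

* With the shallow `i^(-1/3)` depletion law and default rates, the
  simulated micelle population is dominated by small clusters; the
  package does not calibrate the simulated cluster-size distribution to
  the ~30 nm (≈10³-monomer) objects seen by microscopy, which enter
  only through the synthetic diameter generator and the geometry
  estimate.  A steeper registered depletion law can shift the balance.
* The polymer-mass sigmoid is asymmetric (fast rise, slow tail), so
  tangent-based lag and fitted-sigmoid midpoints differ at the few-
  percent level from the direct half-time; the direct t½ is the
  primary observable throughout.
* Dynamics are deterministic mass-action ODEs; the low-concentration
  regime where nucleation becomes stochastic is out of scope.
* The comparator's spontaneous kinetics mix nucleation-limited and
  fragmentation-amplified behavior; its concentration-scaling exponents
  are regime-dependent and are reported for the default design only.
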