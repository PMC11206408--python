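# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Units and constants

Lengths are Å, times ps, energies kcal mol⁻¹, charges elementary-charge
units. R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹; k_B and h are the exact SI
values, giving an Eyring prefactor k_B·T/h = 6.462×10¹² s⁻¹ at the default
temperature of 310.15 K (the thermostat temperature of the simulations
the pipeline targets). Coulomb energies use 332.0637 kcal Å mol⁻¹ e⁻².
All boxes are orthorhombic and all distances use the minimum-image
convention applied per Cartesian axis.

## Membrane geometry

The reference plane is the per-frame mean z of the upper-leaflet phosphate
(P) atoms; its spread σ_z uses the population convention. Leaflets are
assigned statically: a P atom whose time-averaged z lies above the
bilayer midplane (the all-frame mean of P z, which coincides with the box
midplane for the systems modelled but is robust to the coordinate origin)
is "upper". No flip-flop is assumed at the simulated timescales.

Penetration depth is Δz(residue, frame) = mean_z(upper P) − z(cog), with
the **centre of geometry** (unweighted, not mass-weighted). The sign
convention — exported in the profile metadata — is Δz > 0 for residues
buried *below* the phosphate plane. A residue is flagged buried when its
deepest excursion passes the pooled x̄ − σ band of the phosphate z
distribution, i.e. max Δz > pooled σ_z; pooled (all-frame) statistics are
used rather than per-frame ones, matching the shaded-band presentation
such profiles are read against. Flagged residues contiguous in sequence
numbering merge into hotspots.

In-plane density maps are xy histograms over all frames; optional
smoothing uses an isotropic Gaussian with σ given in Å (converted to
bins) and periodic wrapping, which conserves total counts exactly.
Residue–substrate profiles take the per-frame minimum over atom pairs;
the 5 Å contact-shell cutoff is a strict less-than.

## Solvation

g(r) is normalised by ρ_ref = (population count)/(box volume) and exact
spherical-shell volumes; the cumulative count n(r) is counted directly
rather than integrated, so the quadrature identity
n(r) ≈ ρ_ref ∫ g 4πs² ds is a meaningful internal consistency check
(midpoint quadrature makes it accurate to ≪1% once r spans a few bins;
immediately at the origin the midpoint rule misstates shell volumes, a
region where physical RDFs have no support). r_max must not exceed half
the smallest box edge. The reference point may be a single atom or the
per-frame midpoint of two atoms (e.g. the His-Nδ–C_substrate vector
midpoint used for active-site hydration). Default bin width 0.1 Å;
optional Gaussian smoothing of g(r) is specified in bins. The two-shell
water analysis defaults to [2.5, 3.2) and [3.2, 4.4) Å. Coordination
numbers count ligand atoms (oxygen selections by convention) within a
cutoff, averaged over frames.

SASA uses the Shrake–Rupley construction: 960 deterministic golden-spiral
points on each target's expanded sphere (r_vdw + 1.4 Å probe); a point is
buried if inside any neighbour's expanded sphere. Van der Waals radii are
the Bondi set, element-keyed and overridable. At 960 points an isolated
sphere is reproduced to well under 1%.

## Conformational classification

Criteria (strict inequalities, ties → non-productive):
d(Nδ–H_W) < 2.5 Å for the His hydrogen bond, d(C–O_W) < 4.0 Å for
nucleophilic attack, d(O_W1–H_W2) < 2.5 Å for the relay bridge. A lone
water meeting both the H-bond and attack criteria forces *single-water*;
only otherwise is the two-water relay tested (the categories are treated
as disjoint alternatives). Hydrogen ambiguity is resolved by minimising
over each water's two hydrogens; candidate waters are restricted to
oxygens within 8 Å of the substrate carbon (a performance guard that
cannot exclude a qualifying water, since the attack criterion is 4 Å).
The summary record keeps the nucleophile (water nearest the carbon) for
the Ca²⁺–water distance.

Microstate clustering runs on a 2-distance plane (default
d(Nδ–C) vs d(Ca²⁺–O_substrate)): a gridded Gaussian KDE (width 1.0 Å,
grid 0.05 Å, 3σ padding), thresholded at a quantile (default the median)
of the grid-cell densities; cells above threshold form 8-connected
components and each record joins the component containing its cell, else
noise. Thresholding on grid-cell rather than per-point densities keeps
well-separated clusters intact (each cluster retains essentially all its
members) while still discarding low-density stragglers.

## Free energy (WHAM)

Windows carry a CV series, harmonic bias centre and force constant, and a
discard fraction (default 0.2 — the leading fifth of each window is
treated as restraint equilibration, mirroring the convention of dropping
2.5 ps of 12.5 ps windows). Equilibration is judged by time-block
analysis: the retained series is split into 4 equal blocks and each
block's histogram compared with the pooled one via the Bhattacharyya
coefficient; all coefficients ≥ 0.9 passes.

The solver iterates the standard self-consistency pair (see README) with
the first window's offset anchored at zero, until max|Δfᵢ| < 10⁻⁷
(default), on a uniform grid of 0.05 Å bins spanning the sampled range.
Empty terminal bins are truncated; empty interior bins are treated as
missing with a warning rather than assigned infinite F; adjacent windows
without histogram overlap trigger a warning naming the gap, and a fully
disconnected chain is an error. Profile features locate the reactant and
product minima inside caller-stated ξ ranges and the transition state as
the interior maximum between them. Statistical error bands come from a
block bootstrap (50 resamples, 50-sample blocks) and are advisory.

Only 1-D profiles are reconstructed; multi-CV cases are assumed projected
onto a band coordinate upstream.

## Synthetic data

The generators are pure functions of (spec, seed) and emulate exactly the
statistical structure the analyses assume — no more:

* **Membrane**: upper/lower-leaflet P atoms at z ~ N(±plane_z, σ_plane)
  with uniform xy; one cog-marker pseudo-atom per protein residue at
  z = plane_z − depth_mean + noise. Default σ_plane 1.5 Å, plane at
  ±20 Å, box 93.21 × 88.40 × 103.30 Å. Not emulated: lipid chains, area
  fluctuations, curvature.
* **Active site**: per frame a state is drawn from the mixture
  (single-water, assisting-water, non-productive) — default probabilities
  (0.75, 0.04, 0.21), the composition of the productive region of the
  trajectory — and the six catalytic distances are drawn from per-state
  Gaussians truncated at zero (the water–Ca²⁺ law is N(3.6, 1.5) Å for
  single-water, N(4.8, 0.2) Å for assisting-water; the remaining defaults
  place each state safely inside/outside the classification criteria).
  Atoms are then placed by explicit trilateration (His-Nδ at the origin,
  substrate C along +x, waters positioned to realise the drawn distances
  to ≤ 0.01 Å) and the whole site is given a uniformly random rigid
  rotation per frame, so 3-D distance code is genuinely exercised. The
  carbonyl O is placed at the drawn Ca–O distance from Ca (its bond
  length to C is not among the planted distances, so the chain stays
  feasible for every positive draw). Draws whose extreme tails violate a
  triangle inequality (~10⁻⁵ of frames) are redrawn; deterministically
  infeasible specs still raise a construction error. Bulk waters are
  uniform outside 6 Å exclusion spheres around **both** His-Nδ and the
  substrate C, so they can never satisfy the 4 Å attack criterion; water
  internal geometry is not physical (only distances consumed by the
  analyses are controlled).
* **Umbrella windows**: Metropolis Monte Carlo on F(ξ) + ½k(ξ−ξ₀)² with
  Gaussian proposals (step 0.05 Å) — only the stationary distribution
  matters for WHAM validation, so no dynamics are modelled. Mirroring the
  MD convention of extracting the CV at a coarser period than the
  integration step, every 10th MC state is recorded (`extraction_stride`),
  which keeps recorded samples close to independent; the leading 20% of
  each window is discarded as equilibration.
* **Analytic surfaces**: the 1-D double well is piecewise half-cosine
  with harmonic confining walls; branch lengths are curvature-matched at
  the top, so the planted barrier and ΔG are exact and the profile is C²
  at the transition state (C¹ at the well/wall junctions). The default
  2-D surface is a four-Gaussian sum (two deep wells, one shallow
  path-bending well, one barrier) whose stationary points are located
  numerically by dense-grid scanning plus gradient-root polishing — never
  assumed.
* **Charges**: a small neutral QM charge cluster whose geometry shifts
  between reactant and transition state, surrounded by MM residue groups
  in a 6–18 Å shell, for which all interaction energies are closed-form
  Coulomb sums.

Passing the recovery tests on these fixtures demonstrates the estimators
and classifiers are correct under the assumed statistical structure; it
does not validate force fields, sampling convergence of real simulations,
or any electronic-structure quantity.

## Path optimisation (CI-NEB)

Improved (upwind) tangents avoid band kinks; interior images feel the
perpendicular true force plus a spring force along the tangent (spring
constant default 5 energy·length⁻²; results are insensitive to it).
Relaxation is FIRE-style damped dynamics with adaptive step. Once the
maximum band force falls below 10·f_tol the highest image climbs: it
feels the true force with inverted parallel component and no springs,
converging to the saddle; f_tol defaults to 10⁻⁴ (energy per length).
Endpoints are pinned exactly. Saddles are verified by central-difference
Hessians of the analytic gradient (step 10⁻⁴): acceptance requires a
small gradient norm and exactly one negative eigenvalue. Molecular
(QM/MM) forces are out of scope; the module contracts on
`energy(x)`/`gradient(x)` callables of arbitrary dimension.

## Kinetics

Transmission coefficient 1 throughout. The population-weighted comparison
treats each pathway's reactive-conformation fraction as a pre-equilibrium
factor on its Eyring rate; the reported ΔΔG‡ = RT·ln(ratio) decomposes
exactly (to machine precision) into the population term and the raw
barrier difference. The specific-activity conversion to k_cat needs the
enzyme molar mass; the default 13.9 kg mol⁻¹ (mature hGIIA, ~124
residues) is logged whenever used. Ratios are reported raw and rounded to
one significant figure, the precision at which such estimates are
communicated.

## Residue energetics

ΔΔE_a(residue) = E_int(residue, TS) − E_int(residue, R) with bare vacuum
point-charge Coulomb sums (ε = 1, no cutoff); each state uses its own
geometry. Negative values stabilise the transition state (the output
header states the convention, since the sign could be defined either
way). This point-charge realisation of "residue deletion" captures the
electrostatic component only: polarisation response and QM re-relaxation
upon deletion are deliberately out of scope, which is the main fidelity
limit of the module. Pairs closer than 0.1 Å raise a singularity error.
The display axis for a residue is d(cog → base reference) − d(cog → acid
reference), placing it on one side of the plane dividing the protein
between the two reaction centres. Residue classes (negative / positive /
polar / apolar) come from a fixed name-keyed table.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 24 umbrella windows with
k = 100 kcal mol⁻¹ Å⁻² and 10⁴ retained samples each (WHAM recovery of a
17.0/−7.9 double well to within ±0.3), 5000-frame active-site ensembles
(population recovery to ±2%, distance laws to ±0.1 Å), 200-frame
membranes with five planted buried runs, a 201² stationary-point grid,
and ~10⁶-sample uniform-gas RDF checks. All randomness flows from a
single seed through `numpy.random.default_rng`/`SeedSequence`; repeated
runs are bit-identical. The whole suite completes in well under a minute
on one CPU.

## Known limitations

* PDB coordinates round-trip at fixed-width precision (10⁻³ Å); XYZ and
  time series round-trip at full precision.
* WHAM is 1-D only; no MBAR, no umbrella integration.
* The biased sampler is MC, not Langevin: time-correlation quantities of
  the windows are not meaningful, only their stationary statistics.
* The truncation at zero of the broad single-water water–Ca²⁺ law
  N(3.6, 1.5) shifts its realised mean/sd by ≈ +0.03/−0.04 Å; recovery
  tolerances (±0.1 Å) absorb this.
* Residue-deletion energetics are electrostatic-only (see above).
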