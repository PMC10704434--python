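# Methods

## Scope and model

`hydrosite` implements equilibrium hydration-site analysis: given frames
of an explicit-water system with a rigid (or restrained) solute, it
treats the frames as independent draws from the solvation ensemble and
estimates, per high-occupancy water site, the mean interaction energies,
the excess entropy relative to bulk water, and first-shell structural
descriptors. No dynamical information is used anywhere; every estimator
is a functional of the equilibrium ensemble only. All lengths are Å,
energies kcal/mol, charges e; boxes are orthorhombic with the
minimum-image convention.

## Site detection

Observations are (frame, water) pairs whose oxygen lies in the analysis
region; each carries the oxygen position and the rigid-body orientation
quaternion built from the two O–H bonds (bisector on +z, H→H axis on
+x). Detection is greedy density clustering:

1. count, for every remaining observation, the observations within
   `site_radius` (1.0 Å, the field's standard site size);
2. accept the best candidate (ties broken by lowest frame index, then
   lowest molecule id — fully deterministic), record the site center as
   the member centroid rather than the seed point (less discretization
   bias), remove the members;
3. block future seeds within `min_center_separation` (2.0 Å = two site
   radii) of an accepted center so one physical site cannot be counted
   twice;
4. stop when the best candidate's per-frame occupancy drops below
   `occupancy_floor`.

The floor defaults to twice the bulk expectation for the site sphere,
2·ρ_bulk·(4π/3)·r³ ≈ 0.276 waters/frame: "high-occupancy" needs a
quantitative reading, and twice bulk is the conventional choice in IST
site mapping. It is configurable, as is everything else, through the run
config. Site occupancy fₒ is the fraction of frames with at least one
member observation (≤ 1 by construction).

## Energetics

Nonbonded energy is truncated Coulomb + Lennard-Jones:
k·qᵢqⱼ/r + 4ε[(σ/r)¹² − (σ/r)⁶] with k = 332.0636 kcal·Å/(mol·e²),
Lorentz–Berthelot combining, a per-pair 10 Å cutoff and no long-range
correction. These are analysis-time interaction energies, not forces for
dynamics, so a sharp cutoff is acceptable and — importantly — exactly
reproducible by the scalar brute-force oracle used in the tests (the two
code paths agree to 1e-8 kcal/mol).

Per member water: E_sw sums interactions with every solute, ligand and
ion atom; E_ww is ½ the interaction with all other waters. The ½
pair-sharing convention makes the neat-liquid per-water total equal the
conventional TIP3P E_tot = −9.53 kcal/mol, which is the bulk reference
all classifications compare against. The first shell is water oxygens
within 3.5 Å O–O (the first minimum of the water g(r)); E_ww per
neighbor is the per-member ratio (½·Σ first-shell energy)/N_nbr averaged
over members that have neighbors, reported as 0 with a flag when no
member has any.

Hydrogen bonds use the standard geometric criterion: donor–acceptor
heavy-atom distance ≤ 3.5 Å and donor H–O···O angle ≤ 30°. Solute–water
bonds consider solute N/O/S heavy atoms; the solute donates through any
hydrogen within 1.25 Å of the heavy atom.

## Excess entropy

Both entropy terms are first-nearest-neighbor (Kozachenko–Leonenko-type)
estimates over the pooled member observations, expressed in k_B and
reported as −TSᵉ at T = 300 K (k_BT = 0.5962 kcal/mol):

* translational, referenced to bulk water at number density ρ_bulk:
  Sᵉ_tr/k_B = γ + ⟨ln[(N−1)·(4π/3)dᵢ³·ρ_bulk·n_frames/N]⟩. The
  n_frames/N factor encodes the reference: a bulk-like water observed
  over n_frames frames presents a pooled cloud of density
  n_frames·ρ_bulk, so bulk-like input gives 0. For a fully occupied site
  (N = n_frames) the factor vanishes and the estimator converges to the
  differential entropy of the position distribution plus ln ρ_bulk —
  hence the Gaussian closed form Sᵉ/k_B = 3/2·ln(2πeσ²) + ln ρ_bulk used
  in calibration, which also lets a planted σ be recovered by inversion
  (within 10% at N = 10⁴).
* orientational, referenced to the uniform distribution on SO(3):
  Sᵉ_or/k_B = γ + ⟨ln[(N−1)·(ωᵢ − sin ωᵢ)/π]⟩, where (ω − sin ω)/π is
  the normalized Haar measure of the geodesic ball of radius ω and ωᵢ is
  the smallest rotation angle to the nearest other orientation (searched
  over ±q to respect the quaternion double cover). Uniform orientations
  give 0; any concentration is negative.

Numerical guards: sites with fewer than 50 member observations are
flagged and report missing entropies (NN estimates below that are too
noisy to act on); degenerate distributions (identical positions or
orientations) are clipped at −10 k_B per term so reports stay finite and
visibly saturated. Calibration of the translational estimator on
homogeneous bulk input uses periodic neighbor search (`boxsize`): a
bounded cube of 10⁴ uniform points carries a ≈ +0.05 k_B boundary bias
that belongs to the test geometry, not the estimator; compact site
clouds never need it.

## Classification

* Environment (A/P/C): pocket heavy atoms within 3.5 Å of the site
  center, priority charged > polar > apolar. An atom is "charged" if it
  is an ion, carries |q| ≥ 0.9 e, or belongs to a formally charged side
  chain group (Asp/Glu carboxylate, Lys/Arg/His⁺); "polar" if its
  element is N/O/S or |q| ≥ 0.4-ish (threshold 0.3 e, catching dipolar
  pseudo-atoms). Sites with no pocket atom within 6 Å are flagged
  exposed and fall to A.
* Water structure (En/Fr): E_ww per neighbor ≤ −1.36 kcal/mol (bulk) is
  enhanced, else frustrated. The per-neighbor comparison, rather than
  total E_ww against −9.53, is the reading under which every published
  category row reproduces its own label; the total-E_ww variant stays
  available via `ww_mode="total"`.
* Energetics (F/U): E_tot strictly below bulk is favorable; ties are
  unfavorable (and ties are enhanced for En/Fr) — arbitrary but fixed,
  documented, and of measure zero on real data.

## Displacement and binding contributions

Default displacement is the envelope criterion: site center within
(nearest ligand-atom distance − r_vdw) ≤ 1.5 Å; the literal
center-distance reading is available and is always a subset at equal
probe. Contributions are occupancy-weighted by default —
ΔH_solv = Σ fₒ(E_tot,bulk − E_tot), −TΔS_solv = −Σ fₒ(−TSᵉ) — because a
half-occupied site expels half a water on average; `occupancy_weighted=False`
reproduces unweighted sums. Crystal matching restricts both sites and
crystal waters to the 5 Å ligand shell and pairs greedily nearest-first
under 2 Å, each crystal water consuming at most one site; apo–holo
conserved-site pairing uses the same 2 Å scale, one coherent "same site"
length.

## Solvation landscape

The per-frame hydration coordinate is the count of water oxygens within
5 Å of any ligand heavy atom (minimum image). The landscape is
ΔG(bin) = −k_BT·ln(P/P_max) over a 2D histogram of an externally
computed binding coordinate (e.g. a tICA projection read from TSV)
against that count, y binned at integers, empty bins masked rather than
zero-filled, optionally weighted by per-frame weights (reweighted
ensembles); without weights the manifest records that raw counts were
used. Rescaling all weights by a constant leaves ΔG unchanged.

## The synthetic generator

`generate_pocket_system` emulates exactly the statistics the analysis
consumes: rigid pseudo-pocket atoms that realize a chosen environment
class within 3.5 Å of each planted center (±1 e for charged, a ±0.4 e
dipole pair with the O end facing the site for polar, neutral carbon for
apolar); site waters present per frame with Bernoulli(fₒ), Gaussian(σ)
positions and uniform/fixed/von Mises–Fisher orientations; background
waters i.i.d. uniform at ρ_bulk = 0.0329 Å⁻³ (ambient TIP3P), excluded
within 2.4 Å of planted centers. Waters are rigid TIP3P (O–H 0.9572 Å,
104.52°, qO = −0.834 e, LJ on oxygen only). Vacant site waters are
relocated into the bulk so the atom count stays constant across frames,
as the trajectory formats require.

What it does *not* emulate — and therefore what passing tests do and do
not show: background waters carry no Boltzmann correlations, so they
clash sterically and the absolute E_ww of synthetic sites is dominated
by rare hard-core contacts rather than hydrogen-bonded structure.
Synthetic data therefore validates *estimator correctness* (oracle
equality of energies, calibrated entropies, exact geometric recovery of
occupancy, centers, classes, displacement and crystal coincidence), not
the liquid-water values of E_ww or N_nbr; those enter through the bulk
reference constants, which are configurable and default to the standard
TIP3P row (E_tot −9.53, E_ww/neighbor −1.36, N_nbr 5.26, N^HB_ww 3.33,
f^HB_ww 0.63). There is also no protein flexibility, no PME, and no
temporal correlation — the estimators are ensemble averages, for which
i.i.d. frames are the cleanest test bed.

## Problem sizes and determinism

The bundled three-site scenario (occupancies 0.9/0.7/0.5, spreads
0.20/0.25/0.30 Å, one site per environment class, 120 background waters)
runs at 2000 frames for statistical recovery and at 60 frames for
file-based end-to-end checks; entropy calibrations use 10⁴ samples.
These sizes put every stochastic check several standard deviations clear
of its tolerance while keeping the full suite in the minutes range. All
randomness flows from one root seed through named substreams;
identical config + seed give byte-identical site tables, and the run
manifest records every resolved default, constant and artifact checksum.

## Known limitations

* Water–water entropy correlations and the full IST spatial integrals
  (g(r,ω) expansions) are out of scope; −TSᵉ is the first-order
  nearest-neighbor estimate per site.
* Truncated electrostatics without Ewald summation: adequate for
  relative per-site comparisons against a bulk reference computed the
  same way, not for absolute solvation energies.
* Orthorhombic boxes only; triclinic cells and mmCIF are not supported.
* The NN entropy estimator's small-N bias is controlled by the N ≥ 50
  floor but not corrected; very low-occupancy sites report missing
  entropy rather than a biased number.
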