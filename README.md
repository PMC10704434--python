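# hydrosite

Hydration-site analysis of protein binding pockets by inhomogeneous
solvation theory (IST), with a synthetic-trajectory generator that plants
sites with known ground truth.

Water in a binding cavity is not a passive backdrop: on ligand binding,
pocket waters are displaced into the bulk or reorganized, and the
enthalpic and entropic cost (or gain) of doing so is a major component of
the binding free energy. `hydrosite` takes an explicit-solvent trajectory
of a (restrained) receptor, locates the high-occupancy water sites in the
pocket, computes per-site IST thermodynamics relative to bulk water,
classifies the sites, decides which ones a bound ligand expels, and
aggregates the solvent contribution to binding. It is aimed at
computational chemists doing water-aware ligand design and at method
developers who need a fully controllable test bed for IST estimators.

## The method

**Sites.** Water-oxygen observations inside the analysis region (by
default a 5 Å shell around the bound pose) are clustered greedily into
1 Å-radius spheres: the densest observation seeds a site, its members are
removed, and the process repeats until the best candidate's per-frame
occupancy falls below a floor (default: twice the expected bulk count in
a 1 Å sphere, 2·ρ_bulk·(4π/3) ≈ 0.276). Sites are numbered by occupancy
*f*ₒ, the fraction of frames in which the sphere holds a water.

**Energetics.** Per site water, E_sw sums nonbonded interactions
(Coulomb + Lennard-Jones, Lorentz–Berthelot, 10 Å cutoff, minimum image)
with all solute/ligand/ion atoms, and E_ww is ½ the interaction with all
other waters, so that the bulk per-water total matches the conventional
TIP3P value E_tot = −9.53 kcal/mol. E_ww per first-shell neighbor
(O–O ≤ 3.5 Å) is compared against the bulk −1.36 kcal/mol.

**Entropy.** Excess entropies relative to bulk come from
first-nearest-neighbor estimators: translational over the member-oxygen
cloud,

    Sᵉ_tr/k_B = γ + ⟨ln[(N−1)·(4π/3)·dᵢ³·ρ_bulk·n_frames/N]⟩,

and orientational on SO(3) with the normalized Haar measure,

    Sᵉ_or/k_B = γ + ⟨ln[(N−1)·(ωᵢ − sin ωᵢ)/π]⟩,

where dᵢ (ωᵢ) is the distance (smallest rotation angle) to the nearest
other member and γ is the Euler–Mascheroni constant. Both are zero for
bulk-like input and are reported as free-energy penalties −TSᵉ at 300 K.

**Classification.** Environment: charged (C), polar (P) or apolar (A)
from the pocket heavy atoms within 3.5 Å of the site center (priority
C > P > A). Water structure: enhanced (En) if E_ww per neighbor is at
least as favorable as bulk, else frustrated (Fr). Energetics: favorable
(F) if E_tot is strictly below bulk, else unfavorable (U).

**Displacement.** A site is displaced when its center falls inside the
ligand's van der Waals envelope expanded by a 1.5 Å probe. Summing over
displaced sites gives the solvent contribution to binding,
ΔH_solv = Σ fₒ·(E_tot,bulk − E_tot,site) and −TΔS_solv = −Σ fₒ·(−TSᵉ);
sites are also matched (≤ 2 Å) against crystallographic waters and
against an independent holo run for conserved-site Δ(−TS) and ΔE_tot.

## Worked example

Plant two hydration sites — one tightly ordered beside a charged
pseudo-atom, one looser in an apolar nook — analyze the synthetic
trajectory, and displace the charged-site water with a one-atom ligand:

```python
import numpy as np
from hydrosite import (AnalysisRegion, BulkReference, SiteSpec, analyze,
                       generate_ligand_and_crystal, generate_pocket_system,
                       flag_displaced, binding_contributions)

specs = [
    SiteSpec(center=[0.0, 0.0, 0.0], occupancy_target=0.9,
             positional_sigma=0.20, orientation_mode="vmf", vmf_kappa=20.0,
             nearest_residue_class="charged"),
    SiteSpec(center=[4.6, 0.0, 0.0], occupancy_target=0.6,
             positional_sigma=0.30, nearest_residue_class="apolar"),
]
topology, frames, truth = generate_pocket_system(
    specs, n_frames=800, n_background_waters=120, seed=42)

region = AnalysisRegion(mode="sphere", sphere_center=[2.3, 0.0, 0.0],
                        sphere_radius=4.5)
bulk = BulkReference()
sites = analyze(topology, frames, region, bulk)
for s in sites:
    t = s.thermo
    print(f"site {s.site_id}: fo={s.fo:.3f} center={np.round(s.center, 2)} "
          f"class={s.labels.composite} -TSe={t.minus_TSe:.2f} kcal/mol "
          f"NwwHB={t.NwwHB:.2f}")

ligand, _ = generate_ligand_and_crystal(specs, displace_subset=[0])
flags = flag_displaced(sites, ligand)
dH, mTdS, _ = binding_contributions(sites, flags, bulk)
print(f"displaced: {sum(flags)} of {len(sites)}; "
      f"dH_solv={dH:.2f} kcal/mol, -T.dS_solv={mTdS:.2f} kcal/mol")
```

This prints:

```
site 1: fo=0.901 center=[ 0.01 -0.01  0.  ] class=C.Fr.U -TSe=3.93 kcal/mol NwwHB=1.08
site 2: fo=0.591 center=[4.59 0.01 0.01] class=A.Fr.U -TSe=1.28 kcal/mol NwwHB=1.06
displaced: 1 of 2; dH_solv=-16.83 kcal/mol, -T.dS_solv=-3.54 kcal/mol
```

Both planted sites are recovered at their centers with their planted
occupancies. The tightly restrained, orientationally ordered site 1 pays
the larger entropy penalty (−TSᵉ = 3.93 kcal/mol), so expelling it yields
an entropy gain of 3.54 kcal/mol (occupancy-weighted, sign flipped into
the binding direction). The negative ΔH_solv reflects the i.i.d.
synthetic solvent, whose clash-dominated site energies sit above the bulk
reference — see `docs/methods.md` for what the generator does and does
not emulate.

The same analysis runs from the shell against files:

```bash
hydrosite synth --seed 1 --out scenario/     # bundled three-site pocket
hydrosite all scenario/run_config.yaml       # site table, categories, report
```

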