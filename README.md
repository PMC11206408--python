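# rpk

Analysis toolkit for simulations of an interfacial enzyme — human group IIA
secreted phospholipase A2 (hGIIA sPLA2) bound to a phospholipid bilayer —
covering the full route from raw trajectories to reaction kinetics:

* **membrane geometry** — penetration depth Δz of each residue below the
  upper-leaflet phosphate plane, buried-residue hotspot detection, in-plane
  density maps, residue–substrate minimum-distance profiles;
* **solvation** — radial distribution functions, hydration-shell
  occupancies, Ca²⁺ coordination numbers, Shrake–Rupley solvent-accessible
  surface areas;
* **catalytic conformations** — classification of active-site microstates
  into *single-water* (one water simultaneously H-bonded to His-Nδ and
  poised to attack the substrate carbonyl carbon), *assisting-water*
  (a two-water relay) and *non-productive* frames, with KDE-based
  clustering in the catalytic-distance plane;
* **free energy** — weighted-histogram (WHAM) reconstruction of 1-D
  profiles from umbrella-sampling windows, with time-block equilibration
  diagnostics, block-bootstrap error bands and barrier/ΔG feature
  extraction;
* **path optimisation** — climbing-image nudged elastic band (CI-NEB) on
  analytic surfaces, with finite-difference saddle verification;
* **kinetics** — Eyring transition-state-theory conversions and a
  population-weighted comparison of competing pathways;
* **residue energetics** — per-residue electrostatic contributions to the
  activation barrier by point-charge residue deletion,
  ΔΔE_a = E_int(TS) − E_int(R).

A first-class `synthetic_data` module generates every input the pipeline
consumes — bilayer trajectories with planted depths, active-site ensembles
with exactly realised catalytic distances, Metropolis-sampled umbrella
windows on planted free-energy surfaces, and point-charge fixtures — so
every stage is testable against known ground truth.

## The core quantities

With R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹ and T = 310.15 K:

* **WHAM**: iterate
  P(ξ_b) = Σᵢ nᵢ(ξ_b) / Σᵢ Nᵢ exp[(fᵢ − wᵢ(ξ_b))/RT] and
  fᵢ = −RT ln Σ_b P(ξ_b) exp[−wᵢ(ξ_b)/RT] with harmonic biases
  wᵢ(ξ) = ½kᵢ(ξ − ξᵢ)² to self-consistency; F(ξ) = −RT ln P, min-zeroed.
* **Eyring**: k = (k_B T/h)·exp(−ΔG‡/RT); inverted,
  ΔG‡ = RT·ln(k_B T/(h·k)).
* **Pathway comparison**: effective rate per pathway rᵢ = pᵢ·kᵢ with pᵢ
  the conformational population; ratio r_fast/r_slow maps to an effective
  ΔΔG‡ = RT·ln(ratio) that decomposes exactly into RT·ln(p_fast/p_slow)
  plus the raw barrier difference.

## Worked example

Population-weighted comparison of the two hydrolysis pathways, using the
conformational populations (75% single-water, 4% assisting-water) and the
umbrella-sampling barriers (17.0 and 19.0 kcal mol⁻¹):

```
$ rpk kinetics compare --populations 0.75,0.04 --barriers 17,19
{
 "fast": "pathway_1",
 "slow": "pathway_2",
 "ratio": 481.1608613778494,
 "ratio_rounded": 500.0,
 "ddg_kcal": 3.806586516361282,
 "population_ddg": 1.806586516361281,
 "barrier_ddg": 2.0
}
```

The single-water pathway is ~500× faster; of its 3.8 kcal mol⁻¹ effective
advantage, 1.8 kcal mol⁻¹ comes from its larger reactive population and
2.0 kcal mol⁻¹ from its lower barrier. The experimental cross-check inverts
a measured specific activity into a barrier:

```
$ rpk kinetics kcat --specific-activity 33.9 --molar-mass 13.9
7.8535
$ rpk kinetics barrier --rate 7.8535
16.9097
```

i.e. a turnover of 7.85 s⁻¹ corresponds to an activation free energy of
16.9 kcal mol⁻¹ — in line with the 17.0 kcal mol⁻¹ umbrella-sampling
barrier of the single-water pathway.

A full synthetic free-energy round trip (generate biased windows on a
planted double well, reconstruct with WHAM):

```
$ rpk --seed 1 simulate windows --barrier 17 --delta-g -7.9 --out win/
$ rpk wham --meta win/metadata.dat --discard 0.0 --out profile.tsv
```

`profile.tsv` holds (ξ, F, error) columns; the reconstructed barrier and
reaction ΔG land within ~0.1 kcal mol⁻¹ of the planted 17.0/−7.9.

Library use mirrors the CLI one-to-one, e.g.:

```python
from rpk.synthetic_data import ActiveSiteFixtureSpec, gen_active_site_trajectory
from rpk.conformations import catalytic_distances, classify

ens = gen_active_site_trajectory(ActiveSiteFixtureSpec(n_frames=5000, seed=0))
records, summary = classify(catalytic_distances(ens.trajectory, ens.atom_map))
print(summary)          # fractions per label, e.g. ~0.75 / 0.04 / 0.21
```

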