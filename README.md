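# chpi

CH–π interactions between aliphatic C–H bonds and aromatic rings are among
the most common noncovalent contacts in protein–ligand complexes — they
dominate carbohydrate recognition, where pyranose ring protons stack on
tryptophan and tyrosine side chains — yet standard empirical docking scores
barely register them.  `chpi` is a toolkit for structural bioinformaticians
and docking-method developers that

* **detects** CH–π contacts geometrically in PDB/PDBQT structures,
* **scores** them with an empirical pairwise CH–π energy added to a
  re-implemented pairwise docking base score,
* **fits** the CH–π parameters by exhaustive two-stage grid search against
  dimer interaction-energy curves, and
* **validates** the term by torsion grid search over ligand-moiety or
  side-chain rotamers.

## The model

A contact is defined by an aliphatic hydrogen within 3.5 Å of an aromatic
ring centroid and characterized by the descriptors *R* (H–centroid
distance), θ (C–H–centroid angle), ω (H/edge–plane dihedral), θ₁
(carbon–centroid–normal angle), θ₂ (tilt of the C–H bond off the ring
normal), and the horizontal/vertical offsets *R*_H, *R*_V.

The hydrogen-dependent CH–π energy is a sum over every aliphatic proton and
every aromatic ring **carbon** (ring nitrogens are excluded):

```
E_CHπ = − Σ_H Σ_C  E_HC · ½ · exp( −(R_HC − R⁰_HC)² / C_HC ) · f(θ₂)
f(θ₂) = max(cos θ₂, 0)
```

with fitted constants E_HC = 0.29 kcal/mol, R⁰_HC = 3.58 Å, C_HC = 0.85.
The ½ reflects that only one lobe of each ring carbon's π orbital faces the
proton; the cosine decay turns off hydrogens pointing away from the ring.
A hydrogen-independent variant for hydrogen-free docking grids replaces
R_HC by the aliphatic-carbon/ring-carbon distance and drops f(θ₂)
(E_CC = 0.26, R⁰_CC = 4.49 Å, c_CC = 0.75).  The combined score is

```
E_total = E_base + w · E_CHπ
```

where `E_base` is the published pairwise docking score (two attractive
Gaussians, quadratic soft repulsion, hydrophobic and hydrogen-bond terms,
8 Å cutoff) and *w* is an empirical weighting factor — 1.0 during fitting,
0.3 recommended for general scoring.

## Worked example

```python
from chpi import DimerSpec, build_dimer, total_energy

benzene, methane = build_dimer(DimerSpec("A", r_v=3.8))   # C–H at the centroid
bd = total_energy(benzene, methane, w=1.0, mode="hdep")
print(f"base {bd.e_base:.3f}  chpi {bd.e_chpi:.3f}  total {bd.total:.3f}")
```

prints

```
base -0.382  chpi -0.621  total -1.004
```

The base score alone sees only −0.38 kcal/mol for the canonical perpendicular
methane–benzene dimer; the CH–π term adds −0.62 kcal/mol, giving the ≈−1.0
kcal/mol expected of a genuine CH–π contact.  `examples/` contains one short
script per capability (detection, scoring, scans, fitting, rotamer search),
and the `chpi` command line mirrors them:

```sh
chpi scan --geometry A --axis vertical --mode hdep --w 1.0 --out curve.tsv
chpi score --receptor rec.pdbqt --ligand lig.pdbqt --w 0.3 --mode hindep
```

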