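# tailbind

Analysis toolkit for studying how the intrinsically disordered, highly acidic
C-terminal tails of tubulin ("E-hooks") steer the docking of dynein's
microtubule binding domain (MTBD) onto the microtubule. The package
implements the three quantitative pillars of that analysis as a reusable,
tested pipeline over synthetic ensembles with known ground truth:

1. **Distance-resolved contact mapping.** The ligand is displaced rigidly
   from its bound pose along the axis perpendicular to the microtubule
   surface (offset ladder 5, 15, 25, 35, 45, 55 Å). A contact is a
   (tail heavy atom, ligand heavy atom) pair within 4 Å (boundary
   inclusive). Per-frame counts, replicate averages, the grand mean
   N<sub>c</sub>, and per-residue profiles (raw or normalised to shares)
   quantify how the tail grabs and releases the ligand along the approach.
2. **Conformational clustering.** Frames are superposed by the Kabsch
   algorithm and clustered with the Daura neighbour-count algorithm at a
   1.5 Å Cα RMSD cutoff; the five most populated clusters are analysed,
   occupancies kept relative to *all* frames so the unclustered remainder
   stays visible. Free-state clusters are matched to bound-state clusters by
   minimal representative RMSD, and the free→bound occupancy relation is
   summarised by a least-squares line weighted by the contact count
   N<sub>c</sub>.
3. **Continuum electrostatics.** A finite-difference linearized
   Poisson–Boltzmann solver, ∇·(ε∇φ) − εκ²φ = −4πρ, with a two-dielectric
   map (ε<sub>in</sub> = 2, ε<sub>out</sub> = 80), Debye screening at
   I = 0.15 M, 2 grids/Å, perfil 70 and Debye–Hückel boundary conditions.
   With *only* the tail charged (selective charging) the Coulombic force
   F = Σ qE on the ligand yields the distance-resolved perpendicular force
   profile: attraction (negative) at long range that reels the ligand in,
   repulsion (positive) just before docking — the "soft-landing" signature.

Synthetic generators stand in for molecular-dynamics input: trajectories
with planted per-frame contact counts, conformer mixtures with known cluster
occupancies, and point-charge systems with closed-form screened-Coulomb and
Born references. Every generator verifies its ground truth with the
pipeline's own oracles before handing it to an analysis.

## Worked example

```python
import numpy as np
import tailbind as tb

# the beta-tubulin tail, built in extended geometry with formal charges
tail = tb.assign_charges(tb.build_tail(None, tb.BETA_TAIL_SEQUENCE))
print(np.nansum(tail.charge))            # -11.0  (3 Asp + 8 Glu)

# soft-landing force profile on the planted charge preset
from tailbind.synth import gen_charge_system
import tailbind.electrostatics as es
sys_ = gen_charge_system("tail_ligand_flip")
prof = es.force_distance_profile(
    {d: [s] for d, s in sys_["structures"].items()},
    "Ehooks", "MTBD", axis=sys_["axis"], scale=1.0,
    eps_in=80, eps_out=80, ionic_strength=0.15)
print(prof.as_frame()[["distance", "F_perp"]].round(4))
```

prints (kcal/(mol·Å); negative = pulled toward the receptor):

```
   distance  F_perp
0       5.0  0.1321
1      15.0 -0.4169
2      25.0 -0.1824
3      35.0 -0.0255
4      45.0 -0.0047
5      55.0 -0.0010
```

i.e. the tail charges pull the ligand in from 55 Å down to 15 Å and push
back at 5 Å, each value within ~1.5 % of the analytic screened-Coulomb
superposition over the planted charges.

The numbered scripts under `analysis/` run the full narrative:
`01_build_system.py` (tails, charges, offset ladder), `02_contacts.py`
(contact statistics across the ladder), `03_clustering.py` (Daura clusters,
free/bound correspondence, weighted regression), `04_electrostatics.py`
(solver validation and the force profile), `05_full_pipeline.py` (everything
from one config). Small summary tables land in `results/`.

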