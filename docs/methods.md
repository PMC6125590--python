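# Methods

## System and scope

The package analyses a receptor–ligand system in which the receptor carries
intrinsically disordered, strongly acidic C-terminal tails (the α-tail
sequence `VGVDSVEGEGEEEGEEY`, net formal charge −8; the β-tail
`DATADEQGEFEEEGEEDEA`, net −11) and the ligand is a small structured domain
docking onto the receptor surface. Three analyses are implemented:
distance-resolved atomic contacts, conformational clustering with
free/bound correspondence, and continuum-electrostatic steering forces.
Molecular-dynamics sampling itself is out of scope; ensembles are supplied
either as multi-model PDB files or by the synthetic generators described
below.

## Tail construction and charge model

Tails are built residue-by-residue from one-letter sequences using ideal
backbone internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
trans peptide ω = 180°) with the extended conformation φ = −120°, ψ = +120°
as default; per-residue φ/ψ arrays allow conformer generation. Asp, Glu, Lys
and Arg receive minimal side chains so charge carriers exist. A full-detail
homology model would add nothing here: starting tail coordinates are always
re-sampled into an ensemble before any statistic is computed.

The formal charge model places −1 on the carboxylate-centre atom of every
Asp/Glu (CG/CD) and +1 on Lys NZ / Arg CZ, with van der Waals radii by
element (Bondi values, 1.7 Å default). Acidic tail residues are *always*
kept deprotonated — at pH 7 these highly solvent-exposed carboxylates are
fully ionized, so no per-snapshot titration machinery is included. Termini
are uncharged by default (`charge_termini=True` adds the zwitterion).
Alternatively, per-atom charges and radii are copied verbatim from a PQR
file.

## Contacts

A contact is an (atom, atom) pair across the two groups with Euclidean
separation ≤ cutoff (default 4.0 Å, boundary inclusive). Counting pairs —
rather than "a tail atom touching anything" — makes per-residue attribution
well defined on both sides; one tail atom touching two ligand atoms
contributes two contacts. Hydrogens are excluded on both sides by default
(`include_ligand_hydrogens=True` selects the asymmetric heavy-vs-all
reading). Counting uses a k-d tree but is required — and tested — to agree
pair-for-pair with exhaustive O(N²) enumeration. Per-frame counts are kept
per replicate; the replicate-average series and the grand mean N<sub>c</sub>
(contacts per frame over all frames and runs) summarise each ladder
distance. Normalised per-residue profiles report each residue's share of the
total and are undefined (an error) when the total is zero.

## Superposition and clustering

Pairwise frame RMSDs use the closed-form Kabsch superposition. The fit
selection and the RMSD selection may differ: fitting on the structured body
while evaluating RMSD over all Cα (tail included) retains the tail's
orientation relative to the body in the distance measure — the convention
used throughout the pipeline. Degenerate (collinear/coincident) fit sets are
rejected. The all-pairs matrix is evaluated with a batched trace identity
(rmsd² = (|A|² + |B|² − 2 tr(R AᵀB))/n, singular values from the 3×3
spectrum of HᵀH), which is algebraically exact but cancels large terms:
identical frames come out at ~1e−8 Å rather than 0, far below any
clustering cutoff.

Clustering is the Daura neighbour-count algorithm: repeatedly take the frame
with the most neighbours within the cutoff (default 1.5 Å, inclusive) as a
cluster centre, remove it and its neighbours, repeat. Ties in neighbour
count break toward the lowest frame index, making partitions
platform-deterministic. The centre — the most connected conformation —
serves as the cluster representative. Every frame is assigned; "unclustered"
mass is whatever lies outside the analysed top-k (default 5), so occupancies
are always fractions of all frames. Occupancies are pooled across replicates
by default (per-replicate analysis is available by clustering replicates
separately).

Bound clusters are matched to free clusters by minimal superposed RMSD
between representatives; ties break toward the more occupied free cluster.
The free→bound occupancy relation is fit by weighted least squares
(statsmodels WLS; weights = per-point N<sub>c</sub>), reporting slope,
intercept and weighted R².

## Electrostatics

The linearized Poisson–Boltzmann equation ∇·(ε∇φ) − εκ²φ = −4πρ is solved
on a cubic grid centred on the solute, spacing h = 1/scale (default
2 grids/Å), box edge ≥ largest solute extent / (perfil/100) with perfil 70,
node counts odd. Potentials are in kT/e: a unit charge in uniform dielectric
gives φ = ℓq/(εr) with ℓ = e²/(4πε₀kT) ≈ 560.5 Å at 298.15 K. The
two-dielectric map (ε_in = 2, ε_out = 80) is built from inflated van der
Waals spheres rather than a probe-rolled molecular surface — adequate at
desk scale, with the probe inflation configurable (default 0). Permittivity
is assigned per *edge* from the edge midpoint, halving the boundary-placement
bias of node-based assignment. κ is the bulk Debye parameter
(κ⁻¹ = 7.93 Å at I = 0.15 M, 298.15 K, ε 80) outside the spheres and zero
inside. Charges spread to the eight surrounding nodes trilinearly; boundary
faces hold the Debye–Hückel superposition of all source charges; the
interior is relaxed by red-black successive over-relaxation with the
Laplacian-optimal factor ω = 2/(1 + sin(π/n)), converged when the max-norm
residual relative to the source norm is ≤ 1e−6.

Validated limits (all computed by the test suite and the acceptance script):
a unit charge in uniform ε = 80 matches Coulomb within 5 % over the 3–15
grid-spacing shell (3.8 % measured at scale 2) and the Yukawa profile within
5 % at I = 0.15 M (4.7 %); the Born reaction potential of a q = +1, R = 2 Å
sphere (ε 2/80) is reproduced within 10 % (4.6 %).

Forces use selective charging: the dielectric cavity is shaped by the full
complex, only the source group's charges enter the solve, and the force on
the target is the Coulombic term F = Σ qᵢE(rᵢ) with E = −∇φ by central
differences, reported in kcal/(mol·Å) (kT × 0.5925 kcal/mol at 298.15 K).
Dielectric-boundary pressure and ionic-pressure force terms are *not*
computed; output metadata records `force_model="qE"`. In homogeneous
dielectric this reproduces screened-Coulomb pair forces within 3 % and
satisfies Newton's third law and linearity in source charge. The
distance-resolved profile averages the force over snapshots at each ladder
distance and reports the signed projection on the offset axis
(negative = toward the receptor); d = 0 is excluded by default because
artificially close contacts produce excessively large forces there.

## Synthetic data

*Conformer mixtures* draw per-frame conformer labels i.i.d. from the
occupancy vector (defaults 0.35/0.25/0.20/0.15/0.05, n = 2000 frames,
matching the study-scale frame count) and add isotropic Gaussian coordinate
noise (σ = 0.25 Å, giving intra-conformer RMSD ≈ σ√6 ≈ 0.6 Å < half the
1.5 Å cutoff). Conformers are generated by perturbing the tail's backbone
dihedrals (±80°) and re-drawn until all pairs differ by more than 4.5 Å
(three cutoffs), so cluster recovery is geometrically unambiguous. What this
does **not** emulate: correlated dynamics, gradual interconversion, or
partially overlapping states — passing recovery tests shows the clustering
machinery is correct, not that real trajectories are this clean.

*Planted-contact trajectories* keep ligand atoms on a line spaced 10 Å
apart; a frame with planted count c places the first c tail atoms 3 Å above
their partners and the rest 40 Å away, so exactly c pairs fall within 4 Å.
An optional random rigid motion of each frame exercises invariance. The
generator re-counts every frame with the contact engine before returning.

*Charge presets* provide a Born ion, an opposite pair, a mirror-symmetric
pair (exact perpendicular cancellation), and `tail_ligand_flip`: a line of
−1 charges spanning 2–20 Å above the receptor surface with a +2 ligand
charge on the offset ladder (bound height 3 Å). At small offsets most tail
charge sits above the ligand (net repulsion from the surface); at large
offsets all of it sits below (net attraction) — reproducing the sign
structure of the soft-landing force profile without claiming its absolute
magnitudes, which depend on the full atomistic system. Every preset attaches
its closed-form screened-Coulomb/Born reference and checks its own sign
contract at construction.

## Pipeline

`PipelineConfig` defaults mirror the study conditions: offset ladder
{0, 5, 15, 25, 35, 45, 55} Å, 4 Å contact cutoff, 1.5 Å cluster cutoff with
top 5, scale 2 / perfil 70 / ε 2/80 / I = 0.15 M, three replicates of 2000
frames with the second half analysed (`frame_window=(0.5, 1.0)`). Excluding
an outlier run is a manual per-distance config flag, never automatic. The
synthetic force stage runs the point-charge preset at `force_scale`
(default 1 grid/Å): point charges on 10 Å spacings gain nothing from sub-Å
grids, and per-distance boxes stay small. Planted contact means per distance
(14 bound, dip to 3–4 at 5–15 Å, 7–8 at 25–35 Å, ≤1 beyond) emulate the
non-monotone distance dependence of the tail–ligand contact count. Stage
seeds are derived from the master seed by hashing, so every output is a pure
function of (config, seed); reports carry the config hash.

Analysis scripts keep clustering at 600 frames per state (3 × 300 pooled)
— enough for stable top-5 occupancies at desk scale; the acceptance
occupancy-recovery check runs the full n = 2000.

## Known limitations

- Only the qE force component is computed; boundary-pressure and ionic
  terms of a full PB force decomposition are absent (flagged in metadata).
- The dielectric boundary is a sphere union, not a molecular surface; Born
  accuracy at 2 grids/Å is ~5 %, dominated by boundary placement.
- Built tails are idealised extended chains with minimal side chains — they
  carry charge and geometry, not rotamer realism.
- The trace-identity RMSD path returns ~1e−8 Å, not exactly 0, for
  identical frames.
- Cluster partitions are deterministic but, like the underlying greedy
  algorithm, can change under frame re-ordering when neighbour-count ties
  occur between overlapping neighbourhoods.
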