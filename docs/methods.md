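# Methods

## The system and the question

Histamine is a biogenic diamine: an imidazole ring plus an ethylamine side
chain. At physiological pH it is predominantly a monocation, protonated
on the aliphatic amine. Under an independent-site protonation model with
pKa 6.0 for the ring nitrogen and 9.7 for the amine, the monocation
fraction at pH 7.4 is

f = 1/(1 + 10^(pH−pKa_amine)) · 1/(1 + 10^(pKa_ring−pH)) = 0.957,

i.e. 96% to the nearest percent. The package therefore works with the
N^τ monocation throughout: ring nitrogen N1 (adjacent to the side chain)
is a bare hydrogen-bond acceptor, ring N3 carries the tautomeric proton,
and the side-chain amine N2 carries three.

The monocation has two conformer families distinguished by the side-chain
torsion φ (ring carbon–Cβ–Cα–N2, heavy atoms only): *gauche* (|φ| near
60°, folded, permitting an intramolecular N2–H···N1 contact) and *trans*
(|φ| near 180°, extended). The question the toolchain serves: when every
exchangeable proton is swapped for deuterium, how does the balance between
hydration and receptor interaction shift the binding affinity?

## The H/D cycle

Component electronic energies (from any external engine; the package
consumes them as delimited text) enter as two supermolecule association
legs per isotope state:

- ΔE_HYDR: ligand + water cluster → hydrated complex;
- ΔE_INTER: ligand + binding-site cluster → bound complex;
- ΔE_BIND = ΔE_INTER − ΔE_HYDR.

All differences are D-minus-H: ΔΔE_X = ΔE_X(D) − ΔE_X(H), so
ΔΔE_BIND = ΔΔE_INTER − ΔΔE_HYDR holds as an algebraic identity (asserted
to 1e-9) and a negative ΔΔE_BIND means deuteration strengthens binding.
This orientation is chosen because it reproduces, with a single
convention, every entry of the reference component table bundled with the
package (−10.69/−11.54 binding legs, +0.43/−0.42 component differences,
−0.85 overall).

Affinity conversions use T = 298.15 K and R = 1.98720425e−3
kcal/(mol·K): ΔG = −RT ln10 · pKi and, in the relative Cheng–Prusoff
form, ΔΔG = −RT ln10 · ΔpIC50. At 298.15 K these give −5.9 kcal/mol for
pKi 4.3 and −0.75 kcal/mol for a 0.55 pIC50 shift at the printed
precision (300 K would give −0.76); temperature is configurable.

## The deuteration transform

Deuteration is mimicked geometrically (the Ubbelohde effect): every
hydrogen covalently bound to N, O or S is contracted toward its heavy
atom so |X–H|_new = (1 − f)|X–H|_old with f = 0.023 by default, the heavy
atom frozen, and the transformed bonds emitted as (atom, atom, length)
constraints for an engine that re-optimises everything else. The
transform is applied once, not iterated with re-optimisation cycles.
Composition is multiplicative: f1 then f2 equals 1 − (1−f1)(1−f2).

"Exchangeable" is operationalised as every H within covalent range of an
N/O/S atom. The covalent-detection cutoff is 1.4 Å rather than the 1.2 Å
sometimes used for N–H/O–H alone, because thiol S–H bonds are ≈1.34 Å
and a cysteine thiol is an exchangeable site; 1.4 Å cleanly separates all
covalent X–H (≤1.35 Å) from any nonbonded contact (≥2 Å) in these
systems. A hydrogen equidistant (within 1e-6 Å) to two candidate heavy
atoms is treated as a malformed structure and raises.

## Hydrogen-bond and RDF conventions

Hydrogen bonds are geometric: donor–acceptor heavy-atom distance
≤ 3.5 Å and D–H···A angle ≥ 135°, both boundaries inclusive and both
configurable. No energy criterion is applied. These defaults are the
common convention and sit comfortably outside the 2.8–3.0 Å first-shell
peaks of aqueous amine hydration. Occupancy of a donor/acceptor pair is
the fraction of frames in which any donor hydrogen satisfies the
criteria; per-donor simultaneous counts use distinct bonded partners.

g(r) is normalised as pair count / (n_frames · n_centers · ρ · V_shell).
For box domains V_shell is the analytic 4πr²dr, which assumes the shells
stay inside the box — fixtures therefore restrict centers to the box
interior. For spherical droplets V_shell is the Monte-Carlo estimate of
shell ∩ droplet volume per center (seeded, ≥1e5 samples), which handles
shells protruding past the surface. Coordination numbers integrate
ρ g(r) 4πr² exactly per histogram shell (g is piecewise constant), with
the bin containing r_cut entered fractionally; on box fixtures this
agrees with direct neighbour counting to well under 2%.

Conformer classification is a pure function of |φ|: gauche at or below
90°, trans at or above 120°, an explicit *intermediate* band between
(real trajectories show a mix of folded structures with and without the
intramolecular contact, so a forced binary would misreport them). The
per-frame record also carries d(N1,N2) and an intramolecular-bond flag
(d ≤ 3.5 Å and an N2–H pointing at N1 within the angular criterion).
Population fractions carry Wilson 95% intervals, which stay inside [0,1]
and behave at near-unanimous counts. Clustering is k-medoids (PAM BUILD
initialisation, then Voronoi iteration) on standardised features —
torsion separations on the circle scaled by the circular standard
deviation, distances z-scored — because medoids are actual frames and
therefore inspectable representatives; medoid ties break to the lowest
frame index, making the procedure fully deterministic.

## What the generators emulate — and what they do not

`simgen` produces fixtures with *known ground truth*, not physics:

- **Histamine template.** Idealized internal coordinates (ring bond
  1.37 Å, C–C 1.53 Å, C–N 1.49 Å, N–H 1.01/1.03 Å); the requested
  side-chain torsion is built exactly. The fixed ring–Cβ orientation
  places d(N1,N2) ≈ 3.1 Å at φ = 62° and ≈ 4.4 Å at φ = 159°, the folded
  and extended regimes of the solution conformers.
- **Waters.** Rigid 3-site geometry (O–H 0.9572 Å, H–O–H 104.52°,
  matching the common 3-site solvent models). Droplet/box packing is
  random sequential addition with a 2.4 Å heavy-atom clash exclusion.
  RSA jams well below liquid-water density, so a droplet holds fewer
  near-solute waters than a real first+second shell; the bundled demo
  config widens the shell cutoff to 5 Å to fill a 36-molecule layer,
  while the shell-selection default stays at the 36-within-4-Å
  convention used for real cluster extraction.
- **Trajectories.** Frames are i.i.d. draws, not a Markov chain: the
  estimators in scope (populations, occupancies, RDFs) are marginal
  statistics, and autocorrelation is deliberately out of scope. Gauche
  frames draw |φ| uniform in [40°, 90°], trans in [140°, 180°] (random
  sign), straddling the representative 62°/159° values. Hydrogen-bond
  occupancy schedules toggle the partner molecule between a bonded
  position (2.8 Å along the best-aligned donor X–H axis, so the bonded
  geometry is near-linear and detectable) and a broken one (5.0 Å).
  Isotropic Gaussian jitter (default σ = 0.02 Å) is added to every atom;
  at this level torsion noise is ≈1°, so boundary leakage from the
  sampling windows into the intermediate band stays a few tenths of a
  percent. The drawn states, torsions and per-pair schedules are logged
  on the trajectory so estimators are validated against the generator's
  own ground truth, not against themselves.
- **Toy pocket.** Sixteen residues (98–103, 186–190, 250–254) as
  idealized stubs: a full Asp98 carboxylate accepting the ammonium
  hydrogen bond at 2.8 Å, Tyr250 hydroxyl donating to the other
  carboxylate oxygen, Thr103 accepting the ring N3–H, Thr190 donating to
  a backbone-like carbonyl on Asp186 at 2.76 Å, exchangeable −OH/−SH
  groups on Thr252 and Cys102, and Cα stubs for the hydrophobic rest.
  Constructed hydrogen bonds are built slightly bent (≈165–175°), as in
  real geometries; an exactly linear bond would make the surrogate score
  (below) blind to donor-H displacement.
- **Surrogate score.** A Gaussian well per detected hydrogen bond,
  −5·exp(−((d−2.9)/0.3)²) kcal/mol with d the through-hydrogen path
  length |D–H| + |H···A|. It exists so the cycle bookkeeping can be
  exercised end-to-end on synthetic structures, including a non-zero
  response to deuteration; it is not a force field and none of its
  outputs are physical predictions.

Consequently, passing tests demonstrate that the *estimators and
transforms* are correct (population recovery inside 99% binomial bands at
5000 frames, occupancy recovery to ±0.02 at 2000 frames, ideal-gas RDF
flat to sampling error, exact 2.3% contraction); they say nothing about
force-field accuracy, sampling convergence, or receptor biology on real
data.

## Reference tables as inputs

The per-residue decomposition table (36 residues, total −14.2 kcal/mol)
and the cycle component energies are published-table mirrors bundled as
TSVs — they are *inputs* to the bookkeeping, not computed here. The
decomposition filter keeps favorable contributions at or below
−0.06 kcal/mol and unfavorable ones at or above +0.02 kcal/mol,
inclusively (the reference table contains rows at exactly those values),
yielding 18 rows each; the anchor Asp98 at −5.45 kcal/mol carries 38.4%
of the total.

## Problem sizes and determinism

Default analysis sizes — 5000-frame recovery runs, 2000-frame occupancy
runs, an 800-frame demo pipeline, droplets of tens of waters — were
chosen so every statistical check has comfortable resolving power (the
99% binomial band at n = 5000 is ±1.6 points) while the whole suite and
the acceptance script each run in well under a minute of CPU. Every
stochastic component draws from a single `numpy.random.default_rng(seed)`
per call; identical (spec, seed) inputs are bit-reproducible, and the
pipeline manifest records output checksums to make re-run identity
checkable.

## Known limitations

- No periodic boundary conditions, no minimum-image imaging; domains are
  finite droplets or boxes.
- i.i.d. frames mean no kinetics: hydrogen-bond lifetimes and torsional
  autocorrelation cannot be studied on these fixtures.
- The XYZ format carries no residue metadata; structures read from XYZ
  get a single synthetic residue.
- Quantum-chemical and MM-GBSA energies are consumed, never computed; the
  surrogate score is a bookkeeping device.
- k-medoids builds the full pairwise distance matrix (fine to a few
  thousand frames; quadratic beyond).
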