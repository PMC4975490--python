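# Methods

## The model

`gomotor` implements a structure-based (Gō-type) coarse-grained model of a
myosin motor head. Each residue is a single bead at its Cα position; the
energy function is biased toward one or two reference (crystal)
conformations. The full Hamiltonian is an additive sum of six terms

    H = H_preMH + H_preConv + H_postConv + H_preConv–MH + H_postConv–MH + H_MH–Actin

* **H_preMH** — the catalytic motor-head (MH) domain, parameterised from the
  pre-powerstroke conformation: harmonic bonds and angles, a 1,3-cosine
  dihedral term, attractive 10–12 potentials on native contacts and a
  (σ/r)¹² repulsion on all non-native pairs,

      E_contact(r) = ε_h [ 5 (r₀/r)¹² − 6 (r₀/r)¹⁰ ],   min at r₀, depth −ε_h

* **H_preConv / H_postConv** — the converter domain, same functional form,
  with native geometry taken from the pre- or post-powerstroke structure
  respectively,
* **H_preConv–MH / H_postConv–MH** — converter–MH native contacts of each
  conformation (the exclusive parts of these two maps are what
  distinguishes the basins),
* **H_MH–Actin** — native contacts between the MH and the actin interface,
  extracted from the aligned actin-bound complex. Actin beads are frozen
  (a rigid binding surface with no internal terms).

A native contact is a pair with Cα–Cα distance < 0.8 nm in the reference
conformation and sequence separation (j − i) > 3; the separation filter
applies along a chain (including converter–MH pairs near the domain
junction, which would otherwise double-count with bonded terms) but never
across chains (MH–actin).

Default parameters follow standard structure-based-model practice:
K_r = 20 kcal/(mol·Å²), K_θ = 20 kcal/(mol·rad²), K_φ(1) = 1.0 and
K_φ(3) = 0.5 kcal/mol, ε_h = ε_l = 1.0 kcal/mol, σ = 4 Å. Internally all
lengths are nm and all energies are in units of ε_h.

### Scenario toggles

The mechanochemical states are selected by switching terms on or off:

| scenario | terms active |
|---|---|
| leading head (pre-powerstroke, ADP) | preMH, preConv, preConv–MH, MH–Actin |
| trailing head (post-powerstroke, ADP) | preMH, postConv, postConv–MH, MH–Actin |
| powerstroke (ADP·Pi / ADP) | all six |

The powerstroke step itself is modelled by removing the phosphate-mediated
native contacts from H_preMH while all six terms stay on: with those
contacts present the pre basin dominates; without them the ensemble shifts
to the post basin.

**Pi-mediated contacts.** A residue *coordinates* the phosphate if its Cα
lies within 0.8 nm of any phosphate ligand atom. Which native contacts
count as "mediated" is ambiguous at Cα resolution; both readings are
implemented (`mode="both"`: both endpoints coordinating — the most literal
bridged-pair reading; `mode="any"`: every native contact touching a
coordinating residue). The pipeline default is `"any"`: at one bead per
residue the bridged-pair subset is so small that releasing the phosphate
barely perturbs the pocket, whereas the any-endpoint reading releases the
full coordination shell and reproduces the powerstroke inversion. Both
modes are config switches.

### Junction treatment

The converter is chain-continuous with the MH. The bond across the
junction always acts (a separate "linker" term); the angles and dihedrals
spanning the junction are omitted by default (`junction_bonded =
"bond_only"`), making the hinge a free pivot whose orientation is set
entirely by the converter–MH contact maps. This matters for the dual-basin
model: harmonic angle terms from *both* basins would add into a single
well at the averaged angle and destroy the bistability. A `"basin"` option
assigns the junction bonded terms to the respective converter basin
instead.

Shared converter–MH pairs (native in both conformations) contribute one
term per basin under the literal additive Hamiltonian (the default); a
`dedup_shared_converter` switch keeps only the pre copy. Note that a
shared pair whose two native distances differ substantially makes the
literal sum pathological (each basin's short-distance core penalises the
other basin's minimum); the synthetic fixtures are constructed so that
shared pairs only occur at pivot-invariant distances.

## Dynamics

The Langevin equation m r̈ = −ζ ṙ − ∂H/∂r + Γ(t), with
⟨Γᵢ(t)·Γⱼ(t′)⟩ = (6 ζ k_B T / h) δᵢⱼ δ(t−t′), is integrated with a BBK
(damped velocity-Verlet) scheme; the same per-step Gaussian force enters
both velocity half-kicks. Defaults: T = 300 K (k_BT = 0.596 ε_h),
ζ = 0.05 τ_L⁻¹, h = 0.0025 τ_L with τ_L = (m σ²/ε_h)^½ and m = 1 per
bead. The low friction accelerates conformational sampling without
changing the sampled ensemble. Each run relaxes `n_relax` steps before
sampling; the random stream is fully determined by the seed, so identical
configurations reproduce bit-identically.

External strain is a constant force on the converter beads along the actin
axis, specified in kJ mol⁻¹ nm⁻¹ (converted once, 1 kJ = 1/4.184 kcal).
The strain scenario applies the stated magnitude per bead: under the
total-force reading the 0–5 kJ mol⁻¹ nm⁻¹ range produces no measurable
response in this model class, while per-bead forces give the expected
gradual shift of the inter-subunit distance; both conventions are exposed
(`ExternalForce(per_bead=...)`, config `strain_per_bead`).

Validation relies on closed forms: positional variance k_BT/k and mean
displacement F/k of a harmonically tethered bead, and equipartition of
kinetic energy — all reproduced to ~1 % (asserted at 3 %).

## The synthetic toy motor

Real myosin structures cannot ship with the package, so every behavioural
claim is exercised on a deterministic miniature motor
(`gomotor.synthetic`) built to have the same structural logic:

* a **slab** of 34 beads (boustrophedon over a 2 × 2 × n grid, 0.38 nm
  along rows, 0.47 nm between rows/layers, ±0.08 nm anti-collinearity
  dither) — the big-subunit analogue. The tight packing gives ≈ 3.5
  contacts per bead; a looser lattice partially melts at k_BT = 0.6 ε_h.
* a four-bead **flap** hugging one end face at 0.52 nm standoff plus a
  two-bead riser — the small-subunit / switch-element analogue. Its
  anchors to the slab are weak, wide contacts, and a pseudo-phosphate
  placed at the flap pocket makes exactly this anchoring Pi-mediated.
* a 12-bead **converter plate** on a free-pivot hinge above the flap. At
  the pre hinge angle it docks onto the flap (14 exclusive contacts); at
  the post angle it folds onto the rigid slab top face (14). The docks
  are nearly degenerate so that basin exchange is observable within
  minutes of CPU; the pre basin's extra stability with phosphate present
  comes from the anchored flap presenting a rigid docking site.

Generation is a pure function of `ToyMotorSpec`; both conformations are
self-avoiding, share bit-identical body coordinates, and carry disjoint
non-empty exclusive converter–MH contact sets.

### What the toy does and does not show

The toy reproduces, qualitatively: the converter-ensemble separation
between leading and trailing heads; the widening of the switch-I–switch-II
distance in the trailing head (the ADP-release reporter); the inversion of
the pre/post basin populations upon phosphate-contact removal; and the
monotone shift of the inter-subunit distance under forward strain.

It does **not** reproduce effects that require the motor-head body itself
to deform between conformations: because the two reference structures
share one rigid body (which is also what makes the construction exactly
testable), the small-subunit RMSD after fitting the big subunit shows no
systematic leading/trailing ordering — that signal, in the real system,
comes from elastic distortion of the MH under the post-converter dock.
Passing the toy suite therefore validates the machinery (terms, toggles,
integrator, observables) and the allosteric contact logic, not the
elastic response of a real protein topology.

## Observables and estimators

* Fitted-subset RMSD: Kabsch superposition (proper rotation enforced) on
  the fit group, RMS deviation over the measure group.
* Group distances: unweighted Cα centre-of-geometry separation.
* Modes: Gaussian KDE with Silverman bandwidth on a 512-point grid, peaks
  by local maxima with a prominence floor of 5 % of the global maximum;
  for bimodal targets the two most prominent peaks in ascending order.
  Histogram bins default to 0.01 nm (RMSD) and 0.05 nm (distances).
* Basin populations: fraction of samples on each side of a threshold
  placed midway between the pre-pose (0) and post-pose converter RMSD —
  a threshold computed from the two reference structures, not fitted to
  the data.

### Sampling sizes and pooling

Two-state populations in the dual-basin model carry large
single-trajectory variance (dwell times are of order 10⁵ steps), so
population and strain-mode estimates pool several independent replicas
with derived seeds (`replicas` in the scenario config; 3–4 replicas of
2 × 10⁶ steps for populations, 3 × 7 × 10⁵ per strain magnitude). The
default sampling lengths (10⁶ steps for the head scenarios, snapshots
every 500 steps) were chosen by convergence diagnostics — crossing counts
and mode stability across seeds.

## Numerical notes

* Collinear bonded frames make the analytic dihedral gradient singular;
  the kernels guard the exactly-degenerate case and the toy geometry keeps
  native angles ≈ 134°, far from the singularity. Real Cα chains satisfy
  this naturally.
* The energy guard aborts a run (with the offending frame attached) if
  |E| exceeds a configurable bound — the symptom of a too-large time step.
* Repulsion uses the exact all-pairs sum (no cutoff approximations);
  native pairs of any active basin, bonded neighbours (|i−j| ≤ 3 within a
  chain) and frozen–frozen pairs are excluded.
* Altloc policy on PDB read: first-listed conformer. Duplicate CA records
  with conflicting coordinates are an error.

## Limitations

* The lever arm is not modelled; directionality comparisons between motor
  classes are out of scope.
* Actin is a frozen interface — no filament flexibility.
* Strain is an external force on one head, not a two-head simulation.
* Real-structure workflows (published pre/post conformations and the
  actin-bound template) are supported through the config (PDB paths,
  residue-range partitions, explicit actin correspondences) but require
  the user to supply the files and the subdomain ranges — the published
  model description does not print residue ranges, so
  `data/myosin6_partition.yaml` ships as a documented interpretation.
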