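# gomotor

Structure-based coarse-grained modelling of the myosin mechanochemical
cycle: build Cα models and multi-basin Gō-type Hamiltonians from pairs of
conformations, run Langevin dynamics under scenario-specific term toggles
and strain forces, and analyse the distributional observables that report
on the powerstroke and on ADP release.

## The problem

A myosin motor head walks on actin through a cycle of nucleotide-coupled
conformational changes. Two of its steps carry the physics of the motor:
the **powerstroke** — the swing of the converter domain from the pre- to
the post-powerstroke pose, triggered by inorganic-phosphate (Pi) release —
and **ADP release**, whose rate differs between the leading head
(pre-powerstroke converter) and the trailing head (post-powerstroke
converter) of a two-head-bound dimer, with forward strain on the trailing
head accelerating it further. `gomotor` provides the minimal physical
model in which these couplings can be simulated and measured: a Cα bead
per residue, an energy function funnelled toward the reference
conformations, and nothing else.

## The model

The Hamiltonian is an additive six-term structure-based energy

    H = H_preMH + H_preConv + H_postConv + H_preConv–MH + H_postConv–MH + H_MH–Actin

with, for each domain term, harmonic bonds K_r/2 (r−r₀)², harmonic angles
K_θ/2 (θ−θ₀)², dihedrals Σ_{n=1,3} K_φ(n)[1−cos n(φ−φ₀)], native-contact
attraction ε_h[5(r₀/r)¹²−6(r₀/r)¹⁰] for pairs within 0.8 nm at sequence
separation > 3 in the reference structure, and ε_l(σ/r)¹² repulsion for
all other pairs (K_r = 20 kcal/mol·Å², K_θ = 20 kcal/mol·rad²,
K_φ(1) = 1, K_φ(3) = 0.5, ε_h = ε_l = 1 kcal/mol, σ = 4 Å). Motion follows
the Langevin equation m r̈ = −ζṙ − ∂H/∂r + Γ(t) with
⟨Γᵢ·Γⱼ⟩ = (6ζk_BT/h)δᵢⱼ, integrated by a BBK scheme at T = 300 K,
ζ = 0.05 τ_L⁻¹, h = 0.0025 τ_L.

Scenarios of the cycle are term toggles: the leading head keeps the pre
converter terms, the trailing head the post ones; the powerstroke
simulations keep all six terms and model Pi release by deleting the
phosphate-mediated contact subset from the motor-head term. Strain is a
constant pulling force on the converter along the actin axis. Actin is a
frozen interface.

Everything is exercised end-to-end on a deterministic synthetic "toy
motor" (a contact-rich slab + a Pi-anchored switch flap + a hinged
converter plate) so the full pipeline is testable without structure
downloads; real PDB inputs are supported through the same config surface.
See `docs/methods.md` for the model details and for what the toy does and
does not demonstrate.

## Worked example

```bash
python examples/03_powerstroke_pi_release.py
```

prints (seed 21, two pooled replicas of 10⁶ steps per condition):

```
powerstroke_with_pi:
  active MH contacts: 139
  basin threshold:    1.57 nm (midpoint between the pose references)
  pre-basin fraction:  0.74
  post-basin fraction: 0.26
powerstroke_without_pi:
  active MH contacts: 112
  basin threshold:    1.57 nm (midpoint between the pose references)
  pre-basin fraction:  0.24
  post-basin fraction: 0.76
```

With the 27 phosphate-mediated contacts present the converter favours
the pre-powerstroke basin (74 % of frames below the threshold on the
converter-RMSD coordinate; pooled longer runs give ~90 %); removing them
inverts the populations — the ensemble swings to the post-powerstroke
basin. That inversion *is* the powerstroke mechanism in this model class.

The other examples cover the contact-map algebra
(`01_contact_maps.py`), the leading/trailing asymmetry
(`02_leading_vs_trailing.py`: converter RMSD mode 0.38 nm vs 3.14 nm, and
the switch-I–switch-II distance widening from 0.466 to 0.470 nm in the
trailing head), the strain scan (`04_strain_response.py`: inter-subunit
distance mode 1.98 → 2.49 → 2.76 nm as the per-bead strain grows 0 → 3 → 5
kJ mol⁻¹ nm⁻¹), and the PDB/topology file workflow (`05_pdb_workflow.py`).

A thin CLI wraps the same pipeline: `gomotor demo`,
`gomotor simulate --config run.yaml --scenario strain_scan`,
`gomotor build --out model.top`.

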