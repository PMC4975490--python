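"""Deterministic toy fixtures: a two-domain "toy motor", a filament
surrogate and a pseudo-phosphate pocket.

The toy motor caricatures the structural logic of a myosin head at
miniature scale:

* a rigid, contact-rich **slab** (the big-subunit analogue) built as a
  boustrophedon over a 2 x 2 x n grid of beads;
* a four-bead **flap** hugging one end face of the slab plus a two-bead
  riser (together the small-subunit analogue).  The flap is held against
  the slab only by a handful of native contacts, and a pseudo-phosphate
  placed at the flap pocket makes exactly those anchors "Pi-mediated":
  removing them releases the flap, mimicking the loss of the
  switch-loop anchoring on phosphate release;
* a **converter plate** hinged above the flap.  In the *pre* pose it hangs
  down along the end face and docks onto the flap (so the pre basin is
  anchored through the Pi-stabilised element); in the *post* pose it folds
  over onto the rigid top face of the slab.  The two poses therefore carry
  disjoint, non-empty exclusive converter-MH contact sets while the body
  coordinates are bitwise identical — the same construction the dual-basin
  model needs.

Everything is a pure function of ToyMotorSpec: no randomness enters the
geometry (the seed is recorded for provenance only).  A small alternating
z-dither keeps bonded frames away from collinear degeneracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure import CAlphaStructure, DomainPartition

_SPACING_Y = 0.47      # inter-row spacing, nm (tight packing: the 0.8 nm
_SPACING_Z = 0.47      # cutoff then captures in-plane and 3D diagonals,
                       # giving a folded-protein-like contact density)
_DITHER = 0.08         # anti-collinearity z-dither, nm (keeps bonded frames
                       # ~45 deg away from the collinear dihedral singularity
                       # even under thermal angle fluctuations)
_SELF_AVOID = 0.38     # minimum allowed non-bonded distance, nm
_FLAP_STANDOFF = 0.52  # flap plane offset from the slab end face, nm


@dataclass
class ToyMotorSpec:
    """Geometry of the toy motor; generation is deterministic given this."""

    n_body: int = 40
    n_conv: int = 12
    hinge_angle_pre: float = -1.11
    hinge_angle_post: float = 3.27
    bead_spacing: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_body < 12:
            raise ValueError("n_body must be >= 12")
        if self.n_conv < 6:
            raise ValueError("n_conv must be >= 6")
        if abs(self.hinge_angle_pre - self.hinge_angle_post) < 0.3:
            raise ValueError("hinge angles must differ by >= 0.3 rad")


def _slab_coords(n_slab: int, s: float) -> np.ndarray:
    """Boustrophedon walk over two layers x two rows, ending near x = 0."""
    a = (n_slab + 2) // 4            # first row pair length
    rest = n_slab - 2 * a
    rows = [a, a, rest - rest // 2, rest // 2]
    coords = []
    k = 0
    for r, length in enumerate(rows):
        z = 0.0 if r < 2 else _SPACING_Z
        y = (r % 2) * _SPACING_Y
        xs = np.arange(length) * s
        if r % 2 == 1:     # return rows run backwards
            xs = xs[::-1]
        for x in xs:
            coords.append([x, y, z + _DITHER * (-1.0) ** k])
            k += 1
    return np.array(coords)


def _canonical_converter(n_conv: int, s: float, hinge: np.ndarray) -> np.ndarray:
    """Unrotated converter plate: two unequal rows extending -x from the
    hinge.  The return row stops short of the hinge so that no plate bead
    other than the hinge-adjacent one stays near the riser through the
    swing (pairs at an angle-invariant distance from the pivot are fine;
    angle-variant near-riser pairs would be native in both poses with
    conflicting distances)."""
    row1 = min(n_conv, n_conv // 2 + 1)
    row2 = n_conv - row1
    coords = []
    for k in range(row1):
        coords.append([hinge[0] - 0.5 - s * k, 0.0,
                       hinge[2] + _DITHER * (-1.0) ** k])
    x_far = hinge[0] - 0.5 - s * (row1 - 1)
    for k in range(row2):
        coords.append([x_far + s * k, _SPACING_Y,
                       hinge[2] + _DITHER * (-1.0) ** k])
    return np.array(coords)


def _rotate_about_y(points: np.ndarray, pivot: np.ndarray,
                    angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rel = points - pivot
    out = rel.copy()
    out[:, 0] = rel[:, 0] * c + rel[:, 2] * s
    out[:, 2] = -rel[:, 0] * s + rel[:, 2] * c
    return out + pivot


def _min_nonbonded(coords: np.ndarray) -> float:
    d = cdist(coords, coords)
    n = len(coords)
    iu, ju = np.triu_indices(n, k=2)       # exclude self and bonded neighbours
    return float(d[iu, ju].min())


def _make_structure(coords: np.ndarray) -> CAlphaStructure:
    n = len(coords)
    return CAlphaStructure(
        coords=coords,
        chain_ids=np.full(n, "A"),
        res_numbers=np.arange(1, n + 1),
        res_names=np.full(n, "GLY"),
    )


def make_toy_motor(spec: ToyMotorSpec | None = None):
    """Build the pre/post conformations and the domain partition.

    Returns ``(pre, post, partition)``.  Body (slab + flap + riser)
    coordinates are identical between the conformations; only the converter
    plate is rotated about the hinge bead.  Both conformations are
    self-avoiding; if a requested hinge angle produces a clash the angle is
    nudged in 0.05 rad steps (up to 0.25 rad) before giving up.
    """
    spec = spec or ToyMotorSpec()
    s = spec.bead_spacing
    n_slab = spec.n_body - 6
    slab = _slab_coords(n_slab, s)
    # slab ends near (0, 0, z_top); flap hugs the end face
    flap = np.array([
        [-_FLAP_STANDOFF, 0.0, _SPACING_Z],
        [-_FLAP_STANDOFF, 0.0, 0.0],
        [-_FLAP_STANDOFF, _SPACING_Y, 0.0],
        [-_FLAP_STANDOFF, _SPACING_Y, _SPACING_Z],
    ])
    riser = np.array([
        [-_FLAP_STANDOFF, 0.5 * _SPACING_Y, _SPACING_Z + 0.50],
        [-_FLAP_STANDOFF, 0.5 * _SPACING_Y, _SPACING_Z + 1.05],
    ])
    body = np.vstack([slab, flap, riser])
    hinge = body[-1]
    canonical = _canonical_converter(spec.n_conv, s, hinge)

    def place(angle: float) -> np.ndarray:
        for trial in range(6):
            for sign in ((1.0,) if trial == 0 else (1.0, -1.0)):
                a = angle + sign * 0.05 * trial
                conv = _rotate_about_y(canonical, hinge, a)
                coords = np.vstack([body, conv])
                if _min_nonbonded(coords) >= _SELF_AVOID:
                    return coords
        raise ValueError(
            f"converter clash unavoidable near hinge angle {angle:.2f} rad")

    pre = _make_structure(place(spec.hinge_angle_pre))
    post = _make_structure(place(spec.hinge_angle_post))

    nb, nc = spec.n_body, spec.n_conv
    mh = np.arange(1, nb + 1)
    conv = np.arange(nb + 1, nb + nc + 1)
    big = np.arange(1, n_slab + 1)
    small = np.arange(n_slab + 1, nb + 1)          # flap + riser
    # end-column slab beads (x ~ 0): the P-loop analogue
    end_col = np.nonzero(np.abs(slab[:, 0]) < 1e-9)[0] + 1
    partition = DomainPartition({
        "MH": mh, "converter": conv, "MH_big": big, "MH_small": small,
        "P_loop": end_col,
        "switch_I": np.array([n_slab + 1, n_slab + 2]),
        "switch_II": np.array([n_slab + 3, n_slab + 4]),
    })
    partition.validate(pre.n_beads)
    return pre, post, partition


def make_toy_filament(n: int, spacing: float = 0.55,
                      axis=(1.0, 0.0, 0.0), origin=(0.0, 0.0, 0.0)) -> CAlphaStructure:
    """Straight filament surrogate: ``n`` beads at exact ``spacing`` along
    ``axis`` starting from ``origin``; the principal axis of the result is
    exactly ``axis`` (oriented along increasing bead index)."""
    if n < 4:
        raise ValueError("filament needs n >= 4")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    coords = np.asarray(origin, dtype=float) + spacing * np.arange(n)[:, None] * axis
    st = CAlphaStructure(
        coords=coords,
        chain_ids=np.full(n, "F"),
        res_numbers=np.arange(1, n + 1),
        res_names=np.full(n, "ACT"),
    )
    return st


def make_toy_ligand(pre: CAlphaStructure, pocket) -> CAlphaStructure:
    """Return a copy of ``pre`` with a single pseudo-phosphate atom at the
    pocket centroid.  Pocket beads must be mutually within 1.2 nm; the
    construction guarantees every pocket bead coordinates the ligand at the
    default 0.8 nm cutoff."""
    pocket = np.asarray(pocket, dtype=int)
    if pocket.size == 0:
        raise ValueError("empty pocket")
    xyz = pre.coords_of(pocket)
    if pocket.size > 1 and cdist(xyz, xyz).max() > 1.2:
        raise ValueError("pocket too dispersed (beads must be within 1.2 nm)")
    centroid = xyz.mean(axis=0)
    if np.linalg.norm(xyz - centroid, axis=1).max() >= 0.8:
        raise ValueError("pocket too dispersed for the coordination cutoff")
    out = CAlphaStructure(
        coords=pre.coords.copy(),
        chain_ids=pre.chain_ids.copy(),
        res_numbers=pre.res_numbers.copy(),
        res_names=pre.res_names.copy(),
        ligands=list(pre.ligands) + [("PO4", "P", centroid)],
    )
    return out


def default_pocket(spec: ToyMotorSpec | None = None) -> np.ndarray:
    """The flap beads: the pocket whose pseudo-Pi mediates the flap anchors."""
    spec = spec or ToyMotorSpec()
    n_slab = spec.n_body - 6
    return np.arange(n_slab + 1, n_slab + 5)
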