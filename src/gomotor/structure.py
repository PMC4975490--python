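"""C-alpha structures, PDB I/O, superposition and fitted RMSD.

The model represents each residue by a single bead at the C-alpha position;
hetero groups of interest (ADP, phosphate, Mg) are carried along as ligand
atoms so that phosphate-mediated contacts can be identified.  All coordinates
are stored in nm.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .units import NM_PER_ANGSTROM

#: hetero residue names retained as ligands on read
LIGAND_RESNAMES = {"ADP", "PO4", "PI", "MG", "2PO", "PO3"}

#: names under which a ligand atom counts as phosphate
PHOSPHATE_NAMES = {"PO4", "PI", "2PO", "PO3"}


@dataclass
class CAlphaStructure:
    """One bead per residue at the C-alpha position, plus ligand heavy atoms.

    Bead indices are 1-based and contiguous (``1..n_beads``); every group /
    contact-map index in the package refers to this numbering.
    """

    coords: np.ndarray                      # (N, 3), nm
    chain_ids: np.ndarray                   # (N,), str
    res_numbers: np.ndarray                 # (N,), int, author numbering
    res_names: np.ndarray                   # (N,), str, 3-letter codes
    ligands: list[tuple[str, str, np.ndarray]] = field(default_factory=list)
    #: (ligand_name, atom_name, coord nm)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.chain_ids = np.asarray(self.chain_ids)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        self.res_names = np.asarray(self.res_names)
        n = self.n_beads
        for arr, name in ((self.chain_ids, "chain_ids"),
                          (self.res_numbers, "res_numbers"),
                          (self.res_names, "res_names")):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != N {n}")
        self._warn_spacing()

    def _warn_spacing(self) -> None:
        for cid in np.unique(self.chain_ids):
            xyz = self.coords[self.chain_ids == cid]
            if len(xyz) < 2:
                continue
            d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            bad = (d < 0.2) | (d > 0.6)
            if bad.any():
                warnings.warn(
                    f"chain {cid}: {int(bad.sum())} consecutive CA-CA distances "
                    f"outside [0.2, 0.6] nm (min {d.min():.3f}, max {d.max():.3f})",
                    stacklevel=3,
                )

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def coords_of(self, beads: np.ndarray) -> np.ndarray:
        """Coordinates of a 1-based bead-index set, in the stored order."""
        beads = np.asarray(beads, dtype=int)
        if beads.min() < 1 or beads.max() > self.n_beads:
            raise IndexError("bead index outside [1, N]")
        return self.coords[beads - 1]

    def phosphate_atoms(self) -> np.ndarray:
        """(M, 3) coordinates of all phosphate ligand atoms."""
        pts = [c for name, _a, c in self.ligands if name.upper() in PHOSPHATE_NAMES]
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass
class DomainPartition:
    """Named bead groups: MH, converter, MH_big, MH_small, P_loop, switch_I,
    switch_II, actin.  Groups are 1-based index arrays."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.unique(np.asarray(v, dtype=int))
                       for k, v in self.groups.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def validate(self, n_beads: int) -> None:
        for name, g in self.groups.items():
            if len(g) and (g.min() < 1 or g.max() > n_beads):
                raise ValueError(f"group {name} outside [1, {n_beads}]")
        g = self.groups
        if "MH" in g and "converter" in g:
            if np.intersect1d(g["MH"], g["converter"]).size:
                raise ValueError("MH and converter overlap")
        if "MH_big" in g and "MH_small" in g and "MH" in g:
            if np.intersect1d(g["MH_big"], g["MH_small"]).size:
                raise ValueError("MH_big and MH_small overlap")
            union = np.union1d(g["MH_big"], g["MH_small"])
            if not np.array_equal(union, g["MH"]):
                raise ValueError("MH_big + MH_small must partition MH")
        for motif in ("P_loop", "switch_I", "switch_II"):
            if motif in g and "MH" in g:
                if np.setdiff1d(g[motif], g["MH"]).size:
                    raise ValueError(f"{motif} not contained in MH")


def partition_from_ranges(structure: CAlphaStructure,
                          ranges: dict[str, list]) -> DomainPartition:
    """Build a partition from residue-number ranges.

    ``ranges`` maps a group name to a list of ``[first, last]`` residue
    numbers (inclusive) or ``[chain, first, last]`` entries.  The published
    structures never come with printed residue ranges for the subdomains, so
    these are configuration, not constants.
    """
    groups: dict[str, np.ndarray] = {}
    for name, spans in ranges.items():
        beads: list[int] = []
        for span in spans:
            if len(span) == 3:
                chain, lo, hi = span
                mask = (structure.chain_ids == str(chain)) \
                    & (structure.res_numbers >= int(lo)) \
                    & (structure.res_numbers <= int(hi))
            else:
                lo, hi = span
                mask = (structure.res_numbers >= int(lo)) \
                    & (structure.res_numbers <= int(hi))
            beads.extend((np.nonzero(mask)[0] + 1).tolist())
        groups[name] = np.array(sorted(set(beads)), dtype=int)
    part = DomainPartition(groups)
    part.validate(structure.n_beads)
    return part


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_calpha(pdb_text: str, chain_filter=None) -> CAlphaStructure:
    """Parse PDB-format text into a :class:`CAlphaStructure`.

    One bead per residue with a CA atom, in file order.  HETATM groups named
    ADP/PO4/PI/MG are kept as ligands.  Alternate locations resolve to the
    first-listed conformer.  Raises ``ValueError`` if no CA atoms are found or
    if a residue carries conflicting (non-altloc) CA records.
    """
    pdbfile = bpdb.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdbfile.get_structure(model=1, altloc="first")
    if chain_filter is not None:
        chain_filter = {str(c) for c in chain_filter}
        atoms = atoms[np.isin(atoms.chain_id, list(chain_filter))]

    ca = atoms[(atoms.atom_name == "CA") & ~atoms.hetero]
    if ca.array_length() == 0:
        raise ValueError("no CA atoms in PDB input")

    keys = list(zip(ca.chain_id, ca.res_id, ca.ins_code))
    seen: dict[tuple, int] = {}
    keep = np.ones(len(keys), dtype=bool)
    for idx, key in enumerate(keys):
        if key in seen:
            prev = seen[key]
            if not np.allclose(ca.coord[prev], ca.coord[idx]):
                raise ValueError(
                    f"residue {key[0]}/{key[1]}{key[2]} has conflicting CA records")
            keep[idx] = False
        else:
            seen[key] = idx
    ca = ca[keep]

    ligands: list[tuple[str, str, np.ndarray]] = []
    het = atoms[atoms.hetero]
    for i in range(het.array_length()):
        resname = str(het.res_name[i]).strip().upper()
        if resname in LIGAND_RESNAMES:
            ligands.append((resname, str(het.atom_name[i]).strip(),
                            het.coord[i] * NM_PER_ANGSTROM))

    return CAlphaStructure(
        coords=ca.coord * NM_PER_ANGSTROM,
        chain_ids=ca.chain_id.astype(str),
        res_numbers=ca.res_id.astype(int),
        res_names=ca.res_name.astype(str),
        ligands=ligands,
    )


def _to_atom_array(structure: CAlphaStructure,
                   coords_nm: np.ndarray) -> bst.AtomArray:
    n = structure.n_beads
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords_nm, dtype=float) / NM_PER_ANGSTROM
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.res_numbers
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = np.full(n, "CA", dtype="U6")
    arr.element = np.full(n, "C", dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(path, structure: CAlphaStructure, frames=None) -> None:
    """Write the structure (or a multi-MODEL trajectory of bead frames)."""
    if frames is None:
        atoms = _to_atom_array(structure, structure.coords)
    else:
        frames = np.asarray(frames, dtype=float)
        stack = bst.stack([_to_atom_array(structure, f) for f in frames])
        atoms = stack
    out = bpdb.PDBFile()
    out.set_structure(atoms)
    out.write(str(path))


def write_xyz(path, frames: np.ndarray, names=None) -> None:
    """Plain multi-frame XYZ (coordinates in nm)."""
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    if names is None:
        names = ["CA"] * n
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{n}\n\n")
            for name, (x, y, z) in zip(names, f):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with the proper rotation R (det = +1) and
    translation t minimising the RMSD of ``R @ x + t`` over the matched
    points.  Raises for mismatched sizes or degenerate (<3 or collinear)
    point sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"size mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    # collinearity check: second principal extent must be non-zero
    for pts in (x, y):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1.0):
            raise ValueError("collinear point set: rotation underdetermined")
    H = x.T @ y
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    diff = (mobile @ R.T + t) - reference
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)


def fitted_rmsd(frame: np.ndarray, reference, fit_group, measure_group) -> float:
    """RMSD of ``measure_group`` after superposing ``frame`` onto the
    reference using ``fit_group`` only — the "RMSD of the small subunit after
    least-squares fitting of the big subunit" observable.

    ``frame`` is an (N, 3) coordinate array in the reference's bead
    numbering; ``reference`` may be a structure or a bare (N, 3) array.
    """
    fit_group = np.asarray(fit_group, dtype=int)
    measure_group = np.asarray(measure_group, dtype=int)
    if fit_group.size == 0 or measure_group.size == 0:
        raise ValueError("empty fit or measure group")
    ref = reference.coords if hasattr(reference, "coords") else np.asarray(reference)
    frame = np.asarray(frame, dtype=float)
    R, t, _ = kabsch_superpose(frame[fit_group - 1], ref[fit_group - 1])
    moved = apply_transform(frame[measure_group - 1], R, t)
    diff = moved - ref[measure_group - 1]
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def map_actin(motor: CAlphaStructure, template_complex: CAlphaStructure,
              correspondence, actin_beads) -> np.ndarray:
    """Place actin beads in the motor frame by structural superposition.

    ``correspondence`` is an explicit list of (motor_bead, template_bead)
    index pairs over the shared myosin part; the template myosin is
    superposed onto the motor over those pairs and the same transform is
    applied to the template's ``actin_beads``.  Returns the transformed
    actin coordinates (nm).
    """
    pairs = np.asarray(correspondence, dtype=int)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("correspondence needs at least 3 bead pairs")
    mob = template_complex.coords_of(pairs[:, 1])
    ref = motor.coords_of(pairs[:, 0])
    R, t, _ = kabsch_superpose(mob, ref)
    return apply_transform(template_complex.coords_of(np.asarray(actin_beads)), R, t)
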